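"""Published site-specific glycoform measurements used as package inputs.

The bundled TSV transcribes the LC-ESI-MS relative glycoform amounts (%)
measured on the three N-glycosylation sites of the SUBEX-C57Y ERAD substrate
purified from the *Arabidopsis* *os9* and *mns4 mns5* mutants.  Isomer
annotations attach the structure calls established by diagnostic digestion
and isomer-specific chromatography: in *os9* the dominant Hex8HexNAc2 is the
monoglucosylated Glc1Man7GlcNAc2; in *mns4 mns5*, where C-branch trimming is
absent, the dominant Hex9HexNAc2 is Glc1Man8GlcNAc2 (one extra mannose).
"""

from __future__ import annotations

from importlib import resources

from .quantify import GlycoformTable, read_table

#: isomer annotation per genotype: composition label -> registry structure
GENOTYPE_ANNOTATIONS = {
    "os9": {"Hex8HexNAc2": "Glc1Man7GlcNAc2"},
    "mns4mns5": {"Hex9HexNAc2": "Glc1Man8GlcNAc2"},
}

SITE_COLUMNS = [
    "site1_os9", "site1_mns4mns5",
    "site2_os9", "site2_mns4mns5",
    "site3_os9", "site3_mns4mns5",
]

#: glycopeptide backbones of the three sequons (site 2 is the worked example)
SITE_PEPTIDES = {"site2": "NLSLSSNR"}


def load_site_glycoforms() -> GlycoformTable:
    """The measured per-site glycoform table, with isomer annotations."""
    path = resources.files("glycotrim.data") / "subex_site_glycoforms.tsv"
    with resources.as_file(path) as p:
        table = read_table(p)
    table.annotations = {
        col: GENOTYPE_ANNOTATIONS[col.split("_", 1)[1]] for col in table.data.columns
    }
    return table
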