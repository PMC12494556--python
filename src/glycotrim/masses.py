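"""Monoisotopic mass constants shared across the package.

Monosaccharide *residue* masses (the glycosidic-bond form, one water less
than the free sugar) are computed from their elemental formulas with
pyteomics, so the whole package runs off a single atomic-mass table.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

# residue (dehydrated) formulas of the four composition classes
HEX = _pmass.calculate_mass(formula="C6H10O5")  # Glc, Man, Gal ...
HEXNAC = _pmass.calculate_mass(formula="C8H13NO5")  # GlcNAc, GalNAc
DHEX = _pmass.calculate_mass(formula="C6H10O4")  # Fuc
PENT = _pmass.calculate_mass(formula="C5H8O4")  # Xyl, Ara

WATER = _pmass.calculate_mass(formula="H2O")

#: fixed Cys modification (iodoacetamide S-alkylation)
CARBAMIDOMETHYL = _pmass.calculate_mass(formula="C2H3NO")

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def peptide_monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide with carbamidomethylated Cys.

    Raises ``ValueError`` on an empty sequence or non-standard residues.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s) in peptide: {sorted(bad)}")
    return _pmass.calculate_mass(sequence=sequence) + sequence.count("C") * CARBAMIDOMETHYL
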