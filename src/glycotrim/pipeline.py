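"""Configuration, shared TSV/FASTA readers and the end-to-end pipeline.

The pipeline maps (protein FASTA, per-site deconvoluted peak lists) to a
per-site glycoform table: sequon detection, in-silico tryptic digestion,
glycoform enumeration, ppm-tolerance annotation, relative quantification and
isobaric-structure inference.  Data go to files; logging goes to stderr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import enzymes, quantify
from .glycan import GlycanComposition
from .proteomics import (
    DEFAULT_RANGES,
    DEFAULT_TOL_PPM,
    Assignment,
    PeakList,
    ProteinRecord,
    enumerate_glycoforms,
    find_sequons,
    match_peaks,
    theoretical_masses,
    tryptic_digest,
)

log = logging.getLogger("glycotrim")


class InputError(ValueError):
    """Missing or unreadable input (exit code 2 at the CLI)."""


class ValidationError(ValueError):
    """Readable but inconsistent input (exit code 3 at the CLI)."""


@dataclass
class PipelineConfig:
    tol_ppm: float = DEFAULT_TOL_PPM
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    max_missed: int = 0
    mns45_extended: bool = False
    max_glc: int = 1  # glucosylation bound for isomer inference
    outdir: str = "glycotrim_out"
    verbosity: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValidationError("tol_ppm must be > 0")
        if self.max_missed < 0 or self.max_glc < 0:
            raise ValidationError("max_missed and max_glc must be >= 0")
        self.ranges = {k: tuple(v) for k, v in self.ranges.items()}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise InputError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> None:
        for name in self.__dataclass_fields__:
            log.info("config %s = %r", name, getattr(self, name))


# ---------------------------------------------------------------------------
# shared readers / writers
# ---------------------------------------------------------------------------

PEAKLIST_HEADER = ["neutral_mass_da", "intensity"]


def read_fasta(path) -> list[ProteinRecord]:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise InputError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    try:
        return [ProteinRecord(r.id, str(r.seq).upper()) for r in records]
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def read_peaklist(path, sample: str = "", site: str = "") -> PeakList:
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise InputError(f"cannot read peak list {path}: {exc}") from exc
    except Exception as exc:
        raise ValidationError(f"malformed peak list {path}: {exc}") from exc
    if list(df.columns[:2]) != PEAKLIST_HEADER:
        raise ValidationError(
            f"peak list {path} must have header {PEAKLIST_HEADER!r}, "
            f"got {list(df.columns[:2])!r}")
    try:
        return PeakList(df[PEAKLIST_HEADER[0]].to_numpy(float),
                        df[PEAKLIST_HEADER[1]].to_numpy(float),
                        sample=sample, site=site)
    except ValueError as exc:
        raise ValidationError(f"invalid peak list {path}: {exc}") from exc


def write_peaklist(peaks: PeakList, path) -> None:
    pd.DataFrame({PEAKLIST_HEADER[0]: peaks.masses,
                  PEAKLIST_HEADER[1]: peaks.intensities}).to_csv(
        path, sep="\t", index=False)


def assignments_frame(assignments: list[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_index": [a.peak_index for a in assignments],
            "neutral_mass_da": [a.peak_mass for a in assignments],
            "intensity": [a.intensity for a in assignments],
            "peptide": [a.candidate.peptide.sequence for a in assignments],
            "composition": [a.candidate.glycan.label for a in assignments],
            "theoretical_mass_da": [a.candidate.neutral_mass for a in assignments],
            "ppm_error": [a.ppm_error for a in assignments],
        }
    )


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeaklistInput:
    path: str
    site: str
    sample: str
    peptide: str


def run_pipeline(config: PipelineConfig, fasta_path,
                 peaklists: list[PeaklistInput]) -> dict[str, Path]:
    """Annotate, quantify and structurally interpret each site's peak list.

    Writes per-site assignment TSVs, the glycoform table, an isomer-inference
    TSV and returns the paths.  Raises :class:`InputError` /
    :class:`ValidationError` for the two failure classes.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    config.echo()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteins = read_fasta(fasta_path)
    sequons = {p.id: find_sequons(p) for p in proteins}
    if not any(sequons.values()):
        raise ValidationError(f"no N-glycosylation sequon in {fasta_path}")
    peptides = {p.id: tryptic_digest(p, config.max_missed) for p in proteins}

    compositions = enumerate_glycoforms(config.ranges)
    outputs: dict[str, Path] = {}
    columns: dict[str, pd.Series] = {}
    observed_comps: set[str] = set()

    for item in peaklists:
        backbone = item.peptide.upper()
        hits = [
            (p, s)
            for p in proteins
            for pep in peptides[p.id]
            if pep.sequence == backbone
            for s in sequons[p.id]
            if pep.start <= s.position <= pep.end
        ]
        if not hits:
            raise ValidationError(
                f"peptide {backbone} is not a tryptic peptide carrying a sequon "
                f"in {fasta_path}")
        n_seq = len({s.position for _, s in hits})
        if n_seq > 1:
            log.warning("peptide %s carries %d sequons; composition is reported "
                        "per peptide, not per site", backbone, n_seq)
        peaks = read_peaklist(item.path, sample=item.sample, site=item.site)
        cands = theoretical_masses(backbone, compositions)
        assigned = match_peaks(peaks, cands, config.tol_ppm)
        log.info("%s/%s: %d peaks, %d assigned", item.site, item.sample,
                 len(peaks), len(assigned))
        frame = assignments_frame(assigned)
        apath = outdir / f"assignments_{item.site}_{item.sample}.tsv"
        frame.to_csv(apath, sep="\t", index=False)
        outputs[f"assignments:{item.site}:{item.sample}"] = apath
        col = f"{item.site}_{item.sample}"
        columns[col] = quantify.quantify_site(assigned)
        observed_comps.update(columns[col].index)

    # isomer inference for the observed oligomannosidic compositions
    inference_rows = []
    annotations: dict[str, dict[str, str]] = {c: {} for c in columns}
    for label in sorted(observed_comps):
        comp = GlycanComposition.from_label(label)
        if comp.hexnac != 2 or comp.dhex or comp.pent:
            continue
        result = enzymes.infer_isomer(comp, max_glc=config.max_glc)
        for rank, cand in enumerate(result, start=1):
            inference_rows.append(
                {"composition": label, "rank": rank, "structure": cand.name,
                 "glc_count": cand.glc_count, "jbm_limit": cand.jbm_limit.label,
                 "endoM_sensitive": cand.endoM_sensitive,
                 "evidence": "; ".join(cand.evidence)})
        if len(result) and result.candidates[0].glc_count >= 1:
            for col in annotations:
                annotations[col][label] = result.candidates[0].name
    ipath = outdir / "isomer_inference.tsv"
    pd.DataFrame(inference_rows).to_csv(ipath, sep="\t", index=False)
    outputs["inference"] = ipath

    table = quantify.GlycoformTable.from_columns(columns, annotations)
    tpath = outdir / "glycoform_table.tsv"
    quantify.write_report(table, tpath)
    outputs["table"] = tpath
    return outputs
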