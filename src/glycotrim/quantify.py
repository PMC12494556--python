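"""Site-specific relative glycoform quantification.

Relative abundance of a glycoform at one site is its assigned deconvoluted
peak intensity divided by the summed intensity of all assigned glycoforms at
that site, in percent.  Unassigned (decoy/contaminant) peaks never enter the
denominator, so each site column sums to exactly 100.  Isomer annotations
(e.g. Hex8HexNAc2 -> Glc1Man7GlcNAc2) attach tree-level structure calls from
the enzyme engine to MS-level composition rows, which is what turns a
composition table into a monoglucosylation statement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .enzymes import NotASubstrate
from .glycan import GlycanComposition, build_canonical
from .proteomics import Assignment


class EmptySiteError(ValueError):
    """No assignments (or no positive intensity) for a site."""


class TableFormatError(ValueError):
    """Malformed glycoform-table TSV."""


def _composition_sort_key(label: str):
    c = GlycanComposition.from_label(label)
    return (c.hexnac + c.hex + c.dhex + c.pent, c.hex, c.hexnac, c.dhex, c.pent)


def quantify_site(assignments: list[Assignment]) -> pd.Series:
    """Relative amounts (%) per composition label from assigned intensities.

    Multiple peaks assigned to the same composition are summed before
    normalization.  Raises :class:`EmptySiteError` without assignments.
    """
    if not assignments:
        raise EmptySiteError("no assignments for this site")
    totals: dict[str, float] = {}
    for a in assignments:
        label = a.candidate.glycan.label
        totals[label] = totals.get(label, 0.0) + a.intensity
    denom = sum(totals.values())
    if denom <= 0:
        raise EmptySiteError("assigned intensities sum to zero")
    labels = sorted(totals, key=_composition_sort_key)
    return pd.Series({lab: 100.0 * totals[lab] / denom for lab in labels},
                     name="relative_amount")


@dataclass
class GlycoformTable:
    """Rows = composition labels, columns = ``site<k>_<sample>``; cells = %.

    ``annotations`` maps column -> {composition label -> structure name} with
    structure names resolvable by the glycan registry.
    """

    data: pd.DataFrame
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_columns(cls, columns: dict[str, pd.Series],
                     annotations: dict[str, dict[str, str]] | None = None) -> "GlycoformTable":
        df = pd.DataFrame(columns).fillna(0.0)
        df = df.loc[sorted(df.index, key=_composition_sort_key)]
        df = df[sorted(df.columns)]
        df.index.name = "composition"
        return cls(df, annotations or {})

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def monoglucosylated_composition(self, column: str) -> str:
        """The one composition annotated with a Glc1 structure in ``column``."""
        ann = self.annotations.get(column, {})
        mono = []
        for comp_label, structure in ann.items():
            try:
                tree = build_canonical(structure)
            except Exception as exc:
                raise KeyError(
                    f"column {column!r}: annotation {structure!r} not in registry"
                ) from exc
            if len(tree.find(sugar="Glc")) == 1:
                mono.append(comp_label)
        if len(mono) != 1:
            raise KeyError(
                f"column {column!r} must have exactly one monoglucosylated "
                f"annotation, found {mono or 'none'}"
            )
        return mono[0]


def monoglucosylated_fraction(table: GlycoformTable, columns: list[str]) -> float:
    """Mean relative amount (%) of the monoglucosylated glycoform over columns."""
    if not columns:
        raise ValueError("no columns selected")
    vals = []
    for col in columns:
        if col not in table.data.columns:
            raise KeyError(f"unknown column {col!r}")
        comp = table.monoglucosylated_composition(col)
        vals.append(float(table.data.at[comp, col]) if comp in table.data.index else 0.0)
    return sum(vals) / len(vals)


def write_report(table: GlycoformTable, path) -> None:
    """TSV with a leading ``composition`` column and a ``total`` footer row.

    Percentages are written to one decimal place (internal precision is kept
    by the in-memory table, not the report).
    """
    df = table.data.copy()
    df.loc["total"] = df.sum(axis=0)
    df.round(1).to_csv(path, sep="\t", float_format="%.1f")


def read_table(path) -> GlycoformTable:
    """Read a report TSV back; warns on columns not summing to 100 +/- 0.5."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise TableFormatError(f"cannot read glycoform table {path}: {exc}") from exc
    if df.index.name != "composition" or df.empty:
        raise TableFormatError(
            f"glycoform table {path} must have a leading 'composition' column")
    df = df.drop(index="total", errors="ignore").astype(float)
    for lab in df.index:
        GlycanComposition.from_label(str(lab))  # raises on malformed rows
    for col, s in df.sum(axis=0).items():
        if abs(s - 100.0) > 0.5:
            warnings.warn(f"column {col} sums to {s:.2f}, expected 100±0.5")
    # deterministic order: site ascending, then sample/genotype lexicographic
    return GlycoformTable(df[sorted(df.columns)])
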