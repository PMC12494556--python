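"""Glycopeptide-centric proteomics: sequons, tryptic digestion, theoretical
glycopeptide masses and ppm-tolerance annotation of deconvoluted peak lists.

Input spectra are deconvoluted neutral monoisotopic masses (Da), not m/z;
charge-state deconvolution happens upstream of this package.  Glycopeptides
are recognised by the characteristic ladder of hexose-spaced mass shifts on a
common peptide backbone, then assigned to enumerated HexNAc/Hex/dHex/Pent
compositions within a ppm tolerance.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from . import masses
from .glycan import GlycanComposition

SEQUON_RE = re.compile(r"N(?=[^P][ST])")
CLEAVAGE_RE = re.compile(r"[KR](?!P)")

#: default annotation tolerance for Orbitrap-class deconvoluted masses
DEFAULT_TOL_PPM = 10.0
#: default glycoform enumeration bounds per monosaccharide class
DEFAULT_RANGES = {"hexnac": (1, 2), "hex": (0, 12), "dhex": (0, 1), "pent": (0, 1)}


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = set(self.sequence) - masses.STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue(s) in {self.id}: {sorted(bad)}")


@dataclass(frozen=True)
class Sequon:
    position: int  # 1-based Asn position
    motif: str  # the three-residue N-X-S/T window


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int = 1  # 1-based inclusive coordinates in the parent protein
    end: int = 0
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)

    @property
    def mass(self) -> float:
        return peptide_mass(self)


@dataclass(frozen=True)
class GlycopeptideCandidate:
    peptide: Peptide
    glycan: GlycanComposition
    neutral_mass: float

    @property
    def label(self) -> str:
        return f"{self.peptide.sequence}+{self.glycan.label}"


@dataclass(frozen=True)
class PeakList:
    """Deconvoluted (neutral mass, intensity) pairs, sorted ascending by mass."""

    masses: np.ndarray
    intensities: np.ndarray
    sample: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if m.shape != i.shape or m.ndim != 1:
            raise ValueError("masses and intensities must be 1-D and equally long")
        if np.any(m <= 0) or np.any(i < 0):
            raise ValueError("masses must be positive and intensities non-negative")
        order = np.argsort(m, kind="stable")
        object.__setattr__(self, "masses", m[order])
        object.__setattr__(self, "intensities", i[order])

    def __len__(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class Assignment:
    peak_index: int
    peak_mass: float
    intensity: float
    candidate: GlycopeptideCandidate
    ppm_error: float


@dataclass(frozen=True)
class LadderHypothesis:
    base_mass: float
    peak_indices: tuple[int, ...]


# ---------------------------------------------------------------------------


def find_sequons(protein: ProteinRecord) -> list[Sequon]:
    """All N-X-S/T sequons (X != P), 1-based, ascending; overlaps included."""
    seq = protein.sequence
    return [Sequon(m.start() + 1, seq[m.start():m.start() + 3])
            for m in SEQUON_RE.finditer(seq)]


def tryptic_digest(protein: ProteinRecord | str, max_missed: int = 0) -> list[Peptide]:
    """In-silico trypsin digest: cleave after K/R unless followed by P.

    Emits every peptide with at most ``max_missed`` internal cleavage sites,
    ordered by start position then length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    cuts = [0] + [m.end() for m in CLEAVAGE_RE.finditer(seq) if m.end() < len(seq)]
    cuts.append(len(seq))
    out = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            out.append(Peptide(seq[cuts[i]:cuts[j]], start=cuts[i] + 1,
                               end=cuts[j], missed_cleavages=j - i - 1))
    return out


def peptide_mass(peptide: Peptide | str) -> float:
    """Neutral monoisotopic mass; Cys carries fixed carbamidomethylation."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    return masses.peptide_monoisotopic_mass(seq)


def enumerate_glycoforms(
    ranges: dict[str, tuple[int, int]] | None = None,
) -> list[GlycanComposition]:
    """Cartesian product of per-class count ranges, deterministic order.

    Compositions without any HexNAc are dropped: an N-glycan remnant always
    retains at least the innermost GlcNAc.
    """
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for cls, (lo, hi) in r.items():
        if lo > hi or lo < 0:
            raise ValueError(f"invalid range for {cls}: {lo}..{hi}")
    out = []
    for hexnac, hexose, dhex, pent in itertools.product(
        range(r["hexnac"][0], r["hexnac"][1] + 1),
        range(r["hex"][0], r["hex"][1] + 1),
        range(r["dhex"][0], r["dhex"][1] + 1),
        range(r["pent"][0], r["pent"][1] + 1),
    ):
        if hexnac == 0:
            continue
        out.append(GlycanComposition(hexnac=hexnac, hex=hexose, dhex=dhex, pent=pent))
    return out


def theoretical_masses(
    peptide: Peptide | str, compositions: list[GlycanComposition]
) -> list[GlycopeptideCandidate]:
    """One glycopeptide candidate per composition on the given backbone."""
    pep = peptide if isinstance(peptide, Peptide) else Peptide(peptide)
    base = peptide_mass(pep)
    return [GlycopeptideCandidate(pep, comp, base + comp.mass()) for comp in compositions]


def match_peaks(
    peaks: PeakList,
    candidates: list[GlycopeptideCandidate],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[Assignment]:
    """Assign peaks to candidates within a ppm tolerance.

    Each peak goes to the candidate with the smallest absolute ppm error
    (ties to the lower candidate mass); each candidate is used at most once,
    keeping its best peak.  Peaks that lose a candidate are left unassigned
    rather than rerouted, which keeps the mapping order-independent.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if not candidates or not len(peaks):
        return []
    cand = sorted(candidates, key=lambda c: c.neutral_mass)
    cmasses = np.array([c.neutral_mass for c in cand])
    best_for_candidate: dict[int, Assignment] = {}
    for idx, (pm, inten) in enumerate(zip(peaks.masses, peaks.intensities)):
        pos = int(np.searchsorted(cmasses, pm))
        choices = [j for j in (pos - 1, pos) if 0 <= j < len(cand)]
        best_j, best_abs = None, None
        for j in choices:
            ppm = (pm - cmasses[j]) / cmasses[j] * 1e6
            if abs(ppm) > tol_ppm:
                continue
            # strict < keeps the lower-mass candidate on exact ties
            if best_abs is None or abs(ppm) < best_abs:
                best_j, best_abs = j, abs(ppm)
        if best_j is None:
            continue
        ppm = (pm - cmasses[best_j]) / cmasses[best_j] * 1e6
        a = Assignment(idx, float(pm), float(inten), cand[best_j], float(ppm))
        held = best_for_candidate.get(best_j)
        if held is None or abs(a.ppm_error) < abs(held.ppm_error):
            best_for_candidate[best_j] = a
    return sorted(best_for_candidate.values(), key=lambda a: a.peak_index)


def detect_hexose_ladder(
    peaks: PeakList,
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_chain: int = 3,
    max_gap: int = 1,
) -> list[LadderHypothesis]:
    """Find maximal chains of peaks spaced by one hexose (162.0528 Da).

    Consecutive members may skip up to ``max_gap`` missing rungs.  Chains are
    grown greedily from the lowest unused peak, preferring the nearest rung;
    chains shorter than ``min_chain`` members are discarded.
    """
    if min_chain < 2:
        raise ValueError("min_chain must be >= 2")
    used: set[int] = set()
    out: list[LadderHypothesis] = []
    pm = peaks.masses
    for start in range(len(pm)):
        if start in used:
            continue
        chain = [start]
        cur = start
        while True:
            nxt = None
            for k in range(1, max_gap + 2):
                target = pm[cur] + k * masses.HEX
                tol = target * tol_ppm * 1e-6
                cands = [j for j in range(cur + 1, len(pm))
                         if j not in used and abs(pm[j] - target) <= tol]
                if cands:
                    nxt = min(cands, key=lambda j: abs(pm[j] - target))
                    break
            if nxt is None:
                break
            chain.append(nxt)
            cur = nxt
        if len(chain) >= min_chain:
            used.update(chain)
            out.append(LadderHypothesis(float(pm[chain[0]]), tuple(chain)))
    return out
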