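"""Seeded generator of deconvoluted glycopeptide spectra with ground truth.

Emulates the observable properties of deconvoluted LC-ESI-MS spectra of
tryptic glycopeptides: one neutral-mass peak per glycoform at its theoretical
monoisotopic mass perturbed by ppm-scale normal error, lognormal intensity
noise around the true glycoform proportions, and decoy peaks placed away from
every theoretical candidate mass.  It deliberately does not model
chromatography, isotope envelopes or charge states - those are removed by the
upstream deconvolution this package assumes.

A single pseudo-random stream per spectrum, seeded from the spec, with a
fixed draw order (mass errors, then intensities, then decoys) makes outputs
byte-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .enzymes import RULES, NotASubstrate, jbm_digest
from .glycan import GlycanComposition, GlycanTree
from .proteomics import (
    DEFAULT_RANGES,
    GlycopeptideCandidate,
    PeakList,
    enumerate_glycoforms,
    theoretical_masses,
)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one synthetic glycopeptide spectrum."""

    peptide: str
    proportions: dict  # composition label or GlycanComposition -> fraction
    site: str = "site2"
    sample: str = "synthetic"
    total_intensity: float = 1e7
    ppm_sd: float = 3.0
    intensity_cv: float = 0.2
    n_decoys: int = 25
    decoy_window: tuple[float, float] = (-200.0, 200.0)  # Da around the glycoform span
    decoy_min_ppm: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_sd < 0 or self.intensity_cv < 0 or self.n_decoys < 0:
            raise ValueError("ppm_sd, intensity_cv and n_decoys must be >= 0")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"glycoform proportions sum to {total}, expected 1")

    def compositions(self) -> list[GlycanComposition]:
        out = []
        for key in self.proportions:
            out.append(key if isinstance(key, GlycanComposition)
                       else GlycanComposition.from_label(key))
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Per-peak provenance aligned with the generated PeakList."""

    provenance: tuple[str, ...]  # composition label, or "decoy"
    proportions: dict  # composition label -> true fraction

    def true_peaks(self) -> list[int]:
        return [i for i, p in enumerate(self.provenance) if p != "decoy"]


class DecoyPlacementError(RuntimeError):
    """Could not place a decoy outside the ppm exclusion zones."""


def simulate_spectrum(spec: SimulationSpec) -> tuple[PeakList, GroundTruth]:
    """Generate one deconvoluted spectrum and its ground truth.

    Decoy peaks are drawn uniformly in the window around the glycoform mass
    span and rejected (bounded retries) while within ``decoy_min_ppm`` of any
    theoretical mass of the *default enumeration* on this backbone, so decoys
    are unassignable at tolerances below that offset.
    """
    rng = np.random.default_rng(spec.seed)
    comps = spec.compositions()
    fractions = np.array(list(spec.proportions.values()), dtype=float)
    cands = theoretical_masses(spec.peptide, comps)
    theo = np.array([c.neutral_mass for c in cands])

    # 1) mass errors
    eps = rng.normal(0.0, spec.ppm_sd * 1e-6, size=len(theo)) if spec.ppm_sd else np.zeros(len(theo))
    obs_masses = theo * (1.0 + eps)
    # 2) intensities (lognormal, unit mean, given cv)
    if spec.intensity_cv > 0:
        sigma = math.sqrt(math.log1p(spec.intensity_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(theo))
    else:
        noise = np.ones(len(theo))
    intensities = spec.total_intensity * fractions * noise
    # 3) decoys, excluded around every default-enumeration theoretical mass
    exclusion = np.array(
        [c.neutral_mass for c in theoretical_masses(spec.peptide, enumerate_glycoforms())]
    )
    lo = theo.min() + spec.decoy_window[0]
    hi = theo.max() + spec.decoy_window[1]
    median_int = float(np.median(intensities)) if len(intensities) else 1.0
    decoy_masses, decoy_ints = [], []
    for _ in range(spec.n_decoys):
        for _attempt in range(1000):
            m = rng.uniform(lo, hi)
            if np.min(np.abs(m - exclusion) / exclusion) * 1e6 >= spec.decoy_min_ppm:
                decoy_masses.append(m)
                decoy_ints.append(0.2 * median_int * rng.uniform(0.1, 1.0))
                break
        else:
            raise DecoyPlacementError(
                f"no decoy position found in [{lo:.1f}, {hi:.1f}] outside "
                f"{spec.decoy_min_ppm} ppm of {len(exclusion)} theoretical masses")

    all_masses = np.concatenate([obs_masses, np.array(decoy_masses)])
    all_ints = np.concatenate([intensities, np.array(decoy_ints)])
    prov = [c.label for c in comps] + ["decoy"] * len(decoy_masses)
    order = np.argsort(all_masses, kind="stable")
    peaks = PeakList(all_masses[order], all_ints[order], sample=spec.sample, site=spec.site)
    truth = GroundTruth(
        provenance=tuple(prov[i] for i in order),
        proportions={c.label: float(f) for c, f in zip(comps, fractions)},
    )
    return peaks, truth


def simulate_digestion_series(
    structure: GlycanTree,
    enzymes: list[str],
    iteration_weights: dict[int | str, float],
    total_intensity: float = 1e6,
) -> PeakList:
    """Released-glycan spectrum of a partial exoglycosidase digestion.

    ``enzymes`` are applied in order; all but the last run to completion
    (single application for single-site rules), the last - JBM-style
    iterative trimming - is sampled at the requested iteration depths.
    ``iteration_weights`` maps an iteration count (or ``"limit"``) to the
    fraction of material digested that far; the product composition of each
    depth is reported at its *released* (free reducing glycan) neutral mass.
    """
    if not enzymes:
        raise ValueError("enzyme sequence must not be empty")
    for name in enzymes:
        if name not in RULES and name != "JBM":
            raise ValueError(f"unknown enzyme {name!r}")
    total = sum(iteration_weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"iteration weights sum to {total}, expected 1")

    tree = structure
    for name in enzymes[:-1]:
        tree = RULES[name].apply(tree).product
    last = enzymes[-1]

    peak_map: dict[float, float] = {}
    for depth, weight in iteration_weights.items():
        if last == "JBM":
            iters = None if depth == "limit" else int(depth)
            product = jbm_digest(tree, iterations=iters).product
        else:
            product = RULES[last].apply(tree).product if depth != 0 else tree
        mass = product.composition().mass(released=True)
        peak_map[mass] = peak_map.get(mass, 0.0) + total_intensity * weight
    masses = np.array(sorted(peak_map))
    return PeakList(masses, np.array([peak_map[m] for m in masses]),
                    sample="digest", site="released")
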