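"""Shared fixtures and the independent mass oracle.

The oracle computes peptide and monosaccharide masses from a hand-frozen
atomic-mass table and residue formulas, independently of the pyteomics path
used by the implementation.
"""

from __future__ import annotations

import pytest

# NIST monoisotopic atomic masses, frozen here independently of pyteomics
ATOMIC = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
          "O": 15.9949146221, "S": 31.97207069}

AA_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}

SUGAR_FORMULAS = {"Hex": "C6H10O5", "HexNAc": "C8H13NO5",
                  "dHex": "C6H10O4", "Pent": "C5H8O4"}


def formula_mass(formula: str) -> float:
    import re

    out = 0.0
    for elem, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if elem:
            out += ATOMIC[elem] * (int(count) if count else 1)
    return out


def oracle_peptide_mass(sequence: str) -> float:
    """Residue-formula summation + water + carbamidomethyl per Cys."""
    water = formula_mass("H2O")
    cam = formula_mass("C2H3NO")
    return (sum(formula_mass(AA_FORMULAS[a]) for a in sequence)
            + water + cam * sequence.count("C"))


def oracle_sugar_mass(name: str) -> float:
    return formula_mass(SUGAR_FORMULAS[name])


@pytest.fixture(scope="session")
def registry():
    from glycotrim import build_canonical, registry_names

    return {name: build_canonical(name) for name in registry_names()}


@pytest.fixture(scope="session")
def default_candidates():
    """Theoretical glycopeptide masses on the worked-example backbone."""
    from glycotrim import enumerate_glycoforms, theoretical_masses

    return theoretical_masses("NLSLSSNR", enumerate_glycoforms())


#: measured site-1 os9 relative amounts (%), normalized to generator fractions
_OS9_SITE1_PERCENT = {
    "HexNAc1": 3.1, "Hex2HexNAc2": 0.3, "Hex3HexNAc2": 0.6,
    "Hex4HexNAc2": 1.3, "Hex5HexNAc2": 1.6, "Hex6HexNAc2": 2.6,
    "Hex7HexNAc2": 16.4, "Hex8HexNAc2": 63.7, "Hex9HexNAc2": 5.0,
    "Hex10HexNAc2": 5.5,
}
_total = sum(_OS9_SITE1_PERCENT.values())
OS9_SITE1_PROPORTIONS = {k: v / _total for k, v in _OS9_SITE1_PERCENT.items()}
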