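"""Shared fixtures and the independent elemental-composition mass oracle.

The oracle computes residue masses by summing element monoisotopic masses
over per-residue chemical formulas — a path entirely independent of the
package's residue tables.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

import glycotarget as gt

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# monoisotopic element masses (CODATA/AME-derived, standard values)
ELEMENTS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# residue (dehydrated) formulas of the 20 canonical amino acids
AA_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}

# dehydrated monosaccharide residue formulas
SUGAR_FORMULAS = {
    "HexNAc": "C8H13NO5",
    "Hex": "C6H10O5",
    "Fuc": "C6H10O4",
    "NeuAc": "C11H17NO8",
    "Acetyl": "C2H2O",
}


def formula_mass(formula: str) -> float:
    """Sum element masses of a Hill-style formula like ``C6H12N2O``."""
    import re

    mass = 0.0
    for sym, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not sym:
            continue
        mass += ELEMENTS[sym] * (int(count) if count else 1)
    return mass


def oracle_peptide_mass(sequence: str, cys_mod: bool = True) -> float:
    """Independent peptide monoisotopic mass from elemental formulas."""
    mass = formula_mass("H2O")
    for aa in sequence:
        mass += formula_mass(AA_FORMULAS[aa])
        if cys_mod and aa == "C":
            mass += formula_mass("C2H3NO")  # carbamidomethyl
    return mass


@pytest.fixture(scope="session")
def epo_sequence() -> str:
    return gt.load_epo_mature()


@pytest.fixture(scope="session")
def target_transition() -> gt.TransitionEntry:
    return gt.target_transition()


@pytest.fixture(scope="session")
def target_glycopeptide() -> gt.Glycopeptide:
    pep = gt.Peptide(sequence="HCSLNENITVPDTK", start=32, end=45, missed_cleavages=2)
    return gt.Glycopeptide(pep, gt.parse_glycan_composition("_6_7_1_4"), site=38)
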