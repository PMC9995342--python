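"""Monoisotopic mass arithmetic for peptides, glycans and glycopeptides.

All masses are monoisotopic and in daltons.  Glycan compositions are counts
of dehydrated monosaccharide residue classes (HexNAc, Hex, Fuc, NeuAc plus
an optional O-acetyl), so the mass of an attached glycan is a plain sum of
residue masses with no extra water.  Two text notations are supported:

* parenthesized: ``HexNAc(6)Hex(7)Fuc(1)NeuAc(4)``
* underscore suffix: ``_6_7_1_4`` (digit order HexNAc, Hex, Fuc, NeuAc, as
  appended to a peptide sequence, e.g. ``HCSLNENITVPDTK_6_7_1_4``)

The underscore digit order follows the composition-table convention
(HexNAc first); it is the only reading consistent with the published
precursor m/z of the tetra-sialylated erythropoietin target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "WATER",
    "PROTON",
    "C13_MINUS_C12",
    "AMINO_ACID_RESIDUE_MASSES",
    "MONOSACCHARIDE_RESIDUE_MASSES",
    "CARBAMIDOMETHYL",
    "DEFAULT_FIXED_MODS",
    "GlycanComposition",
    "Peptide",
    "Glycopeptide",
    "peptide_monoisotopic_mass",
    "parse_glycan_composition",
    "glycan_mass",
    "glycopeptide_mass",
    "glycopeptide_mz",
]

WATER = 18.010565
PROTON = 1.007276
#: mass difference between one 13C and one 12C; isotopologue spacing at z=1
C13_MINUS_C12 = 1.003355

#: monoisotopic residue (dehydrated) masses of the 20 canonical amino acids
AMINO_ACID_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: monoisotopic residue masses of the monosaccharide classes
MONOSACCHARIDE_RESIDUE_MASSES: dict[str, float] = {
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "Fuc": 146.057909,
    "NeuAc": 291.095417,
    "Acetyl": 42.010565,
}

#: monosaccharide classes in canonical (underscore-notation) order
MONOSACCHARIDE_ORDER = ("HexNAc", "Hex", "Fuc", "NeuAc", "Acetyl")

#: carbamidomethylation (chloroacetamide alkylation of Cys), fixed by default
CARBAMIDOMETHYL = 57.021464
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}

_PAREN_TOKEN = re.compile(r"([A-Za-z]+)\((\-?\d+)\)")


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide residue classes on one glycan."""

    counts: tuple[tuple[str, int], ...] = ()

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "GlycanComposition":
        clean = {}
        for k, v in counts.items():
            if k not in MONOSACCHARIDE_RESIDUE_MASSES:
                raise ValueError(f"unknown monosaccharide class {k!r}")
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValueError(f"count for {k} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"count for {k} must be >= 0, got {v}")
            if v:
                clean[k] = v
        return cls(tuple((k, clean[k]) for k in MONOSACCHARIDE_ORDER if k in clean))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, key: str) -> int:
        return dict(self.counts).get(key, 0)

    def total_residues(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def mass(self) -> float:
        return glycan_mass(self)

    def to_parenthesized(self) -> str:
        return "".join(f"{k}({n})" for k, n in self.counts)

    def to_underscore(self) -> str:
        d = self.as_dict()
        if d.get("Acetyl"):
            raise ValueError("underscore notation has no digit position for Acetyl")
        return "".join(f"_{d.get(k, 0)}" for k in MONOSACCHARIDE_ORDER[:4])

    def __str__(self) -> str:  # canonical form
        return self.to_parenthesized()


def parse_glycan_composition(text: str) -> GlycanComposition:
    """Parse either notation into a :class:`GlycanComposition`.

    Underscore notation maps digit positions to (HexNAc, Hex, Fuc, NeuAc).
    A peptide-suffixed name like ``HCSLNENITVPDTK_6_7_1_4`` is accepted; only
    the numeric suffix is read.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty glycan composition string")
    if "(" in text:
        tokens = _PAREN_TOKEN.findall(text)
        if "".join(f"{k}({n})" for k, n in tokens) != text.replace(" ", ""):
            raise ValueError(f"malformed glycan composition {text!r}")
        counts: dict[str, int] = {}
        for name, num in tokens:
            if name not in MONOSACCHARIDE_RESIDUE_MASSES:
                raise ValueError(f"unknown monosaccharide class {name!r} in {text!r}")
            n = int(num)
            if n < 0:
                raise ValueError(f"negative count for {name} in {text!r}")
            counts[name] = counts.get(name, 0) + n
        return GlycanComposition.from_dict(counts)
    # underscore notation, possibly with a leading peptide sequence
    m = re.search(r"(?:^|[A-Z\]])((?:_\d+){4})$", text) or re.fullmatch(r"((?:_\d+){4})", text)
    if not m:
        raise ValueError(f"malformed underscore glycan notation {text!r}")
    digits = [int(x) for x in m.group(1).split("_")[1:]]
    return GlycanComposition.from_dict(dict(zip(MONOSACCHARIDE_ORDER[:4], digits)))


def glycan_mass(g: GlycanComposition) -> float:
    """Mass of an attached glycan: sum of dehydrated residue masses."""
    return sum(n * MONOSACCHARIDE_RESIDUE_MASSES[k] for k, n in g.counts)


@dataclass(frozen=True)
class Peptide:
    """A fully specific proteolytic peptide with fixed modifications.

    ``start``/``end`` are 1-based inclusive coordinates in the parent
    protein (0 when the peptide is free-standing).
    """

    sequence: str
    fixed_mods: tuple[tuple[str, float], ...] = tuple(DEFAULT_FIXED_MODS.items())
    start: int = 0
    end: int = 0
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in AMINO_ACID_RESIDUE_MASSES:
                raise ValueError(
                    f"unknown residue symbol {aa!r} at position {i + 1} in {self.sequence!r}"
                )
        if self.start and self.end and self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}..{self.end} inconsistent with "
                f"length {len(self.sequence)}"
            )

    @property
    def mass(self) -> float:
        return peptide_monoisotopic_mass(self)

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def peptide_monoisotopic_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass: residue sum + water + fixed modifications."""
    mods = dict(peptide.fixed_mods)
    mass = WATER
    for aa in peptide.sequence:
        mass += AMINO_ACID_RESIDUE_MASSES[aa] + mods.get(aa, 0.0)
    return mass


@dataclass(frozen=True)
class Glycopeptide:
    """Peptide + glycan composition attached at one Asn of a sequon."""

    peptide: Peptide
    glycan: GlycanComposition
    site: int = 0  # 1-based protein position of the glycosylated Asn; 0 if unknown

    def __post_init__(self) -> None:
        if self.site:
            if not self.peptide.covers(self.site):
                raise ValueError(
                    f"glycosite {self.site} outside peptide "
                    f"{self.peptide.start}..{self.peptide.end}"
                )
            idx = self.site - self.peptide.start
            if self.peptide.sequence[idx] != "N":
                raise ValueError(f"residue at site {self.site} is not Asn")

    @property
    def mass(self) -> float:
        return glycopeptide_mass(self)

    @property
    def name(self) -> str:
        try:
            suffix = self.glycan.to_underscore()
        except ValueError:
            suffix = "_" + self.glycan.to_parenthesized()
        return self.peptide.sequence + suffix


def glycopeptide_mass(gp: Glycopeptide) -> float:
    """Neutral mass; additive in the peptide and glycan masses."""
    return peptide_monoisotopic_mass(gp.peptide) + glycan_mass(gp.glycan)


def glycopeptide_mz(gp: Glycopeptide, charge: int, isotopologue: int = 0) -> float:
    """m/z of a chosen isotopologue of ``[M + charge*H]^charge+``.

    ``isotopologue`` counts 13C substitutions: 0 is monoisotopic, 2 is the
    M+2 peak.  SIM assays frequently monitor a higher isotopologue of large
    glycopeptides because it is the most intense cluster member.
    """
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    if isotopologue < 0:
        raise ValueError(f"isotopologue index must be >= 0, got {isotopologue}")
    m = glycopeptide_mass(gp)
    return (m + isotopologue * C13_MINUS_C12 + charge * PROTON) / charge
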