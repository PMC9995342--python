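"""In-silico protease digestion and N-glycosylation sequon discovery.

The assay this package targets digests erythropoietin with Glu-C followed
by trypsin, i.e. cleavage C-terminal to E/D/R/K with up to two missed
cleavages.  Single-enzyme rules are provided as well.  Digestion is fully
specific: every emitted peptide starts and ends at a cleavage boundary (or
a protein terminus) and carries its 1-based coordinates and its
missed-cleavage count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .chem import (
    DEFAULT_FIXED_MODS,
    GlycanComposition,
    Glycopeptide,
    Peptide,
    peptide_monoisotopic_mass,
)

__all__ = [
    "EnzymeRule",
    "TRYPSIN",
    "GLU_C",
    "GLUC_TRYPSIN",
    "GlycositeAnnotation",
    "digest",
    "cleavage_boundaries",
    "find_sequons",
    "enumerate_candidates",
    "read_fasta",
    "peptides_to_frame",
    "load_epo_mature",
    "EPO_FASTA",
]

EPO_FASTA = Path(__file__).parent / "data" / "epo_mature.fasta"


@dataclass(frozen=True)
class EnzymeRule:
    """C-terminal cleavage rule with optional proline blocking."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()
    max_missed: int = 2

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def with_proline_blocking(self, on: bool) -> "EnzymeRule":
        return EnzymeRule(
            self.name,
            self.cleave_after,
            frozenset("P") if on else frozenset(),
            self.max_missed,
        )


#: trypsin: after K/R, not before P (standard convention)
TRYPSIN = EnzymeRule("trypsin", frozenset("KR"), frozenset("P"))
#: Glu-C in phosphate-type specificity: after E/D
GLU_C = EnzymeRule("glu-c", frozenset("ED"))
#: combined Glu-C + trypsin: after E/D/R/K; proline blocking on by default
GLUC_TRYPSIN = EnzymeRule("glu-c+trypsin", frozenset("EDRK"), frozenset("P"))


def cleavage_boundaries(protein: str, rule: EnzymeRule) -> list[int]:
    """0-based indices i such that the bond after residue i-1 is cut.

    Returned values are segment start positions (excluding 0 and len)."""
    cuts = []
    for i in range(len(protein) - 1):
        if protein[i] in rule.cleave_after and protein[i + 1] not in rule.blocked_by_next:
            cuts.append(i + 1)
    return cuts


def digest(
    protein: str,
    rule: EnzymeRule,
    fixed_mods: dict[str, float] | None = None,
) -> list[Peptide]:
    """All fully specific peptides with 0..``rule.max_missed`` missed cleavages.

    The zero-missed-cleavage subset partitions the protein.  Peptides are
    ordered by start position, then by missed-cleavage count.
    """
    if not protein:
        raise ValueError("protein sequence must be non-empty")
    protein = protein.upper()
    mods = tuple((fixed_mods if fixed_mods is not None else DEFAULT_FIXED_MODS).items())
    cuts = [0] + cleavage_boundaries(protein, rule) + [len(protein)]
    peptides = []
    for si in range(len(cuts) - 1):
        for mc in range(rule.max_missed + 1):
            ei = si + mc + 1
            if ei >= len(cuts):
                break
            start, end = cuts[si], cuts[ei]
            peptides.append(
                Peptide(
                    sequence=protein[start:end],
                    fixed_mods=mods,
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                )
            )
    return peptides


@dataclass(frozen=True)
class GlycositeAnnotation:
    """One N-glycosylation sequon (N-X-[S/T], X != P) in a protein."""

    protein_position: int  # 1-based Asn index
    sequon: str

    def __post_init__(self) -> None:
        if not re.fullmatch(r"N[^P][ST]", self.sequon):
            raise ValueError(f"{self.sequon!r} is not a valid N-X-[S/T] sequon")


def find_sequons(protein: str) -> list[GlycositeAnnotation]:
    """Every N-X-[S/T] motif with X != P, 1-based Asn positions."""
    protein = protein.upper()
    out = []
    for m in re.finditer(r"(?=(N[^P][ST]))", protein):
        out.append(GlycositeAnnotation(m.start() + 1, m.group(1)))
    return out


def enumerate_candidates(
    peptides: list[Peptide],
    sites: list[GlycositeAnnotation],
    glycans: list[GlycanComposition],
    on_uncovered: str = "warn",
) -> list[Glycopeptide]:
    """Cross product of site-covering peptides and glycan compositions.

    A site not covered by any peptide is reported via a warning (or raises
    with ``on_uncovered='raise'``) rather than silently dropped.
    """
    if not glycans:
        raise ValueError("glycan list must be non-empty")
    candidates = []
    for site in sites:
        covering = [p for p in peptides if p.covers(site.protein_position)]
        if not covering:
            msg = f"glycosite {site.protein_position} not covered by any peptide"
            if on_uncovered == "raise":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        for pep in covering:
            for gly in glycans:
                candidates.append(Glycopeptide(pep, gly, site.protein_position))
    return candidates


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_epo_mature() -> str:
    """The packaged 165-residue mature erythropoietin chain."""
    return next(iter(read_fasta(EPO_FASTA).values()))


def peptides_to_frame(peptides: list[Peptide]) -> pd.DataFrame:
    """Peptide table: sequence, coordinates, missed cleavages, mass."""
    return pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptides],
            "start": [p.start for p in peptides],
            "end": [p.end for p in peptides],
            "missed_cleavages": [p.missed_cleavages for p in peptides],
            "mass": [peptide_monoisotopic_mass(p) for p in peptides],
        }
    )
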