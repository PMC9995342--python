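"""Fragment-ion generation and transition (inclusion) lists.

Three fragment families are typical of N-glycopeptide HCD spectra and are
generated here: low-mass oxonium ions diagnostic of the glycan, peptide
backbone b/y ions, and the Y-ladder of glycan-cleaved glycopeptide ions
(intact peptide plus a partial glycan).  Isotopologue clusters support SIM
assays that monitor a non-monoisotopic cluster member.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .chem import (
    C13_MINUS_C12,
    MONOSACCHARIDE_RESIDUE_MASSES,
    PROTON,
    WATER,
    AMINO_ACID_RESIDUE_MASSES,
    GlycanComposition,
    Glycopeptide,
    Peptide,
    glycan_mass,
    glycopeptide_mz,
    peptide_monoisotopic_mass,
)

__all__ = [
    "FragmentIon",
    "TransitionEntry",
    "oxonium_ions",
    "backbone_ions",
    "y_ladder",
    "isotope_cluster",
    "build_transition_list",
    "write_transition_csv",
    "read_transition_csv",
    "TARGET_EXTRA_PRODUCT_MZ",
]

#: the published extra product at 658.23 whose identity is ambiguous
#: (the first 13C isotopologue of the 657.23 trisaccharide oxonium and a
#: nominal y6 candidate coincide there); offered as an optional transition.
TARGET_EXTRA_PRODUCT_MZ = 658.23


@dataclass(frozen=True)
class FragmentIon:
    """One product ion with a recomputable m/z."""

    kind: str  # oxonium | b | y | Y | precursor
    label: str
    mz: float
    charge: int = 1
    composition: GlycanComposition | None = None
    index: int | None = None  # backbone cleavage index for b/y

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


def _oxonium_mz(counts: dict[str, int], water_loss: int = 0) -> float:
    m = sum(n * MONOSACCHARIDE_RESIDUE_MASSES[k] for k, n in counts.items())
    return m - water_loss * WATER + PROTON


def oxonium_ions(g: GlycanComposition) -> list[FragmentIon]:
    """Diagnostic oxonium ions implied by a composition, singly protonated.

    Emitted: one ion per monosaccharide class present, the water-loss
    variant of NeuAc, and the di-/tri-saccharide combinations HexNAc+Hex
    and HexNAc+Hex+NeuAc when the counts allow them.
    """
    ions: list[FragmentIon] = []

    def add(label: str, counts: dict[str, int], water_loss: int = 0) -> None:
        ions.append(
            FragmentIon(
                kind="oxonium",
                label=label,
                mz=_oxonium_mz(counts, water_loss),
                composition=GlycanComposition.from_dict(counts),
            )
        )

    if g["HexNAc"]:
        add("HexNAc", {"HexNAc": 1})
    if g["Hex"]:
        add("Hex", {"Hex": 1})
    if g["Fuc"]:
        add("Fuc", {"Fuc": 1})
    if g["NeuAc"]:
        add("NeuAc", {"NeuAc": 1})
        add("NeuAc-H2O", {"NeuAc": 1}, water_loss=1)
    if g["HexNAc"] and g["Hex"]:
        add("HexNAc+Hex", {"HexNAc": 1, "Hex": 1})
    if g["HexNAc"] and g["Hex"] and g["NeuAc"]:
        add("HexNAc+Hex+NeuAc", {"HexNAc": 1, "Hex": 1, "NeuAc": 1})
    return ions


def backbone_ions(p: Peptide, series: str, charge: int = 1) -> list[FragmentIon]:
    """Full b or y ladder of the glycan-free peptide backbone.

    Convention: backbone fragments are computed on the unglycosylated
    peptide (fixed modifications included).  ``y_n`` = C-terminal n residues
    + water + n_protons; ``b_n`` = N-terminal n residues + n_protons.
    """
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    mods = dict(p.fixed_mods)
    res = [AMINO_ACID_RESIDUE_MASSES[aa] + mods.get(aa, 0.0) for aa in p.sequence]
    ions = []
    n = len(res)
    for i in range(1, n):  # fragments shorter than the full peptide
        if series == "b":
            neutral = sum(res[:i])
        else:
            neutral = sum(res[n - i:]) + WATER
        ions.append(
            FragmentIon(
                kind=series,
                label=f"{series}{i}",
                mz=(neutral + charge * PROTON) / charge,
                charge=charge,
                index=i,
            )
        )
    return ions


#: order in which residues are trimmed from the full glycan to build the
#: Y-ladder: terminal sialic acids (and their acetyls) first, then fucose,
#: then antenna hexoses and finally HexNAc, so that the ladder built up
#: from the bare peptide starts with the core GlcNAc (Y0, Y1 = +HexNAc,
#: ...).  A convention only — the detection stage matches by m/z
#: membership, not order.
_TRIM_ORDER = ("NeuAc", "Acetyl", "Fuc", "Hex", "HexNAc")


def y_ladder(gp: Glycopeptide, charge: int = 1) -> list[FragmentIon]:
    """Glycan-cleaved glycopeptide (Y) ions from bare peptide to intact.

    One residue is trimmed per step, so the ladder has total-residue-count
    + 1 entries, ordered from bare peptide upward.
    """
    pep_mass = peptide_monoisotopic_mass(gp.peptide)
    remaining = gp.glycan.as_dict()
    # build partial compositions from full down to empty, then reverse
    partials = [dict(remaining)]
    for cls in _TRIM_ORDER:
        for _ in range(remaining.get(cls, 0)):
            nxt = dict(partials[-1])
            nxt[cls] -= 1
            partials.append({k: v for k, v in nxt.items() if v > 0})
    partials.reverse()  # bare peptide first
    ions = []
    for k, counts in enumerate(partials):
        comp = GlycanComposition.from_dict(counts)
        mz = (pep_mass + glycan_mass(comp) + charge * PROTON) / charge
        label = "Y0" if not counts else f"Y:{comp.to_parenthesized()}"
        ions.append(
            FragmentIon(kind="Y", label=label, mz=mz, charge=charge, composition=comp)
        )
    return ions


#: averagine model: average residue mass 111.1254 Da containing 4.9384 C
_AVERAGINE_C_PER_DA = 4.9384 / 111.1254
#: natural abundance of 13C
_P13C = 0.0107


def isotope_cluster(mass: float, charge: int, n_peaks: int = 5) -> list[tuple[float, float]]:
    """Approximate 13C isotopologue cluster of a neutral mass.

    m/z values are spaced by 1.003355/charge; relative intensities follow a
    binomial 13C model with the carbon count estimated from an
    averagine-style rule, normalized to a maximum of 1.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    n_c = max(1, round(mass * _AVERAGINE_C_PER_DA))
    mono = (mass + charge * PROTON) / charge
    raw = []
    for k in range(n_peaks):
        if k > n_c:
            p = 0.0
        else:
            p = math.comb(n_c, k) * _P13C**k * (1 - _P13C) ** (n_c - k)
        raw.append(p)
    top = max(raw)
    return [
        (mono + k * C13_MINUS_C12 / charge, raw[k] / top) for k in range(n_peaks)
    ]


@dataclass(frozen=True)
class TransitionEntry:
    """A machine-readable SIM/PRM transition: precursor plus product ions."""

    glycopeptide: Glycopeptide
    charge: int
    monitored_isotopologue: int
    precursor_mz: float
    products: tuple[FragmentIon, ...]
    rt_window: tuple[float, float] = (0.0, 35.0)

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError("product list must be non-empty")
        expect = glycopeptide_mz(self.glycopeptide, self.charge, self.monitored_isotopologue)
        if abs(expect - self.precursor_mz) > 1e-6:
            raise ValueError(
                f"precursor m/z {self.precursor_mz} inconsistent with "
                f"glycopeptide ({expect:.6f})"
            )

    @property
    def name(self) -> str:
        return self.glycopeptide.name


def build_transition_list(
    candidates: list[Glycopeptide],
    charge: int = 4,
    monitored_isotopologue: int = 2,
    rt_window: tuple[float, float] = (0.0, 35.0),
    include_extra_658: bool = False,
) -> list[TransitionEntry]:
    """One transition per candidate; products are the computed oxonium set.

    ``monitored_isotopologue`` defaults to 2: for ~5 kDa glycopeptides the
    M+2 cluster member is the most intense and is the one a SIM method
    lists.  ``include_extra_658`` appends the published-but-ambiguous
    658.23 product.  Duplicate (name, charge) entries collapse with a
    warning.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    entries: dict[tuple[str, int], TransitionEntry] = {}
    for gp in candidates:
        key = (gp.name, charge)
        if key in entries:
            warnings.warn(f"duplicate transition for {key[0]} z={charge}; collapsed",
                          stacklevel=2)
            continue
        # the assay's diagnostic product set: single-residue HexNAc/NeuAc
        # oxonium ions plus the di-/tri-saccharide combinations (the ions a
        # sialylated N-glycopeptide method actually monitors); plain Hex and
        # Fuc oxonium ions are computed by oxonium_ions() but not monitored.
        diagnostic = {"HexNAc", "NeuAc", "NeuAc-H2O", "HexNAc+Hex", "HexNAc+Hex+NeuAc"}
        all_ions = oxonium_ions(gp.glycan)
        products = [ion for ion in all_ions if ion.label in diagnostic] or list(all_ions)
        if include_extra_658:
            products.append(
                FragmentIon(kind="oxonium", label="extra-658.23",
                            mz=TARGET_EXTRA_PRODUCT_MZ)
            )
        entries[key] = TransitionEntry(
            glycopeptide=gp,
            charge=charge,
            monitored_isotopologue=monitored_isotopologue,
            precursor_mz=glycopeptide_mz(gp, charge, monitored_isotopologue),
            products=tuple(products),
            rt_window=rt_window,
        )
    return list(entries.values())


#: minimal vendor-neutral inclusion-list schema; peptide coordinates and
#: missed-cleavage count are carried so the list round-trips losslessly
_CSV_COLUMNS = [
    "peptide", "peptide_start", "peptide_end", "missed_cleavages",
    "glycan", "site", "precursor_mz", "charge", "isotopologue",
    "rt_start", "rt_end", "product_mz", "product_labels",
]


def write_transition_csv(entries: list[TransitionEntry], path: str | Path) -> None:
    """Vendor-neutral inclusion list; floats stored at full precision."""
    rows = []
    for e in entries:
        rows.append(
            {
                "peptide": e.glycopeptide.peptide.sequence,
                "peptide_start": e.glycopeptide.peptide.start,
                "peptide_end": e.glycopeptide.peptide.end,
                "missed_cleavages": e.glycopeptide.peptide.missed_cleavages,
                "glycan": e.glycopeptide.glycan.to_parenthesized(),
                "site": e.glycopeptide.site,
                "precursor_mz": repr(e.precursor_mz),
                "charge": e.charge,
                "isotopologue": e.monitored_isotopologue,
                "rt_start": repr(e.rt_window[0]),
                "rt_end": repr(e.rt_window[1]),
                "product_mz": ";".join(repr(p.mz) for p in e.products),
                "product_labels": ";".join(p.label for p in e.products),
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_transition_csv(path: str | Path) -> list[TransitionEntry]:
    df = pd.read_csv(path, dtype=str)
    entries = []
    for _, row in df.iterrows():
        from .chem import parse_glycan_composition

        glycan = parse_glycan_composition(row["glycan"])
        pep = Peptide(
            sequence=row["peptide"],
            start=int(row["peptide_start"]),
            end=int(row["peptide_end"]),
            missed_cleavages=int(row["missed_cleavages"]),
        )
        mzs = [float(x) for x in row["product_mz"].split(";")]
        labels = row["product_labels"].split(";")
        products = tuple(
            FragmentIon(kind="oxonium", label=lab, mz=mz)
            for lab, mz in zip(labels, mzs)
        )
        entries.append(
            TransitionEntry(
                glycopeptide=Glycopeptide(pep, glycan, int(row["site"])),
                charge=int(row["charge"]),
                monitored_isotopologue=int(row["isotopologue"]),
                precursor_mz=float(row["precursor_mz"]),
                products=products,
                rt_window=(float(row["rt_start"]), float(row["rt_end"])),
            )
        )
    return entries
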