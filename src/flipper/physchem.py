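"""Per-protein physicochemical features for the first screening stage.

The screen's first filter keeps proteins whose length, isoelectric point
(pI), charged-residue content (zeta) and hydrophobic-residue content (phi)
resemble a reference linker.  Charge follows the Henderson-Hasselbalch
model per titratable group with the EMBOSS pKa set; hydropathy is the
Kyte-Doolittle scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

# Kyte & Doolittle hydropathy, range [-4.5, 4.5]
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# EMBOSS pKa values; "Nterm"/"Cterm" are the free termini
EMBOSS_PKA: Mapping[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

BASIC_GROUPS = ("K", "R", "H")
ACIDIC_GROUPS = ("D", "E", "C", "Y")

DEFAULT_PHI = frozenset("AVLIMFWY")
DEFAULT_ZETA = frozenset("DEKR")  # H excluded by default: weakly charged at pH 7


@dataclass(frozen=True)
class ResidueScales:
    """pKa, hydropathy and residue-class definitions used throughout.

    ``phi_set`` holds the hydrophobic residues, ``zeta_set`` the charged
    (electrostatic) ones; the two must be disjoint.  Histidine may be
    added to ``zeta_set`` via configuration but is out by default.
    """

    pKa: Mapping[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))
    hydropathy: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    phi_set: frozenset[str] = DEFAULT_PHI
    zeta_set: frozenset[str] = DEFAULT_ZETA

    def __post_init__(self) -> None:
        if self.phi_set & self.zeta_set:
            raise ValueError("phi_set and zeta_set must be disjoint")
        missing = set(KYTE_DOOLITTLE) - set(self.hydropathy)
        if missing:
            raise ValueError(f"hydropathy scale missing residues {sorted(missing)}")


DEFAULT_SCALES = ResidueScales()


@dataclass(frozen=True)
class PhyschemProfile:
    length: int
    pI: float
    gravy: float
    net_charge_pH7: float
    frac_phi: float
    frac_zeta: float
    composition: Mapping[str, float]


def net_charge(seq: str, pH: float, scales: ResidueScales = DEFAULT_SCALES) -> float:
    """Net charge at a given pH (elementary charges).

    Each basic group (N-terminus, K, R, H) contributes
    ``+1 / (1 + 10**(pH - pKa))`` and each acidic group (C-terminus, D, E,
    C, Y) contributes ``-1 / (1 + 10**(pKa - pH))``.  X residues are not
    titratable and contribute nothing.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    pKa = scales.pKa
    counts = {r: seq.count(r) for r in BASIC_GROUPS + ACIDIC_GROUPS}
    charge = 1.0 / (1.0 + 10.0 ** (pH - pKa["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pKa["Cterm"] - pH))
    for r in BASIC_GROUPS:
        if counts[r]:
            charge += counts[r] / (1.0 + 10.0 ** (pH - pKa[r]))
    for r in ACIDIC_GROUPS:
        if counts[r]:
            charge -= counts[r] / (1.0 + 10.0 ** (pKa[r] - pH))
    return charge


def isoelectric_point(seq: str, scales: ResidueScales = DEFAULT_SCALES,
                      tol: float = 1e-3) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The free termini guarantee one acidic and one basic group, so the
    charge is strictly decreasing in pH and the root is unique;
    ``|net_charge(seq, pI)| < tol`` on return.
    """
    lo, hi = 0.0, 14.0
    f_lo = net_charge(seq, lo, scales)
    if f_lo <= 0.0:  # cannot happen with titratable termini
        return lo
    # bisect to a fixed pH resolution well below tol; this pins the root
    # itself (not just the charge) and guarantees |net_charge| < tol
    resolution = min(tol, 1e-6)
    mid = 7.0
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, scales) > 0.0:
            lo = mid
        else:
            hi = mid
    return mid


def gravy(seq: str, scales: ResidueScales = DEFAULT_SCALES) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value); X residues
    are excluded from both numerator and denominator."""
    vals = [scales.hydropathy[c] for c in seq if c != "X"]
    if not vals:
        raise ValueError("gravy undefined for an all-X (or empty) sequence")
    return sum(vals) / len(vals)


def profile(seq: str, scales: ResidueScales = DEFAULT_SCALES) -> PhyschemProfile:
    """All physicochemical features of one sequence.

    Every feature is order-free: ``profile`` is invariant under any
    permutation of the sequence.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    comp: dict[str, float] = {}
    for c in seq:
        comp[c] = comp.get(c, 0.0) + 1.0
    comp = {c: k / n for c, k in sorted(comp.items())}
    return PhyschemProfile(
        length=n,
        pI=isoelectric_point(seq, scales),
        gravy=gravy(seq, scales),
        net_charge_pH7=net_charge(seq, 7.0, scales),
        frac_phi=sum(1 for c in seq if c in scales.phi_set) / n,
        frac_zeta=sum(1 for c in seq if c in scales.zeta_set) / n,
        composition=comp,
    )
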