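"""Sequence-level characteristics of QTY designs.

Variation rates (overall and within the TM domain), molecular weight from
average free-amino-acid masses, and the isoelectric point from a
Henderson–Hasselbalch net-charge model.  These are the numbers that let one
verify that a QTY redesign, despite 35–50% TM variation, barely shifts pI
and adds well under a kilodalton of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .qty_code import STANDARD_AA, InvalidResidueError, QtyDesign

__all__ = [
    "MassTable",
    "PkSet",
    "DesignReport",
    "DEFAULT_MASS_TABLE",
    "BJELLQVIST",
    "variation_rate",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "build_report",
]


@dataclass(frozen=True)
class MassTable:
    """Average free-amino-acid masses in Da plus the water mass lost per bond."""

    masses: dict[str, float]
    water_mass: float = 18.02

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues {sorted(missing)}")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("masses must be positive")


# Average masses of the free amino acids (Da).  The QTY-relevant entries
# (L 131.17, Q 146.14, I 131.17, V 117.15, T 119.12, F 165.19, Y 181.19)
# fix the per-substitution mass deltas +14.97, -12.05, +1.97, +16.00 Da.
DEFAULT_MASS_TABLE = MassTable(
    masses={
        "G": 75.07, "A": 89.09, "S": 105.09, "P": 115.13, "V": 117.15,
        "T": 119.12, "C": 121.16, "L": 131.17, "I": 131.17, "N": 132.12,
        "D": 133.10, "Q": 146.14, "K": 146.19, "E": 147.13, "M": 149.21,
        "H": 155.16, "F": 165.19, "R": 174.20, "Y": 181.19, "W": 204.23,
    }
)


@dataclass(frozen=True)
class PkSet:
    """A published set of ionizable-group pK values.

    ``side`` holds side-chain pKs for D, E, C, Y (acidic) and H, K, R
    (basic).  N- and C-terminal pKs are single values (no residue-specific
    terminal corrections).
    """

    n_term: float
    c_term: float
    side: dict[str, float]
    name: str = "custom"

    ACIDIC = ("D", "E", "C", "Y")
    BASIC = ("H", "K", "R")

    def __post_init__(self) -> None:
        for label, pk in [("n_term", self.n_term), ("c_term", self.c_term),
                          *self.side.items()]:
            if not 0.0 < pk < 14.0:
                raise ValueError(f"pK for {label} out of (0,14): {pk}")
        missing = set(self.ACIDIC + self.BASIC) - set(self.side)
        if missing:
            raise ValueError(f"pK set missing side chains {sorted(missing)}")


#: Default pK set (Bjellqvist), the convention used by common pI servers.
BJELLQVIST = PkSet(
    n_term=7.50,
    c_term=3.55,
    side={"D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
          "H": 5.98, "K": 10.00, "R": 12.00},
    name="bjellqvist",
)


@dataclass(frozen=True)
class DesignReport:
    """Per-design characteristics mirroring a native-vs-variant summary row."""

    design_id: str
    variation_overall: float  # percent of the whole chain
    variation_tm: float       # percent of TM residues
    mw_native: float          # kDa
    mw_variant: float         # kDa
    pi_native: float
    pi_variant: float
    delta_mw: float           # kDa, variant - native
    delta_pi: float           # pH units, variant - native


def _check_residues(residues: str, known: set[str] | frozenset[str]) -> None:
    bad = set(residues) - set(known)
    if bad:
        raise InvalidResidueError(f"unknown residue(s) {sorted(bad)}")


def variation_rate(design: QtyDesign, scope: str = "overall") -> float:
    """Percent of positions changed by the QTY substitution.

    ``scope='overall'`` divides by the chain length, ``scope='tm'`` by the
    number of TM residues.  Rounded to 2 decimals.
    """
    n_subs = design.n_substitutions
    if scope == "overall":
        denom = len(design.native.residues)
    elif scope == "tm":
        denom = design.n_tm_residues
        if denom == 0:
            raise ZeroDivisionError("TM variation undefined: no TM residues")
    else:
        raise ValueError(f"scope must be 'overall' or 'tm', got {scope!r}")
    return round(100.0 * n_subs / denom, 2)


def molecular_weight(residues: str, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Peptide molecular weight in Da.

    Sum of free-amino-acid masses minus one water per peptide bond.
    """
    if not residues:
        raise ValueError("empty sequence")
    _check_residues(residues, set(table.masses))
    total = sum(table.masses[r] for r in residues)
    return total - (len(residues) - 1) * table.water_mass


def net_charge(residues: str, pH: float, pks: PkSet = BJELLQVIST) -> float:
    """Net Henderson–Hasselbalch charge of a peptide at a given pH.

    Basic groups (N-terminus, K, R, H) contribute ``+1/(1+10^(pH-pK))``;
    acidic groups (C-terminus, D, E, C, Y) contribute ``-1/(1+10^(pK-pH))``.
    Cysteines are treated as reduced (all ionizable).
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH out of (0,14): {pH}")
    _check_residues(residues, STANDARD_AA)

    def basic(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def acidic(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = basic(pks.n_term) + acidic(pks.c_term)
    for res in residues:
        if res in PkSet.BASIC:
            charge += basic(pks.side[res])
        elif res in PkSet.ACIDIC:
            charge += acidic(pks.side[res])
    return charge


def isoelectric_point(
    residues: str, pks: PkSet = BJELLQVIST, tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    ``net_charge`` is strictly decreasing in pH, so the root is unique;
    bisection converges to ``tol`` pH units.
    """
    if not residues:
        raise ValueError("empty sequence")
    lo, hi = 1e-9, 14.0 - 1e-9
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(residues, mid, pks) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_report(
    design: QtyDesign,
    table: MassTable = DEFAULT_MASS_TABLE,
    pks: PkSet = BJELLQVIST,
) -> DesignReport:
    """Assemble the characteristics row for one QTY design.

    Molecular weights are reported in kDa; delta fields are variant − native.
    """
    native = design.native.residues
    variant = design.variant_residues
    mw_n = molecular_weight(native, table) / 1000.0
    mw_v = molecular_weight(variant, table) / 1000.0
    pi_n = isoelectric_point(native, pks)
    pi_v = isoelectric_point(variant, pks)
    return DesignReport(
        design_id=design.native.id,
        variation_overall=variation_rate(design, "overall"),
        variation_tm=(
            variation_rate(design, "tm") if design.n_tm_residues else 0.0
        ),
        mw_native=mw_n,
        mw_variant=mw_v,
        pi_native=pi_n,
        pi_variant=pi_v,
        delta_mw=mw_v - mw_n,
        delta_pi=pi_v - pi_n,
    )
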