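"""First-principles physicochemical properties of peptides.

Implements the full property panel a candidate screen needs per peptide:

* three net-charge models — two fixed-contribution conventions used by AMP
  screening tables (``quarter_ph7``: His +0.25; ``anticp_integer``: His +0.5;
  both with K/R +1, D/E −1 and cancelling termini) and a continuous
  Henderson–Hasselbalch model over an explicit :class:`~pepscan.scales.PkaSet`;
* isoelectric point by bisection on the Henderson–Hasselbalch charge, which
  is strictly decreasing in pH, so the root is unique;
* GRAVY (mean Kyte–Doolittle hydropathy), mean hydrophilicity over any
  registered scale, hydrophobic residue fraction with half-up integer
  percent rounding;
* average molecular weight, Guruprasad instability index (DIWV dipeptide
  weights) and the aliphatic index.

Fixed-contribution charges are computed in exact rational arithmetic
(quarters), so table values like +1.25 are reproduced without float fuzz.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping

from Bio.SeqUtils.ProtParamData import DIWV  # published 400-entry dipeptide table

from .scales import (
    AVERAGE_MASS,
    DEFAULT_PKA_SET,
    HOPP_WOODS,
    HYDROPHOBIC_SETS,
    KYTE_DOOLITTLE,
    MASS_WATER,
    PkaSet,
    ScaleTable,
    get_pka_set,
    get_scale,
)
from .sequence import Peptide, residue_counts

# ---------------------------------------------------------------------------
# fixed-contribution charge conventions

_QUARTER = {
    "K": Fraction(1),
    "R": Fraction(1),
    "D": Fraction(-1),
    "E": Fraction(-1),
    "H": Fraction(1, 4),
}
_ANTICP = {
    "K": Fraction(1),
    "R": Fraction(1),
    "D": Fraction(-1),
    "E": Fraction(-1),
    "H": Fraction(1, 2),
}


@dataclass(frozen=True)
class ChargeConvention:
    """A fixed per-residue charge-contribution rule (termini net zero)."""

    name: str
    contributions: Mapping[str, Fraction]


QUARTER_PH7 = ChargeConvention("quarter_ph7", _QUARTER)
ANTICP_INTEGER = ChargeConvention("anticp_integer", _ANTICP)

CHARGE_CONVENTIONS = {c.name: c for c in (QUARTER_PH7, ANTICP_INTEGER)}


def _seq(p: Peptide | str) -> str:
    return p.sequence if isinstance(p, Peptide) else p


def net_charge_fixed(p: Peptide | str, convention: ChargeConvention | str = QUARTER_PH7) -> float:
    """Net charge under a fixed-contribution convention, exact to quarters."""
    if isinstance(convention, str):
        try:
            convention = CHARGE_CONVENTIONS[convention]
        except KeyError:
            raise KeyError(
                f"unknown charge convention {convention!r}; known: {sorted(CHARGE_CONVENTIONS)}"
            ) from None
    total = sum(
        (convention.contributions.get(r, Fraction(0)) for r in _seq(p)), Fraction(0)
    )
    return float(total)


def net_charge_hh(
    p: Peptide | str, pkset: PkaSet | str = DEFAULT_PKA_SET, pH: float = 7.0
) -> float:
    """Henderson–Hasselbalch net charge at a given pH, termini included.

    Basic groups (N-terminus, H, K, R) contribute ``1 / (1 + 10^(pH − pKa))``;
    acidic groups (C-terminus, D, E, C, Y) contribute ``−1 / (1 + 10^(pKa − pH))``.
    """
    if isinstance(pkset, str):
        pkset = get_pka_set(pkset)
    if not 0 <= pH <= 14:
        raise ValueError(f"pH {pH} outside [0, 14]")
    seq = _seq(p)
    counts = residue_counts(seq)
    charge = 1.0 / (1.0 + 10.0 ** (pH - pkset.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pkset.c_terminus - pH))
    for r in "HKR":
        if counts[r]:
            charge += counts[r] / (1.0 + 10.0 ** (pH - pkset.side_chain[r]))
    for r in "DECY":
        if counts[r]:
            charge -= counts[r] / (1.0 + 10.0 ** (pkset.side_chain[r] - pH))
    return charge


def isoelectric_point(
    p: Peptide | str, pkset: PkaSet | str = DEFAULT_PKA_SET, tol: float = 1e-4
) -> float:
    """The unique pH in (0, 14) at which the Henderson–Hasselbalch charge is zero.

    Every peptide carries both termini, so the charge runs from positive at
    pH 0 to negative at pH 14 and is strictly decreasing; plain bisection to
    ``tol`` is guaranteed to converge on the single root.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if isinstance(pkset, str):
        pkset = get_pka_set(pkset)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge_hh(p, pkset, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# scale means and composition properties


def scale_mean(p: Peptide | str, scale: ScaleTable | str) -> float:
    """Mean of a registered per-residue scale over the sequence."""
    if isinstance(scale, str):
        scale = get_scale(scale)
    seq = _seq(p)
    return sum(scale[r] for r in seq) / len(seq)


def gravy(p: Peptide | str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    return scale_mean(p, KYTE_DOOLITTLE)


def hydrophilicity(p: Peptide | str, scale: ScaleTable | str = HOPP_WOODS) -> float:
    """Mean hydrophilicity (Hopp–Woods by default)."""
    return scale_mean(p, scale)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do (12.5% → 13%)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def hydrophobic_fraction(
    p: Peptide | str, hydrophobic_set: frozenset | str = "default"
) -> tuple[float, int]:
    """(fraction of hydrophobic residues, half-up rounded integer percent)."""
    if isinstance(hydrophobic_set, str):
        hydrophobic_set = HYDROPHOBIC_SETS[hydrophobic_set]
    seq = _seq(p)
    frac = sum(r in hydrophobic_set for r in seq) / len(seq)
    return frac, int(round_half_up(100.0 * frac))


def molecular_weight(p: Peptide | str, masses: ScaleTable = AVERAGE_MASS) -> float:
    """Average molecular weight: residue masses plus one water."""
    return sum(masses[r] for r in _seq(p)) + MASS_WATER


def instability_index(p: Peptide | str) -> float:
    """Guruprasad instability index: (10/L) × Σ DIWV over adjacent pairs."""
    seq = _seq(p)
    if len(seq) < 2:
        raise ValueError("instability index needs at least 2 residues")
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def aliphatic_index(p: Peptide | str) -> float:
    """100 × (f_A + 2.9 f_V + 3.9 (f_I + f_L)), f = mole fractions."""
    seq = _seq(p)
    counts = residue_counts(seq)
    n = len(seq)
    return 100.0 * (
        counts["A"] / n + 2.9 * counts["V"] / n + 3.9 * (counts["I"] + counts["L"]) / n
    )


# ---------------------------------------------------------------------------
# assembled panel


@dataclass(frozen=True)
class PanelConfig:
    """Names resolving the scales, pKa set and conventions a panel uses."""

    pka_set: str = "calibrated"
    hh_pH: float = 7.0
    hydrophilicity_scale: str = "hopp_woods"
    hydrophobic_set: str = "default"
    pI_tol: float = 1e-4


@dataclass(frozen=True)
class PropertyPanel:
    """All computed per-peptide properties, one deterministic record."""

    id: str
    length: int
    net_charge_quarter: float
    net_charge_anticp: float
    net_charge_hh: float
    pI: float
    gravy: float
    hydrophilicity: float
    hydrophobic_fraction: float
    hydrophobic_percent_rounded: int
    molecular_weight: float
    instability_index: float
    aliphatic_index: float


def property_panel(p: Peptide, config: PanelConfig = PanelConfig()) -> PropertyPanel:
    """Assemble the full :class:`PropertyPanel` for one peptide."""
    frac, pct = hydrophobic_fraction(p, config.hydrophobic_set)
    return PropertyPanel(
        id=p.id,
        length=len(p),
        net_charge_quarter=net_charge_fixed(p, QUARTER_PH7),
        net_charge_anticp=net_charge_fixed(p, ANTICP_INTEGER),
        net_charge_hh=net_charge_hh(p, config.pka_set, config.hh_pH),
        pI=isoelectric_point(p, config.pka_set, config.pI_tol),
        gravy=gravy(p),
        hydrophilicity=hydrophilicity(p, config.hydrophilicity_scale),
        hydrophobic_fraction=frac,
        hydrophobic_percent_rounded=pct,
        molecular_weight=molecular_weight(p),
        instability_index=instability_index(p),
        aliphatic_index=aliphatic_index(p),
    )
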