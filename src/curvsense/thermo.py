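"""Two-state thermodynamics of the sensing-to-binding continuum.

A surface peptide partitions between solution (state s) and the membrane
(state m).  With partitioning free energy dF_sm (membrane minus solution,
kJ/mol) the equilibrium membrane-bound probability is Boltzmann
distributed,

    P_m = 1 / (1 + (N_s/N_m) * exp(dF_sm / RT)),

where N_s/N_m counts accessible solvent realizations against membrane
binding realizations at a given lipid concentration.  P_m is a steep
switch in dF_sm, which is why empirically a peptide either binds any
membrane ("binder"), binds only strongly curved membranes ("sensor"),
or does not bind at all ("nonbinder"), even though the underlying free
energies form a continuum.

The curvature-sensing observable is the relative binding free energy
ddF (stretched minus tensionless leaflet, kJ/mol; negative = prefers
curvature).  Two corrections make peptides comparable: extrapolation to
the 24-residue reference length and a per-unit-charge correction c_z*z
that compensates for neutral-membrane calculations on cationic peptides,

    ddF_adj = ddF_(L=24) + c_z * z.

ddF_adj maps linearly onto the flat-membrane partitioning free energy,
dF_sm(inf) = a * ddF_adj + b0, and onto curved vesicles of radius R via
an additional (R_ref / R) * ddF_adj curvature term (an analytic
reconstruction of the radius dependence; see docs/methods.md).  The
sensor regime is the window 0.05 <= P_m <= 0.95 at the queried radius.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.constants import Avogadro, gas_constant
from scipy.special import expit

__all__ = [
    "ThermoConstants",
    "Regime",
    "ClassificationResult",
    "length_adjust",
    "adjusted_ddf",
    "ns_over_nm",
    "delta_f_flat",
    "delta_f_radius",
    "binding_probability",
    "transition_free_energy",
    "sensing_window",
    "classify",
    "pm_vs_radius",
]

_LITER_NM3 = 1e24  # nm^3 per liter


@dataclass(frozen=True)
class ThermoConstants:
    """All constants of the sensing/binding model, with literature defaults.

    Attributes
    ----------
    c_z : kJ/mol per unit charge
        Charge correction for relative binding free energies computed on
        neutral membranes.
    slope, intercept : dimensionless, kJ/mol
        Linear map from ddF_adj to the flat-membrane dF_sm.
    r_ref : nm
        Reference vesicle radius of the curvature assay (the stretched
        leaflet mimics a vesicle of this radius).
    temperature : K
        Temperature entering RT in the Boltzmann factor.
    lipid_conc : mol/L
        Lipid concentration c; half the lipids form accessible (outer
        leaflet) membrane area.
    area_per_lipid, peptide_area : nm^2
        A_lip and the characteristic surface footprint A_p of a bound
        helical peptide (5 x 1 nm).
    peptide_volume : nm^3
        Solution volume V_p of the peptide (5 x 1 x 1 nm).
    volume : L
        Accessible solvent volume.
    length_ref : residues
        Reference peptide length for the length extrapolation.
    p_low, p_high : probabilities
        Sensing window boundaries on P_m.
    """

    c_z: float = -0.93
    slope: float = 3.83
    intercept: float = 12.27
    r_ref: float = 12.5
    temperature: float = 298.15
    lipid_conc: float = 1e-3
    area_per_lipid: float = 0.64
    peptide_area: float = 5.0
    peptide_volume: float = 5.0
    volume: float = 1.0
    length_ref: int = 24
    p_low: float = 0.05
    p_high: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "temperature", "lipid_conc", "area_per_lipid",
            "peptide_area", "peptide_volume", "volume", "r_ref",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.p_low < self.p_high < 1:
            raise ValueError("require 0 < p_low < p_high < 1")

    @property
    def rt(self) -> float:
        """Thermal energy R*T in kJ/mol."""
        return gas_constant * 1e-3 * self.temperature

    def with_(self, **kwargs) -> "ThermoConstants":
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = ThermoConstants()


class Regime(str, enum.Enum):
    nonbinder = "nonbinder"
    sensor = "sensor"
    binder = "binder"


@dataclass(frozen=True)
class ClassificationResult:
    """Full record of one peptide's classification chain."""

    ddf_adj: float       # kJ/mol, length- and charge-adjusted
    df_sm: float         # kJ/mol at the queried radius
    p_m: float           # membrane-bound probability
    regime: Regime
    radius: float        # nm (may be inf)
    window: tuple[float, float]  # (p_low, p_high)


def length_adjust(
    ddf: float,
    length: int,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    slope: float | None = None,
) -> float:
    """Extrapolate ddF of a short peptide to the reference length.

    The relative binding free energy scales linearly with length; the
    default is the proportional model ddF_(L=24) = ddF * L_ref / L
    (a line through the origin).  Alternatively a per-residue ``slope``
    (kJ/mol per residue) can be supplied, in which case the line through
    the observed point is extrapolated: ddF + slope * (L_ref - L).
    """
    lo, hi = 7, consts.length_ref
    if not lo <= length <= hi:
        raise ValueError(f"length must be in [{lo}, {hi}], got {length}")
    if slope is None:
        return ddf * consts.length_ref / length
    return ddf + slope * (consts.length_ref - length)


def adjusted_ddf(
    ddf_l24: float, z: int, consts: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Charge-corrected relative binding free energy ddF_adj = ddF + c_z*z."""
    return ddf_l24 + consts.c_z * z


def ns_over_nm(consts: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Solvent-to-membrane realization ratio N_s/N_m.

    N_s = V / V_p and N_m = A / A_p, with accessible membrane area
    A = (1/2) c N_A A_lip in volume V (half the lipids face outward).
    With the defaults (1 mM lipid, 0.64 nm^2 per lipid, a 5 nm^2 / 5 nm^3
    peptide in 1 L) the ratio is ~5.2e3.
    """
    area = 0.5 * consts.lipid_conc * consts.volume * Avogadro * consts.area_per_lipid
    n_s = consts.volume * _LITER_NM3 / consts.peptide_volume
    n_m = area / consts.peptide_area
    return n_s / n_m


def delta_f_flat(ddf_adj: float, consts: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Flat-membrane (R = inf) partitioning free energy from ddF_adj."""
    return consts.slope * ddf_adj + consts.intercept


def delta_f_radius(
    ddf_adj: float, radius: float, consts: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Partitioning free energy on a vesicle of radius R (nm).

    dF_sm(R) = dF_sm(inf) + (R_ref / R) * ddF_adj.  The curvature term
    contributes the full sensing free energy at the reference radius and
    vanishes as R -> inf.
    """
    if not radius > 0:
        raise ValueError(f"radius must be positive (or inf), got {radius}")
    return delta_f_flat(ddf_adj, consts) + (consts.r_ref / radius) * ddf_adj


def binding_probability(
    df_sm: float, ratio: float | None = None,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Two-state membrane binding probability P_m.

    P_m = 1 / (1 + ratio * exp(dF_sm / RT)); computed through a logistic
    form so extreme free energies saturate to 0/1 without overflow.
    ``ratio`` defaults to ns_over_nm(consts).
    """
    r = ns_over_nm(consts) if ratio is None else ratio
    if not r > 0:
        raise ValueError("ratio must be positive")
    return float(expit(-(df_sm / consts.rt + math.log(r))))


def transition_free_energy(
    ratio: float | None = None, consts: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """dF_sm at the transition point P_m = 0.5: -RT ln(N_s/N_m)."""
    r = ns_over_nm(consts) if ratio is None else ratio
    if not r > 0:
        raise ValueError("ratio must be positive")
    return -consts.rt * math.log(r)


def _df_at_probability(p: float, ratio: float, consts: ThermoConstants) -> float:
    # invert P = 1/(1 + r exp(dF/RT))  =>  dF = RT ln((1-P)/(P r))
    return consts.rt * math.log((1.0 - p) / (p * ratio))


def sensing_window(
    radius: float,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    in_df_sm: bool = False,
) -> tuple[float, float]:
    """Sensor-regime boundaries at a vesicle radius, in ddF_adj (default).

    Returns (upper, lower) ddF_adj values at which P_m equals p_low and
    p_high respectively -- i.e. the less-negative boundary toward
    nonbinders first, then the more-negative boundary toward binders.
    With ``in_df_sm=True`` the same boundaries are reported as dF_sm.
    """
    if not radius > 0:
        raise ValueError("radius must be positive (or inf)")
    r = ns_over_nm(consts)
    df_low = _df_at_probability(consts.p_low, r, consts)
    df_high = _df_at_probability(consts.p_high, r, consts)
    if in_df_sm:
        return (df_low, df_high)
    gain = consts.slope + consts.r_ref / radius
    return ((df_low - consts.intercept) / gain, (df_high - consts.intercept) / gain)


def classify(
    ddf: float,
    length: int = 24,
    z: int = 0,
    radius: float = 50.0,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> ClassificationResult:
    """Classify a peptide as nonbinder / sensor / binder.

    Chains the full model: length extrapolation -> charge correction ->
    radius-dependent partitioning free energy -> binding probability ->
    regime label against the (p_low, p_high) window.
    """
    ddf24 = length_adjust(ddf, length, consts)
    dadj = adjusted_ddf(ddf24, z, consts)
    df = delta_f_radius(dadj, radius, consts)
    pm = binding_probability(df, consts=consts)
    if pm < consts.p_low:
        regime = Regime.nonbinder
    elif pm > consts.p_high:
        regime = Regime.binder
    else:
        regime = Regime.sensor
    return ClassificationResult(
        ddf_adj=dadj, df_sm=df, p_m=pm, regime=regime,
        radius=radius, window=(consts.p_low, consts.p_high),
    )


def pm_vs_radius(
    ddf_adj: float,
    radii: Sequence[float] | Iterable[float],
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> list[tuple[float, float]]:
    """P_m evaluated across vesicle radii for a fixed ddF_adj."""
    out = []
    for radius in radii:
        df = delta_f_radius(ddf_adj, radius, consts)
        out.append((float(radius), binding_probability(df, consts=consts)))
    return out
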