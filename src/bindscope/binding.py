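"""Binding-constant estimation and Van 't Hoff thermodynamics.

For a 1:1 protein-ligand complex whose formation enhances the protein
fluorescence, the intensity change follows the hyperbola

    dF(c) = dFmax * Kb * c / (1 + Kb * c)

whose double-reciprocal (Benesi-Hildebrand-type) linearization

    1/dF = 1/dFmax + 1/(Kb * c * dFmax)

is fitted by ordinary least squares of 1/dF on 1/c; then
Kb = intercept/slope and dFmax = 1/intercept.  The free-ligand
concentration is approximated by the total ligand concentration.

Across temperatures, the Van 't Hoff regression of ln Kb on 1/T gives
dH = -R*slope and dS = R*intercept, with dG(T) = dH - T*dS and the
independent cross-check dG(T) = -R*T*ln Kb(T).  The signs of dH and dS
classify the dominant force (Ross-Subramanian convention): both positive
-> hydrophobic; both negative -> hydrogen bonding / van der Waals;
dH ~ 0 with dS > 0 -> electrostatic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GAS_CONSTANT",
    "BindingFitResult",
    "ThermoResult",
    "fit_double_reciprocal",
    "fit_hyperbolic",
    "vant_hoff",
    "classify_forces",
    "delta_g_direct",
]

GAS_CONSTANT = 8.314  # J / (mol K)

#: |dH| below which a positive dS is read as electrostatic rather than
#: hydrophobic (J/mol).
ELECTROSTATIC_DH_THRESHOLD = 1000.0

FORCE_HYDROPHOBIC = "hydrophobic"
FORCE_HBOND_VDW = "hydrogen-bond/van-der-Waals"
FORCE_ELECTROSTATIC = "electrostatic"
FORCE_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class BindingFitResult:
    """Products of the double-reciprocal fit at one temperature."""

    kb: float  # M^-1
    delta_f_max: float  # a.u.
    slope: float  # a.u.^-1 M
    intercept: float  # a.u.^-1
    r_squared: float
    n_points: int
    wavelength: float  # nm
    temperature: float  # K
    method: str = "double-reciprocal"


@dataclass(frozen=True)
class ThermoResult:
    """Van 't Hoff regression products.

    ``delta_g_by_temperature`` holds dH - T*dS (the primary route);
    ``delta_g_direct_by_temperature`` holds -R*T*ln Kb as a cross-check.
    Energies in J/mol, entropies in J/(mol K).
    """

    delta_h: float
    delta_s: float
    delta_g_by_temperature: dict[float, float]
    delta_g_direct_by_temperature: dict[float, float]
    r_squared: float
    force_class: str
    kb_by_temperature: dict[float, float]
    gas_constant: float = GAS_CONSTANT


def _validate_points(points: Sequence[tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (concentration, dF) pairs")
    if arr.shape[0] < 3:
        raise ValueError("insufficient points for Eq. 1 fit (need >= 3 with dF > 0)")
    if np.any(arr[:, 0] <= 0):
        raise ValueError("all concentrations must be positive")
    if np.any(arr[:, 1] <= 0):
        raise ValueError("all dF values must be positive")
    return arr


def fit_double_reciprocal(
    points: Sequence[tuple[float, float]],
    wavelength: float = 340.0,
    temperature: float = 298.15,
) -> BindingFitResult:
    """Fit 1/dF against 1/c by unweighted OLS and return Kb, dFmax, r^2.

    ``r_squared`` is the squared Pearson correlation of the transformed
    variables.  Raises when the regression yields a non-positive slope
    or intercept (no physically meaningful binding constant).
    """
    arr = _validate_points(points)
    x = 1.0 / arr[:, 0]
    y = 1.0 / arr[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate fit: all concentrations equal")
    res = stats.linregress(x, y)
    if res.slope <= 0 or res.intercept <= 0:
        raise ValueError(
            "no physically meaningful binding constant "
            f"(slope={res.slope:.4g}, intercept={res.intercept:.4g})"
        )
    return BindingFitResult(
        kb=res.intercept / res.slope,
        delta_f_max=1.0 / res.intercept,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=arr.shape[0],
        wavelength=wavelength,
        temperature=temperature,
    )


def fit_hyperbolic(
    points: Sequence[tuple[float, float]],
    wavelength: float = 340.0,
    temperature: float = 298.15,
) -> BindingFitResult:
    """Direct nonlinear fit of dF = dFmax*Kb*c/(1+Kb*c).

    A labelled alternative to the double-reciprocal route, never the
    default; useful when reciprocal-space leverage of the smallest dF
    values is a concern.
    """
    arr = _validate_points(points)
    c, df = arr[:, 0], arr[:, 1]
    # seed from the reciprocal fit when possible, else crude moments
    try:
        seed = fit_double_reciprocal(points, wavelength, temperature)
        p0 = (seed.kb, seed.delta_f_max)
    except ValueError:
        p0 = (1.0 / np.median(c), float(df.max()) * 2.0)
    popt, _ = optimize.curve_fit(
        lambda cc, kb, dfmax: dfmax * kb * cc / (1.0 + kb * cc), c, df, p0=p0
    )
    kb, dfmax = float(popt[0]), float(popt[1])
    if kb <= 0 or dfmax <= 0:
        raise ValueError("no physically meaningful binding constant")
    pred = dfmax * kb * c / (1.0 + kb * c)
    ss_res = float(np.sum((df - pred) ** 2))
    ss_tot = float(np.sum((df - df.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BindingFitResult(
        kb=kb,
        delta_f_max=dfmax,
        slope=1.0 / (kb * dfmax),
        intercept=1.0 / dfmax,
        r_squared=max(0.0, min(1.0, r2)),
        n_points=arr.shape[0],
        wavelength=wavelength,
        temperature=temperature,
        method="hyperbolic",
    )


def classify_forces(
    delta_h: float,
    delta_s: float,
    electrostatic_threshold: float = ELECTROSTATIC_DH_THRESHOLD,
) -> str:
    """Dominant-interaction label from the signs of dH and dS (J-based units)."""
    if not (math.isfinite(delta_h) and math.isfinite(delta_s)):
        raise ValueError("dH and dS must be finite")
    if abs(delta_h) <= electrostatic_threshold and delta_s > 0:
        return FORCE_ELECTROSTATIC
    if delta_h > 0 and delta_s > 0:
        return FORCE_HYDROPHOBIC
    if delta_h < 0 and delta_s < 0:
        return FORCE_HBOND_VDW
    return FORCE_INDETERMINATE


def delta_g_direct(kb: float, temperature: float) -> float:
    """Standard free energy -R*T*ln(Kb) in J/mol."""
    if kb <= 0:
        raise ValueError("kb must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return -GAS_CONSTANT * temperature * math.log(kb)


def vant_hoff(k_by_temperature: Mapping[float, float]) -> ThermoResult:
    """Van 't Hoff regression of ln Kb on 1/T.

    Parameters
    ----------
    k_by_temperature:
        Map of absolute temperature (K) to binding constant (M^-1);
        at least two distinct temperatures, all Kb > 0.
    """
    items = sorted(k_by_temperature.items())
    if len(items) < 2:
        raise ValueError("need >= 2 temperatures for Van 't Hoff analysis")
    temps = np.array([t for t, _ in items], dtype=float)
    kbs = np.array([k for _, k in items], dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive (K)")
    if np.any(kbs <= 0):
        raise ValueError("all Kb must be positive")
    if np.ptp(temps) == 0:
        raise ValueError("temperatures must be distinct")

    x = 1.0 / temps
    y = np.log(kbs)
    res = stats.linregress(x, y)
    delta_h = -GAS_CONSTANT * float(res.slope)
    delta_s = GAS_CONSTANT * float(res.intercept)
    # a perfectly flat response is fitted exactly but has zero correlation
    r2 = 1.0 if (np.ptp(y) == 0 or np.isnan(res.rvalue)) else float(res.rvalue) ** 2
    dg = {float(t): delta_h - float(t) * delta_s for t in temps}
    dg_direct = {float(t): delta_g_direct(float(k), float(t)) for t, k in items}
    return ThermoResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g_by_temperature=dg,
        delta_g_direct_by_temperature=dg_direct,
        r_squared=r2,
        force_class=classify_forces(delta_h, delta_s),
        kb_by_temperature={float(t): float(k) for t, k in items},
    )
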