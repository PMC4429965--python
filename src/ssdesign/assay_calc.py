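"""Downstream biochemistry calculations for disulfide-variant characterization.

Covers the Ellman (DTNB) thiol titration arithmetic that counts free
cysteines and deduces disulfide-bridge numbers, Michaelis–Menten kinetics
(Km, Vmax, kcat, kcat/Km), first-order thermal-inactivation half-lives, and
temperature-optimum extraction from activity profiles.

Unit conventions: concentrations in mM, specific activity in U·mg⁻¹
(µmol·min⁻¹·mg⁻¹), molecular weight in kDa, kcat in min⁻¹, catalytic
efficiency in mM⁻¹·min⁻¹, time in min, temperature in °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "ThiolResult",
    "KineticsFit",
    "InactivationFit",
    "ActivityProfile",
    "fit_standard_curve",
    "predict_od",
    "invert_od",
    "free_cysteines",
    "count_bridges",
    "fit_michaelis_menten",
    "catalytic_constants",
    "fit_inactivation",
    "half_life_ratio",
    "temperature_optimum",
]


@dataclass
class StandardCurve:
    """Ellman calibration line: OD410 = slope·[cysteine, mM] + intercept."""

    slope: float  # OD per mM
    intercept: float  # OD
    residual_sd: float = 0.0
    slope_se: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("a valid Ellman curve has positive slope")


@dataclass
class ThiolResult:
    """Free-thiol quantification for one protein sample."""

    od410: float
    free_thiol_mm: float
    protein_mm: float
    per_molecule: float  # raw ratio, kept for audit
    free_cysteines: int  # nearest integer
    bridges: int | None = None  # set when the total cysteine count is known


@dataclass
class KineticsFit:
    km: float  # mM
    vmax: float  # U/mg
    kcat: float | None = None  # min^-1
    efficiency: float | None = None  # mM^-1 min^-1
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __post_init__(self):
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("Km and Vmax must be positive")


@dataclass
class InactivationFit:
    rate: float  # min^-1
    half_life: float  # min
    method: str  # log_linear | interpolation
    r_squared: float | None = None
    temperature: float | None = None  # °C
    extrapolated: bool = False
    alternative_half_life: float | None = None  # interpolation estimate when it disagrees


@dataclass
class ActivityProfile:
    temperatures: np.ndarray  # °C
    activities: np.ndarray  # % of max (normalized to 100)
    optimum: float | None = None
    boundary: bool = False
    tie: bool = False


# --------------------------------------------------------------------------
# thiol titration


def fit_standard_curve(concentrations_mm: Sequence[float],
                       od410: Sequence[float]) -> StandardCurve:
    """Ordinary least-squares line through (concentration, OD410) points."""
    x = np.asarray(concentrations_mm, dtype=float)
    y = np.asarray(od410, dtype=float)
    if x.size < 2 or np.allclose(x, x[0]):
        raise ValueError("need at least two distinct concentrations")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    sd = float(np.sqrt(((y - pred) ** 2).sum() / max(x.size - 2, 1)))
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         residual_sd=sd, slope_se=float(res.stderr or 0.0))


def predict_od(curve: StandardCurve, concentration_mm: float) -> float:
    if concentration_mm < 0:
        raise ValueError("concentration must be non-negative")
    return curve.slope * concentration_mm + curve.intercept


def invert_od(curve: StandardCurve, od410: float) -> float:
    """Concentration (mM) whose predicted OD410 equals the given reading."""
    return (od410 - curve.intercept) / curve.slope


def free_cysteines(curve: StandardCurve, od410: float, protein_mg_per_ml: float,
                   mw_kda: float, total_cysteines: int | None = None,
                   tolerance_od: float = 0.05) -> ThiolResult:
    """Free cysteines per molecule from an Ellman reading.

    Free thiol (mM) = (OD − intercept)/slope, clamped to 0 for readings within
    *tolerance_od* below the intercept; protein molarity = (mg/mL)/MW(kDa);
    the per-molecule ratio is rounded to the nearest integer.  With the total
    cysteine count known, the bridge count (total − free)/2 is deduced.
    """
    if protein_mg_per_ml <= 0 or mw_kda <= 0:
        raise ValueError("protein concentration and MW must be positive")
    if od410 < curve.intercept - tolerance_od:
        raise ValueError(
            f"OD410 {od410} is below the calibration intercept {curve.intercept:.4f} "
            "by more than the tolerance: negative thiol signal"
        )
    thiol_mm = max(invert_od(curve, od410), 0.0)
    protein_mm = protein_mg_per_ml / mw_kda
    ratio = thiol_mm / protein_mm
    free = int(round(ratio))
    bridges = count_bridges(total_cysteines, free) if total_cysteines is not None else None
    return ThiolResult(od410=od410, free_thiol_mm=thiol_mm, protein_mm=protein_mm,
                       per_molecule=ratio, free_cysteines=free, bridges=bridges)


def count_bridges(total_cysteines: int, free_cysteines: int) -> int:
    """Disulfide bridges deduced by difference: (total − free)/2."""
    if not (total_cysteines >= free_cysteines >= 0):
        raise ValueError("need total ≥ free ≥ 0")
    diff = total_cysteines - free_cysteines
    if diff % 2:
        raise ValueError(
            f"total − free = {diff} is odd: inconsistent cysteine accounting"
        )
    return diff // 2


# --------------------------------------------------------------------------
# kinetics


def _hanes_start(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    # Hanes linearization S/v = S/Vmax + Km/Vmax for start values
    res = stats.linregress(s, s / v)
    vmax = 1.0 / res.slope if res.slope > 0 else v.max()
    km = res.intercept * vmax if res.intercept > 0 else np.median(s)
    return max(km, 1e-6), max(vmax, 1e-6)


def fit_michaelis_menten(substrate_mm: Sequence[float], rate_u_per_mg: Sequence[float],
                         mw_kda: float | None = None) -> KineticsFit:
    """Nonlinear least squares of v = Vmax·S/(Km + S).

    Start values come from a Hanes linearization.  With *mw_kda* given, kcat
    (min⁻¹) and catalytic efficiency kcat/Km are filled in.
    """
    s = np.asarray(substrate_mm, dtype=float)
    v = np.asarray(rate_u_per_mg, dtype=float)
    if s.size < 4:
        raise ValueError("need at least 4 substrate levels")
    if np.allclose(v, v[0]):
        raise ValueError("rates are constant: Km is not identifiable")
    km0, vmax0 = _hanes_start(s, v)
    try:
        popt, _ = optimize.curve_fit(
            lambda S, km, vmax: vmax * S / (km + S), s, v,
            p0=[km0, vmax0], maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    km, vmax = float(popt[0]), float(popt[1])
    if km <= 0 or vmax <= 0:
        raise ValueError(f"fit produced non-physical estimates Km={km}, Vmax={vmax}")
    residuals = v - vmax * s / (km + s)
    fit = KineticsFit(km=km, vmax=vmax, residuals=residuals)
    if mw_kda is not None:
        fit.kcat, fit.efficiency = catalytic_constants(vmax, mw_kda, km)
    return fit


def catalytic_constants(vmax_u_per_mg: float, mw_kda: float,
                        km_mm: float) -> tuple[float, float]:
    """kcat (min⁻¹) = Vmax·MW — U/mg (µmol·min⁻¹·mg⁻¹) times kDa (mg·µmol⁻¹)
    — and catalytic efficiency kcat/Km (mM⁻¹·min⁻¹)."""
    if vmax_u_per_mg <= 0 or mw_kda <= 0 or km_mm <= 0:
        raise ValueError("Vmax, MW and Km must be positive")
    kcat = vmax_u_per_mg * mw_kda
    return kcat, kcat / km_mm


# --------------------------------------------------------------------------
# thermal inactivation


def fit_inactivation(time_min: Sequence[float], residual_pct: Sequence[float],
                     temperature: float | None = None,
                     disagreement_tol: float = 0.10) -> InactivationFit:
    """First-order inactivation: log-linear fit of ln(A/A₀) vs t, t½ = ln2/k.

    A monotone-interpolation estimate of the 50% crossing is computed as a
    cross-check and reported when it disagrees with the fit by more than
    *disagreement_tol* (relative).  Series that never reach 50% within the
    measured window are flagged as extrapolated; a flat series yields an
    infinite half-life.
    """
    t = np.asarray(time_min, dtype=float)
    a = np.asarray(residual_pct, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if a[0] <= 0:
        raise ValueError("initial activity must be positive")
    keep = a > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {int((~keep).sum())} non-positive activity points",
                      stacklevel=2)
    t_fit, a_fit = t[keep], a[keep]
    y = np.log(a_fit / a_fit[0])
    res = stats.linregress(t_fit, y)
    k = -float(res.slope)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else None
    if k <= 0:
        return InactivationFit(rate=0.0, half_life=math.inf, method="log_linear",
                               r_squared=r2, temperature=temperature, extrapolated=True)
    half = math.log(2.0) / k

    # independent 50%-crossing estimate by monotone linear interpolation
    alt = None
    frac = a / a[0] * 100.0
    below = np.nonzero(frac <= 50.0)[0]
    if below.size:
        j = below[0]
        if j == 0:
            alt = float(t[0])
        else:
            f0, f1 = frac[j - 1], frac[j]
            alt = float(t[j - 1] + (f0 - 50.0) / (f0 - f1) * (t[j] - t[j - 1]))
    extrapolated = alt is None and half > t.max()
    report_alt = alt if (alt is not None and abs(alt - half) / half > disagreement_tol) else None
    return InactivationFit(rate=k, half_life=half, method="log_linear", r_squared=r2,
                           temperature=temperature, extrapolated=extrapolated,
                           alternative_half_life=report_alt)


def half_life_ratio(t_variant: float, t_wild: float) -> float:
    """Fold-change in half-life, reported to 1 decimal place."""
    if t_variant <= 0 or t_wild <= 0:
        raise ValueError("half-lives must be positive")
    return round(t_variant / t_wild, 1)


# --------------------------------------------------------------------------
# temperature optimum


def temperature_optimum(temperatures_c: Sequence[float],
                        activities: Sequence[float],
                        refine_parabolic: bool = False) -> ActivityProfile:
    """Optimum = argmax of the measured activities (ties → lowest T, flagged).

    Activities are normalized to max = 100%.  Optional 3-point parabolic
    refinement interpolates the vertex through the peak and its neighbours.
    """
    T = np.asarray(temperatures_c, dtype=float)
    A = np.asarray(activities, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 temperatures")
    order = np.argsort(T)
    T, A = T[order], A[order]
    norm = A / A.max() * 100.0
    k = int(np.argmax(norm))
    tie = int((norm == norm[k]).sum()) > 1
    boundary = k in (0, T.size - 1)
    opt = float(T[k])
    if refine_parabolic and 0 < k < T.size - 1:
        x, y = T[k - 1:k + 2], norm[k - 1:k + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
             + x[0] ** 2 * (y[1] - y[2])) / denom
        if a < 0:
            opt = float(np.clip(-b / (2 * a), T[0], T[-1]))
    return ActivityProfile(temperatures=T, activities=norm, optimum=opt,
                           boundary=boundary, tie=tie)
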