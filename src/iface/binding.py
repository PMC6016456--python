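"""Equilibrium binding fits and coupled-assay rates for nucleotide titrations.

Models the fluorescence titrations used to characterize APS binding to
PAPS synthases: a fixed concentration of fluorescent probe (1 μM mant-APS)
is titrated with protein, and the signal follows the bound-probe fraction.
Because the probe concentration is not negligible against the dissociation
constant (KD in the 13-23 μM range), the single-site model uses the exact
ligand-depletion (quadratic) solution rather than the simple hyperbola.
A Hill fit quantifies apparent cooperativity, a competitive back-titration
fit extracts the competitor KD and EC50 from probe displacement, and a
coupled spectrophotometric assay (ADP production linked to NADH consumption
at 340 nm) is converted from an absorbance slope to a specific activity.

All fits use deterministic multi-start nonlinear least squares (midpoint
estimate ×{0.1, 1, 10}) so results never depend on a random seed; parameter
standard errors come from the local curvature (Jacobian) at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import spearmanr

from .errors import DataQualityWarning, FitError, InputError

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "DisplacementFit",
    "RateResult",
    "bound_fraction_depletion",
    "hill_fraction",
    "competitive_bound_fraction",
    "fit_single_site",
    "fit_hill",
    "fit_displacement",
    "coupled_assay_rate",
]


@dataclass
class TitrationCurve:
    """Concentration-signal pairs from a fluorescence titration.

    ``x`` is the titrant concentration series (μM, strictly increasing),
    ``y`` the signal in arbitrary units; ``probe_conc`` is the fixed
    fluorescent-probe concentration and ``fixed_protein_conc`` the constant
    protein concentration of a back-titration, if any.
    """

    x: np.ndarray
    y: np.ndarray
    probe_conc: float
    fixed_protein_conc: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise InputError("x and y must be 1-D arrays of equal length")
        if np.any(self.x < 0):
            raise InputError("concentrations must be non-negative")
        if np.any(np.diff(self.x) <= 0):
            raise InputError("concentration series must be strictly increasing")
        if not self.probe_conc > 0:
            raise InputError(f"probe_conc must be positive, got {self.probe_conc}")


@dataclass
class BindingFit:
    kd: float  # μM (K_half for Hill fits)
    f_min: float
    f_max: float
    hill_n: float = 1.0
    se: dict = field(default_factory=dict)
    rss: float = 0.0
    model: str = "single-site"


@dataclass
class DisplacementFit:
    ec50: float  # μM competitor at half-maximal bound-probe reduction
    competitor_kd: float | None
    top: float
    bottom: float
    slope: float = 1.0
    se: dict = field(default_factory=dict)
    rss: float = 0.0
    model: str = "competitive-equilibrium"


@dataclass
class RateResult:
    slope: float  # ΔA340 per min
    rate: float  # nmol/min in the cuvette
    specific_activity: float  # nmol·min⁻¹·mg⁻¹


# ---------------------------------------------------------------------------
# forward models


def bound_fraction_depletion(p_total: np.ndarray, l_total: float, kd: float) -> np.ndarray:
    """Exact bound-probe fraction under ligand depletion (single site).

    Solves the quadratic mass balance for probe L titrated with protein P:
    fb = ((P+L+KD) − √((P+L+KD)² − 4PL)) / (2L).
    """
    p = np.asarray(p_total, dtype=float)
    s = p + l_total + kd
    disc = np.clip(s * s - 4.0 * p * l_total, 0.0, None)
    return (s - np.sqrt(disc)) / (2.0 * l_total)


def hill_fraction(p_total: np.ndarray, k_half: float, n: float) -> np.ndarray:
    """Hill-equation occupancy Pⁿ/(K½ⁿ + Pⁿ)."""
    p = np.asarray(p_total, dtype=float)
    pn = np.power(np.clip(p, 0.0, None), n)
    return pn / (np.power(k_half, n) + pn)


def _free_protein(p_total: float, l_total: float, kd_l: float,
                  c_total: float, kd_c: float, tol: float = 1e-9) -> float:
    """Free protein concentration with probe and competitor bound, by root finding."""

    def balance(p_free: float) -> float:
        bound_l = l_total * p_free / (kd_l + p_free)
        bound_c = c_total * p_free / (kd_c + p_free)
        return p_free + bound_l + bound_c - p_total

    if p_total == 0:
        return 0.0
    return brentq(balance, 0.0, p_total, xtol=tol)


def competitive_bound_fraction(
    c_total: np.ndarray, p_total: float, l_total: float, kd_l: float, kd_c: float
) -> np.ndarray:
    """Bound-probe fraction versus competitor concentration (exact equilibrium).

    At each competitor concentration the coupled mass balance
    P = P_free + L·P_free/(KD_L+P_free) + C·P_free/(KD_C+P_free)
    is solved numerically; the probe-bound fraction is P_free/(KD_L+P_free).
    """
    out = np.empty_like(np.asarray(c_total, dtype=float))
    for i, c in enumerate(np.atleast_1d(np.asarray(c_total, dtype=float))):
        p_free = _free_protein(p_total, l_total, kd_l, float(c), kd_c)
        out.flat[i] = p_free / (kd_l + p_free)
    return out


# ---------------------------------------------------------------------------
# fitting machinery


def _midpoint_estimate(x: np.ndarray, y: np.ndarray) -> float:
    """Titrant concentration at the half-maximal signal (linear interpolation)."""
    y_mid = 0.5 * (y.min() + y.max())
    idx = int(np.argmin(np.abs(y - y_mid)))
    return max(float(x[idx]), float(x[x > 0].min()) if np.any(x > 0) else 1.0)


def _multi_start_fit(
    model: Callable,
    x: np.ndarray,
    y: np.ndarray,
    starts: Sequence[np.ndarray],
    bounds: tuple,
    param_names: Sequence[str],
) -> tuple[np.ndarray, dict, float]:
    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, x, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError("nonlinear fit failed to converge from every start")
    popt, pcov, rss = best
    with np.errstate(invalid="ignore"):
        errs = np.sqrt(np.diag(pcov))
    se = {name: float(e) for name, e in zip(param_names, errs)}
    return popt, se, rss


def _check_monotone(curve: TitrationCurve, expect: str) -> None:
    rho = float(spearmanr(curve.x, curve.y).statistic)
    if expect == "ascending" and rho < 0.5:
        warnings.warn(
            f"titration is not clearly ascending (Spearman rho={rho:.2f})",
            DataQualityWarning,
            stacklevel=3,
        )


def fit_single_site(curve: TitrationCurve) -> BindingFit:
    """Single-site fit with the exact ligand-depletion model.

    y = F_min + (F_max − F_min)·fb(P; L, KD) with fb from
    :func:`bound_fraction_depletion`. Three deterministic starts (midpoint
    KD estimate ×{0.1, 1, 10}); the lowest-RSS solution is kept.
    """
    x, y = curve.x, curve.y
    if x.size < 6:
        raise InputError(f"need at least 6 titration points, got {x.size}")
    _check_monotone(curve, "ascending")
    L = curve.probe_conc

    def model(p, kd, f_min, f_max):
        return f_min + (f_max - f_min) * bound_fraction_depletion(p, L, kd)

    mid = _midpoint_estimate(x, y)
    span = y.max() - y.min()
    starts = [np.array([mid * f, y.min(), y.max()]) for f in (1.0, 0.1, 10.0)]
    bounds = (
        np.array([1e-6, y.min() - 10 * span - 1.0, y.min()]),
        np.array([1e6, y.max(), y.max() + 10 * span + 1.0]),
    )
    popt, se, rss = _multi_start_fit(model, x, y, starts, bounds, ("kd", "f_min", "f_max"))
    return BindingFit(
        kd=float(popt[0]), f_min=float(popt[1]), f_max=float(popt[2]),
        hill_n=1.0, se=se, rss=rss, model="single-site",
    )


def fit_hill(curve: TitrationCurve, n_bounds: tuple[float, float] = (0.2, 5.0)) -> BindingFit:
    """Hill-equation fit y = F_min + (F_max − F_min)·Pⁿ/(K½ⁿ + Pⁿ).

    Warns when the fitted coefficient is pinned to the allowed bounds.
    """
    x, y = curve.x, curve.y
    if x.size < 6:
        raise InputError(f"need at least 6 titration points, got {x.size}")
    _check_monotone(curve, "ascending")

    def model(p, k_half, n, f_min, f_max):
        return f_min + (f_max - f_min) * hill_fraction(p, k_half, n)

    mid = _midpoint_estimate(x, y)
    span = y.max() - y.min()
    starts = [np.array([mid * f, 1.0, y.min(), y.max()]) for f in (1.0, 0.1, 10.0)]
    bounds = (
        np.array([1e-6, n_bounds[0], y.min() - 10 * span - 1.0, y.min()]),
        np.array([1e6, n_bounds[1], y.max(), y.max() + 10 * span + 1.0]),
    )
    popt, se, rss = _multi_start_fit(
        model, x, y, starts, bounds, ("k_half", "hill_n", "f_min", "f_max")
    )
    n_fit = float(popt[1])
    if np.isclose(n_fit, n_bounds[0]) or np.isclose(n_fit, n_bounds[1]):
        warnings.warn(
            f"Hill coefficient pinned to bound at {n_fit:.2f}", DataQualityWarning,
            stacklevel=2,
        )
    return BindingFit(
        kd=float(popt[0]), f_min=float(popt[2]), f_max=float(popt[3]),
        hill_n=n_fit, se=se, rss=rss, model="hill",
    )


def fit_displacement(curve: TitrationCurve, probe_kd: float | None = None,
                     mode: str = "equilibrium") -> DisplacementFit:
    """Fit a competitive back-titration (probe displaced by unlabeled competitor).

    Default mode solves the exact competitive equilibrium per point with the
    probe KD fixed from a prior single-site fit and fits the competitor KD;
    EC50 is the competitor concentration at half-maximal bound-probe
    reduction, found by bisection on the fitted model. ``mode="logistic"``
    fits a descending four-parameter logistic instead.
    """
    x, y = curve.x, curve.y
    if x.size < 6:
        raise InputError(f"need at least 6 titration points, got {x.size}")
    if np.ptp(x) == 0:
        raise InputError("competitor concentration never varies; EC50 undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = float(spearmanr(x, y).statistic)
    if not rho < -0.5:  # also catches the NaN of a constant signal
        raise InputError(
            f"displacement data are not descending (Spearman rho={rho:.2f})"
        )

    if mode == "logistic":
        def logistic(c, ec50, slope, top, bottom):
            return bottom + (top - bottom) / (1.0 + np.power(c / ec50, slope))

        mid = _midpoint_estimate(x, y)
        starts = [np.array([mid * f, 1.0, y.max(), y.min()]) for f in (1.0, 0.1, 10.0)]
        span = y.max() - y.min()
        bounds = (
            np.array([1e-6, 0.2, y.min(), y.min() - 10 * span - 1.0]),
            np.array([1e6, 5.0, y.max() + 10 * span + 1.0, y.max()]),
        )
        popt, se, rss = _multi_start_fit(
            logistic, x, y, starts, bounds, ("ec50", "slope", "top", "bottom")
        )
        return DisplacementFit(
            ec50=float(popt[0]), competitor_kd=None, top=float(popt[2]),
            bottom=float(popt[3]), slope=float(popt[1]), se=se, rss=rss,
            model="logistic",
        )

    if probe_kd is None:
        raise InputError("equilibrium mode requires probe_kd from a prior single-site fit")
    if curve.fixed_protein_conc is None:
        raise InputError("equilibrium mode requires fixed_protein_conc on the curve")
    P, L = curve.fixed_protein_conc, curve.probe_conc
    fb0 = float(competitive_bound_fraction(np.array([0.0]), P, L, probe_kd, 1.0)[0])

    def model(c, kd_c, top, bottom):
        fb = competitive_bound_fraction(c, P, L, probe_kd, kd_c)
        return bottom + (top - bottom) * fb / fb0

    mid = _midpoint_estimate(x, y)
    span = y.max() - y.min()
    starts = [np.array([max(mid, 1e-3) * f, y.max(), y.min()]) for f in (1.0, 0.1, 10.0)]
    bounds = (
        np.array([1e-6, y.min(), y.min() - 10 * span - 1.0]),
        np.array([1e6, y.max() + 10 * span + 1.0, y.max()]),
    )
    popt, se, rss = _multi_start_fit(model, x, y, starts, bounds, ("kd", "top", "bottom"))
    kd_c = float(popt[0])

    def half_reduction(c):
        fb = float(competitive_bound_fraction(np.array([c]), P, L, probe_kd, kd_c)[0])
        return fb - 0.5 * fb0

    hi = float(x.max())
    while half_reduction(hi) > 0 and hi < 1e9:
        hi *= 10.0
    ec50 = float(brentq(half_reduction, 1e-12, hi, xtol=1e-9))
    return DisplacementFit(
        ec50=ec50, competitor_kd=kd_c, top=float(popt[1]), bottom=float(popt[2]),
        slope=1.0, se=se, rss=rss, model="competitive-equilibrium",
    )


def coupled_assay_rate(
    times_min: np.ndarray,
    a340: np.ndarray,
    volume_ml: float,
    enzyme_mass_mg: float,
    extinction: float = 6220.0,  # NADH ε340, M⁻¹ cm⁻¹
    path_cm: float = 1.0,
    stoichiometry: float = 1.0,
    window: tuple[int, int] | None = None,
) -> RateResult:
    """Specific activity from an NADH-consumption absorbance trace.

    The slope (ΔA340/min) over the user-selected linear window is converted
    via Beer-Lambert to a molar rate, scaled by the cuvette volume to
    nmol/min, divided by the reaction stoichiometry and the enzyme mass.
    NADH consumption gives a negative slope; a positive slope triggers a
    sign warning.
    """
    t = np.asarray(times_min, dtype=float)
    a = np.asarray(a340, dtype=float)
    if window is not None:
        t, a = t[window[0]: window[1]], a[window[0]: window[1]]
    if t.size < 5:
        raise InputError(f"need at least 5 points in the linear window, got {t.size}")
    if not enzyme_mass_mg > 0:
        raise InputError("enzyme_mass_mg must be positive")
    slope = float(np.polyfit(t, a, 1)[0])
    if slope > 1e-12:  # tolerate round-off on a genuinely flat trace
        warnings.warn(
            "positive A340 slope under the NADH-consumption convention",
            DataQualityWarning,
            stacklevel=2,
        )
    molar_rate = abs(slope) / (extinction * path_cm)  # M/min
    rate_nmol = molar_rate * (volume_ml / 1000.0) * 1e9 / stoichiometry  # nmol/min
    return RateResult(
        slope=slope, rate=rate_nmol, specific_activity=rate_nmol / enzyme_mass_mg
    )
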