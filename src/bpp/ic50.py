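"""Percent inhibition and IC50 estimation from dose-response assays.

Enzyme (ACE or DPP-IV) inhibition is read spectrophotometrically and
expressed as

    inhibition (%) = (A_control - A_inhibitor) / (A_control - A_blank) * 100

IC50 -- the extract concentration giving 50 % inhibition -- is obtained
from the "log(inhibitor) vs. normalized response, variable slope" model

    Y = 100 / (1 + 10^((logIC50 - X) * h)),   X = log10(concentration)

i.e. a four-parameter logistic with the bottom and top asymptotes fixed
at 0 and 100 and a free Hill slope h.  Parameters are fitted by
nonlinear least squares; 95 % confidence intervals come from the
asymptotic covariance with Student-t critical values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["IC50Fit", "inhibition_percent", "four_pl", "fit_ic50"]


@dataclass
class IC50Fit:
    """Result of a dose-response fit.

    ``log_ic50`` is log10 of the concentration (mg/mL) at 50 %
    inhibition; ``hill_slope`` is dimensionless.  With free asymptotes
    (``bottom``/``top`` not None) the extra parameters and their
    intervals are appended in the order (logIC50, slope, bottom, top).
    """

    log_ic50: float
    ic50: float
    hill_slope: float
    se: tuple[float, ...]
    ci95: tuple[tuple[float, float], ...]
    converged: bool
    residual_ss: float
    n_points: int
    bottom: float | None = None
    top: float | None = None


def inhibition_percent(a_control: float, a_inhibitor: float, a_blank: float) -> float:
    """Percent inhibition from the three assay absorbances.

    Noisy data may give values outside [0, 100]; they are returned
    as-is with a warning so the caller can decide how to treat them.
    """
    denom = a_control - a_blank
    if denom == 0:
        raise ValueError("degenerate assay: A_control equals A_blank")
    value = 100.0 * (a_control - a_inhibitor) / denom
    if not 0.0 <= value <= 100.0:
        warnings.warn(f"inhibition {value:.2f}% outside [0, 100]", stacklevel=2)
    return value


def four_pl(x: np.ndarray, log_ic50: float, hill_slope: float,
            bottom: float = 0.0, top: float = 100.0) -> np.ndarray:
    """Normalized-response logistic on the log10 concentration axis."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


def fit_ic50(
    points: list[tuple[float, float]],
    free_asymptotes: bool = False,
    normalize: bool = False,
) -> IC50Fit:
    """Fit the dose-response model to (concentration, inhibition %) points.

    At least five distinct concentrations are required (the usual
    guideline for IC50 estimation).  Replicates enter as independent
    points.  ``normalize`` rescales responses to span 0-100 before
    fitting (off by default: percent inhibition is already on that
    scale).  ``free_asymptotes`` releases the 0/100 bottom/top into the
    fit.

    A flat response or any solver failure returns ``converged=False``
    with NaN parameters instead of raising.
    """
    pts = [(float(c), float(y)) for c, y in points]
    if any(c <= 0 for c, _ in pts):
        raise ValueError("concentrations must be positive")
    if len({c for c, _ in pts}) < 5:
        raise ValueError("at least five distinct concentrations are required")
    x = np.log10([c for c, _ in pts])
    y = np.array([v for _, v in pts])
    if normalize:
        lo, hi = y.min(), y.max()
        if hi > lo:
            y = 100.0 * (y - lo) / (hi - lo)

    n_params = 4 if free_asymptotes else 2
    if np.ptp(y) < 1e-12:
        nan_pair = ((np.nan, np.nan),) * n_params
        return IC50Fit(np.nan, np.nan, np.nan, (np.nan,) * n_params, nan_pair,
                       converged=False, residual_ss=float(np.sum((y - y.mean()) ** 2)),
                       n_points=len(pts))

    if free_asymptotes:
        model = lambda xx, l, h, b, t: four_pl(xx, l, h, b, t)  # noqa: E731
        p0 = [float(np.median(x)), 1.0, float(y.min()), float(y.max())]
    else:
        model = lambda xx, l, h: four_pl(xx, l, h)  # noqa: E731
        p0 = [float(np.median(x)), 1.0]

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning):
        nan_pair = ((np.nan, np.nan),) * n_params
        return IC50Fit(np.nan, np.nan, np.nan, (np.nan,) * n_params, nan_pair,
                       converged=False, residual_ss=np.nan, n_points=len(pts))

    resid = y - model(x, *popt)
    rss = float(resid @ resid)
    dof = max(len(pts) - n_params, 1)
    se = np.sqrt(np.diag(pcov))
    tcrit = stats.t.ppf(0.975, dof)
    ci = tuple((float(p - tcrit * s), float(p + tcrit * s)) for p, s in zip(popt, se))
    converged = bool(np.all(np.isfinite(se)))
    return IC50Fit(
        log_ic50=float(popt[0]),
        ic50=float(10.0 ** popt[0]),
        hill_slope=float(popt[1]),
        se=tuple(float(s) for s in se),
        ci95=ci,
        converged=converged,
        residual_ss=rss,
        n_points=len(pts),
        bottom=float(popt[2]) if free_asymptotes else None,
        top=float(popt[3]) if free_asymptotes else None,
    )
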