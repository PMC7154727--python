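"""Metal accumulation regressions for periphyton, tissue and sediment.

Residue concentrations (µg/g dry weight) scale as power laws of dissolved
metal, so they are regressed on the decade-log scale:

    log10(residue) = a + b * log10(dissolved) [+ q * log10(dissolved)^2].

Single-metal and mixture series are contrasted with a pooled regression
carrying a series indicator and its interaction with log concentration,
giving intercept and slope differences with standard errors — mixture
suppression of accumulation (e.g. an order-of-magnitude lower Cd residue at
the same dissolved Cd when Cu and Zn are co-dosed) shows up as the fitted
offset at a reference concentration.  The quadratic term detects reversal
(parabolic) patterns in which residues rise then fall with dissolved metal,
as when heavily dosed grazers stop feeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["LogLogFit", "SeriesContrast", "fit_loglog", "compare_series",
           "detect_reversal"]


@dataclass
class LogLogFit:
    a_int: float  # log10 µg/g at 1 µg/L
    b_slope: float
    r2: float
    n: int
    q_coef: float | None = None  # quadratic coefficient, if requested
    # data retained for pooled contrasts and reversal range checks
    x: np.ndarray | None = None  # log10 dissolved
    y: np.ndarray | None = None  # log10 residue


@dataclass
class SeriesContrast:
    delta_a: float  # mixture minus single intercept
    delta_b: float  # mixture minus single slope
    se_delta_a: float
    se_delta_b: float
    p_interaction: float  # t-test on the slope-difference term
    offset_at_ref: float  # fitted log10 offset at the reference concentration
    se_offset_at_ref: float
    ref_log10_conc: float


def fit_loglog(dissolved, residue, quadratic: bool = False) -> LogLogFit:
    """Ordinary least squares of log10(residue) on log10(dissolved).

    Requires >= 3 positive paired values (below-detection values should be
    substituted upstream).  Closed-form OLS; r2 is 0 when the response has no
    variance.
    """
    dissolved = np.asarray(dissolved, dtype=float)
    residue = np.asarray(residue, dtype=float)
    mask = (dissolved > 0) & (residue > 0)
    if mask.sum() < 3:
        raise ValueError("need >= 3 positive paired values")
    x = np.log10(dissolved[mask])
    y = np.log10(residue[mask])
    cols = [np.ones_like(x), x] + ([x**2] if quadratic else [])
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss <= 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / tss)
    return LogLogFit(
        a_int=float(coef[0]),
        b_slope=float(coef[1]),
        r2=r2,
        n=int(mask.sum()),
        q_coef=float(coef[2]) if quadratic else None,
        x=x,
        y=y,
    )


def compare_series(
    fit_single: LogLogFit,
    fit_mixture: LogLogFit,
    ref_log10_conc: float | None = None,
) -> SeriesContrast:
    """Pooled-regression contrast of mixture vs single-metal accumulation.

    Fits log10(residue) ~ log10(C) + series + series:log10(C) on the pooled
    data (series = 1 for the mixture), reporting the intercept and slope
    differences with standard errors, the interaction-term p-value, and the
    fitted mixture-minus-single offset at ``ref_log10_conc`` (default: the
    pooled median log10 concentration).
    """
    if fit_single.x is None or fit_mixture.x is None:
        raise ValueError("fits must retain their data (use fit_loglog)")
    x = np.concatenate([fit_single.x, fit_mixture.x])
    y = np.concatenate([fit_single.y, fit_mixture.y])
    g = np.concatenate(
        [np.zeros(fit_single.x.size), np.ones(fit_mixture.x.size)]
    )
    if ref_log10_conc is None:
        ref_log10_conc = float(np.median(x))
    X = sm.add_constant(np.column_stack([x, g, g * x]))
    res = sm.OLS(y, X).fit()
    # coefficient order: const, x, g, g*x
    delta_a, delta_b = float(res.params[2]), float(res.params[3])
    cov = np.asarray(res.cov_params())
    se_a, se_b = float(np.sqrt(cov[2, 2])), float(np.sqrt(cov[3, 3]))
    # offset at reference concentration: delta_a + delta_b * x_ref
    grad = np.array([0.0, 0.0, 1.0, ref_log10_conc])
    se_off = float(np.sqrt(grad @ cov @ grad))
    if np.allclose(y - res.fittedvalues, 0, atol=1e-10) and np.isnan(res.pvalues[3]):
        p_int = 1.0  # perfectly collinear identical series: no interaction
    else:
        p_int = float(res.pvalues[3])
    return SeriesContrast(
        delta_a=delta_a,
        delta_b=delta_b,
        se_delta_a=se_a,
        se_delta_b=se_b,
        p_interaction=p_int,
        offset_at_ref=delta_a + delta_b * ref_log10_conc,
        se_offset_at_ref=se_off,
        ref_log10_conc=ref_log10_conc,
    )


def detect_reversal(fit: LogLogFit) -> tuple[bool, float | None]:
    """Flag a parabolic (rise-then-fall) accumulation pattern.

    True iff the quadratic coefficient is negative and the parabola's vertex
    ``-b / (2q)`` lies strictly inside the observed log10 concentration
    range.  Returns (flag, vertex log10 concentration or None).
    """
    if fit.q_coef is None:
        raise ValueError("reversal detection needs a quadratic fit")
    if fit.q_coef >= 0:
        return False, None
    vertex = -fit.b_slope / (2.0 * fit.q_coef)
    lo, hi = float(fit.x.min()), float(fit.x.max())
    return (lo < vertex < hi), float(vertex)
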