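"""Concentration-response fitting and ECp extraction.

Responses (end-of-test counts, or counts normalized to control means) are
regressed on log10 dissolved concentration with a 3-parameter logistic,

    y(x) = y0 / (1 + exp(b * (x - x50))),    x = log10(concentration µg/L),

by deterministic multi-start least squares.  ``x50`` is log10 of the median
effect concentration and ``b > 0`` is the decline steepness per decade.
Control streams enter the regression at a pseudo-log-concentration a fixed
number of decades (default 2) below the lowest treatment.

ECp for an effect fraction p is closed form:

    ECp = 10 ** (x50 + ln(p / (1 - p)) / b),

so EC50 = 10**x50 exactly and ECp is strictly increasing in p.

Confidence intervals use a seeded case-resampling bootstrap when the data
contain at least two partial effects (responses strictly between 20% and 80%
of the fitted control level); otherwise the response is all-or-nothing and
the interval brackets the highest concentration with no apparent response
and the lowest with complete or nearly complete (>= 90%) reduction.

A flat-then-declining piecewise (breakpoint) regression is also provided;
its breakpoint is a no-effect concentration (EC0) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticFit",
    "PiecewiseFit",
    "ECEstimate",
    "fit_logistic3",
    "ecp",
    "ecp_confidence",
    "fit_piecewise",
    "normalize_to_control",
]

#: decades below the lowest treated concentration at which controls enter the
#: regression (the nonlinear-regression tool the field uses needs a finite x
#: for zero-concentration controls)
CONTROL_OFFSET_DECADES = 2.0

#: responses at or above this fraction of the control level count as "no
#: apparent response" — used both for censoring and for the partial band
NO_EFFECT_FRACTION = 0.8
#: responses at or below this fraction of control count as complete or nearly
#: complete reduction (>= 90% effect)
SEVERE_EFFECT_FRACTION = 0.1
#: partial effect band (fractions of y0) deciding bootstrap vs bracketing
PARTIAL_BAND = (0.2, 0.8)

DEFAULT_N_BOOT = 2000

_B_STARTS = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class LogisticFit:
    """3-parameter logistic fit; the curve passes through y0/2 at x50."""

    y0: float
    x50: float  # log10 µg/L
    b: float  # > 0 means decline with concentration
    cov: np.ndarray | None
    rss: float
    n_points: int
    censored_above: float | None = None  # conc µg/L when no decline observed
    converged: bool = True
    # data retained for bootstrap resampling
    concs: np.ndarray | None = None
    responses: np.ndarray | None = None
    control_responses: np.ndarray | None = None

    @property
    def censored(self) -> bool:
        return self.censored_above is not None


@dataclass
class PiecewiseFit:
    """Flat plateau y0 up to breakpoint x0, then linear decline of slope m."""

    y0: float
    x0: float  # log10 breakpoint = log10 EC0 (µg/L)
    m: float  # per log10 unit beyond x0
    rss: float
    n_points: int
    censored_above: float | None = None

    @property
    def ec0(self) -> float:
        return float(10**self.x0)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.y0 + self.m * np.maximum(x - self.x0, 0.0)


@dataclass
class ECEstimate:
    p: float
    conc: float  # µg/L
    ci_low: float
    ci_high: float
    ci_method: str  # "bootstrap" | "bracketing"
    censored: str | None = None  # "greater_than" when no decline observed


def _logistic(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    y0, x50, b = params
    z = np.clip(b * (x - x50), -700.0, 700.0)
    return y0 / (1.0 + np.exp(z))


def _residuals(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return _logistic(params, x) - y


def _jacobian(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    y0, x50, b = params
    z = np.clip(b * (x - x50), -700.0, 700.0)
    s = 1.0 / (1.0 + np.exp(z))
    sp = s * (1.0 - s)  # -ds/dz
    return np.column_stack((s, y0 * sp * b, -y0 * sp * (x - x50)))


def _ls_fit(x: np.ndarray, y: np.ndarray, start: np.ndarray):
    res = least_squares(
        _residuals, start, jac=_jacobian, args=(x, y), method="lm",
        max_nfev=400, ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    # all-or-nothing patterns send b toward infinity: the iteration cap then
    # ends the fit with a stable x50 and near-zero rss, which is usable
    ok = bool(res.success or (res.status == 0 and np.all(np.isfinite(res.x))))
    return res.x, float(2.0 * res.cost), ok


def _design_x(
    concs: np.ndarray,
    control_n: int,
    control_offset_decades: float,
) -> tuple[np.ndarray, float]:
    x_t = np.log10(concs)
    x_c = float(x_t.min() - control_offset_decades)
    return np.concatenate([x_t, np.full(control_n, x_c)]), x_c


def fit_logistic3(
    concs,
    responses,
    control_responses,
    control_offset_decades: float = CONTROL_OFFSET_DECADES,
    no_effect_fraction: float = NO_EFFECT_FRACTION,
) -> LogisticFit:
    """Fit the 3-parameter logistic to treated responses plus controls.

    If every treated response stays at or above ``no_effect_fraction`` of the
    control mean, no decline was observed within the tested range and the
    result is censored above the highest tested concentration (no fit is
    attempted).  Non-convergence is flagged on the returned fit.
    """
    concs = np.asarray(concs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    control_responses = np.asarray(control_responses, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("treated concentrations must be > 0")
    if control_responses.size == 0:
        raise ValueError("control responses are required")
    if concs.size + control_responses.size < 4:
        raise ValueError("need >= 4 informative points")
    y0_bar = float(control_responses.mean())
    if y0_bar <= 0:
        raise ValueError("control mean must be > 0")

    keep = dict(concs=concs, responses=responses, control_responses=control_responses)
    if responses.min() >= no_effect_fraction * y0_bar:
        return LogisticFit(
            y0=y0_bar, x50=np.nan, b=np.nan, cov=None, rss=np.nan,
            n_points=concs.size + control_responses.size,
            censored_above=float(concs.max()), **keep,
        )

    x, _ = _design_x(concs, control_responses.size, control_offset_decades)
    y = np.concatenate([responses, control_responses])
    x50_grid = np.quantile(np.log10(concs), [0.1, 0.3, 0.5, 0.7, 0.9])

    best_p, best_rss, any_ok = None, np.inf, False
    for x50_0 in x50_grid:
        for b0 in _B_STARTS:
            p, rss, ok = _ls_fit(x, y, np.array([y0_bar, x50_0, b0]))
            any_ok = any_ok or ok
            if ok and rss < best_rss - 1e-12:
                best_p, best_rss = p, rss
    if best_p is None:
        return LogisticFit(
            y0=y0_bar, x50=np.nan, b=np.nan, cov=None, rss=np.inf,
            n_points=x.size, converged=False, **keep,
        )

    J = _jacobian(best_p, x, y)
    cov = None
    dof = x.size - 3
    if dof > 0:
        try:
            cov = np.linalg.inv(J.T @ J) * best_rss / dof
        except np.linalg.LinAlgError:
            cov = None
    return LogisticFit(
        y0=float(best_p[0]), x50=float(best_p[1]), b=float(best_p[2]),
        cov=cov, rss=best_rss, n_points=x.size, **keep,
    )


def ecp(fit: LogisticFit, p: float) -> float:
    """Effect concentration for effect fraction p: 10**(x50 + ln(p/(1-p))/b)."""
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if fit.censored:
        raise ValueError(
            f"no decline observed; ECp censored > {fit.censored_above:g} µg/L"
        )
    if not fit.b > 0:
        raise ValueError("fit shows no decline (b <= 0); ECp undefined")
    return float(10 ** (fit.x50 + np.log(p / (1.0 - p)) / fit.b))


def _refit_ecp(
    x: np.ndarray, y: np.ndarray, start: np.ndarray, p: float
) -> float | None:
    params, _, ok = _ls_fit(x, y, start)
    if not ok or params[2] <= 0:
        return None
    exponent = params[1] + np.log(p / (1.0 - p)) / params[2]
    if not np.isfinite(exponent) or abs(exponent) > 300:
        return None
    return float(10**exponent)


def ecp_confidence(
    fit: LogisticFit,
    p: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    partial_band: tuple[float, float] = PARTIAL_BAND,
    severe_effect_fraction: float = SEVERE_EFFECT_FRACTION,
    alpha: float = 0.05,
) -> ECEstimate:
    """ECp with a confidence interval.

    With >= 2 partial-effect points (treated responses strictly inside
    ``partial_band`` as fractions of y0) a nonparametric case-resampling
    bootstrap percentile interval is used.  With an all-or-nothing response
    pattern the interval instead brackets the highest concentration with no
    apparent response and the lowest with >= 90% reduction.
    """
    if fit.concs is None:
        raise ValueError("fit does not retain its data; refit with fit_logistic3")
    concs, responses = fit.concs, fit.responses
    controls = fit.control_responses
    if fit.censored:
        hi = float(fit.censored_above)
        return ECEstimate(p, hi, hi, np.inf, "bracketing", censored="greater_than")
    point = ecp(fit, p)
    lo_f, hi_f = partial_band
    n_partial = int(np.sum(
        (responses > lo_f * fit.y0) & (responses < hi_f * fit.y0)
    ))

    if n_partial >= 2:
        x, _ = _design_x(concs, controls.size, CONTROL_OFFSET_DECADES)
        y = np.concatenate([responses, controls])
        start = np.array([fit.y0, fit.x50, fit.b])
        rng = np.random.default_rng(seed)
        n = x.size
        estimates = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if np.unique(x[idx]).size < 3:
                continue  # degenerate resample cannot identify 3 parameters
            est = _refit_ecp(x[idx], y[idx], start, p)
            if est is not None and np.isfinite(est):
                estimates.append(est)
        if len(estimates) >= max(20, n_boot // 10):
            lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
            return ECEstimate(
                p, point, float(min(lo, point)), float(max(hi, point)), "bootstrap"
            )
        # fall through to bracketing if the bootstrap degenerates

    y0 = fit.y0
    no_effect = concs[responses >= hi_f * y0]
    severe = concs[responses <= severe_effect_fraction * y0]
    lo = float(no_effect.max()) if no_effect.size else float(concs.min())
    hi = float(severe.min()) if severe.size else float(concs.max())
    return ECEstimate(p, point, min(lo, point), max(hi, point), "bracketing")


def fit_piecewise(concs, responses) -> PiecewiseFit:
    """Breakpoint regression: flat at y0 for x <= x0, linear decline beyond.

    The breakpoint is searched over the midpoints between consecutive
    distinct tested log10 concentrations; (y0, m) are conditional least
    squares at each candidate; the global minimum RSS wins, ties broken
    toward the larger breakpoint.  If no candidate yields a decline (m < 0),
    the EC0 is censored above the highest tested concentration.
    """
    concs = np.asarray(concs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("concentrations must be > 0 (controls via pseudo-conc)")
    if concs.size < 5:
        raise ValueError("need >= 5 points spanning flat and declining regions")
    x = np.log10(concs)
    xs = np.unique(x)
    if xs.size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    grid = (xs[:-1] + xs[1:]) / 2.0

    best = None  # (rss, x0, y0, m)
    any_decline = False
    for x0 in grid:  # ascending, so "<= best rss + tie" prefers larger x0
        X = np.column_stack((np.ones_like(x), np.maximum(x - x0, 0.0)))
        coef, *_ = np.linalg.lstsq(X, responses, rcond=None)
        rss = float(np.sum((X @ coef - responses) ** 2))
        any_decline = any_decline or coef[1] < 0
        if best is None or rss <= best[0] + 1e-12:
            best = (rss, float(x0), float(coef[0]), float(coef[1]))
    rss, x0, y0, m = best
    censored = None if any_decline else float(concs.max())
    return PiecewiseFit(y0, x0, m, rss, concs.size, censored_above=censored)


def normalize_to_control(responses, control_mean: float) -> np.ndarray:
    """Responses as fractions of the control mean (may exceed 1)."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return np.asarray(responses, dtype=float) / control_mean
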