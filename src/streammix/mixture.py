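"""Response-addition mixture predictions and additivity classification.

Under response addition (independent action), the joint survival fraction in
a mixture stream is the product of the survival fractions predicted by the
concurrently fitted single-metal concentration-response curves, each
evaluated at that stream's component concentration:

    predicted fraction = prod_i clamp(f_i(C_i) / y0_i, (0, 1]).

Observed abundance is compared to the predicted abundance with a symmetric
factor-of-2 band (symmetric in log space): observed more than twice the
prediction means the mixture was less toxic than additive; observed below
half the prediction means more than additive.

A "something from nothing" detector flags mixture streams whose component
concentrations individually produced no apparent effect in the concurrent
single-metal streams, yet whose joint exposure dropped the response below
the control confidence limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import LogisticFit

__all__ = [
    "MixturePrediction",
    "predict_response_addition",
    "classify_additivity",
    "detect_something_from_nothing",
]

APPROX_ADDITIVE = "approximately_additive"
LESS_THAN = "less_than_additive"
MORE_THAN = "more_than_additive"

_CLAMP_FLOOR = 1e-12


def single_survival(fit: LogisticFit, conc: float) -> float:
    """Predicted fraction of control from one single-metal fit, clamped to
    (0, 1] so apparent stimulation never masks toxicity."""
    if conc <= 0:
        return 1.0
    if fit.censored:
        # no decline observed within the tested range: survival ~ 1
        return 1.0
    z = np.clip(fit.b * (np.log10(conc) - fit.x50), -700, 700)
    s = 1.0 / (1.0 + np.exp(z))
    return float(min(max(s, _CLAMP_FLOOR), 1.0))


@dataclass
class MixturePrediction:
    stream_id: str
    component_concs: dict[str, float]
    single_survivals: dict[str, float]
    predicted_fraction: float
    predicted_abundance: float
    observed_abundance: float | None = None
    ratio: float | None = None  # observed / predicted
    additivity_class: str | None = None
    something_from_nothing: bool | None = None


def predict_response_addition(
    fits: dict[str, LogisticFit],
    concs: dict[str, float],
    control_mean: float,
    observed: float | None = None,
    stream_id: str = "",
    factor: float = 2.0,
) -> MixturePrediction:
    """Response-addition prediction for one mixture stream.

    Requires a single-metal fit for every component with conc > 0 (error
    names the missing metal).  Metals at zero concentration contribute a
    survival of 1.  If ``observed`` is given, the observed/predicted ratio
    and the additivity class are filled in.
    """
    survivals: dict[str, float] = {}
    for metal, c in concs.items():
        if c < 0:
            raise ValueError(f"negative concentration for {metal}")
        if c > 0 and metal not in fits:
            raise KeyError(f"no single-metal fit for component {metal!r}")
        survivals[metal] = single_survival(fits[metal], c) if c > 0 else 1.0
    predicted_fraction = float(np.prod(list(survivals.values()))) if survivals else 1.0
    pred = MixturePrediction(
        stream_id=stream_id,
        component_concs=dict(concs),
        single_survivals=survivals,
        predicted_fraction=predicted_fraction,
        predicted_abundance=predicted_fraction * control_mean,
    )
    if observed is not None:
        pred.observed_abundance = float(observed)
        pred.ratio = float(observed) / pred.predicted_abundance
        pred.additivity_class = classify_additivity(
            observed, pred.predicted_abundance, factor
        )
    return pred


def classify_additivity(observed: float, predicted: float, factor: float = 2.0) -> str:
    """Factor-of-2 (default) band on the observed/predicted abundance ratio."""
    if predicted <= 0:
        raise ValueError("predicted abundance must be > 0")
    if observed > predicted * factor:
        return LESS_THAN
    if observed < predicted / factor:
        return MORE_THAN
    return APPROX_ADDITIVE


def detect_something_from_nothing(
    single_observations: dict[str, list[tuple[float, float]]],
    component_concs: dict[str, float],
    mixture_observed: float,
    control_lcl: float,
    conc_tolerance: float = 2.0,
) -> bool | None:
    """Did jointly non-toxic component concentrations depress the response?

    ``single_observations`` maps each metal to its concurrent single-metal
    (concentration, response) observations.  For every component dosed in the
    mixture, the single-metal observations within ``conc_tolerance``-fold of
    the component concentration are matched; if any component has no match
    the flag is not evaluable (None).  The flag is True iff every matched
    single-metal response is at or above the control lower limit while the
    mixture response falls below it.
    """
    matched_all_ok = True
    for metal, c in component_concs.items():
        if c <= 0:
            continue
        obs = [
            r for conc, r in single_observations.get(metal, [])
            if c / conc_tolerance <= conc <= c * conc_tolerance
        ]
        if not obs:
            return None
        if any(r < control_lcl for r in obs):
            matched_all_ok = False
    return matched_all_ok and mixture_observed < control_lcl
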