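"""Eligibility screening for concentration-response fitting.

Colonization of the test trays is not controlled, so low end-of-test counts
can reflect either metal mortality or colonization shortfall.  Two rules
decide which taxa carry enough signal to regress:

* a taxon is excluded if any control replicate count is zero, or if the
  normal-approximation Poisson lower 95% confidence limit of its control
  counts is negative (mean - z*sqrt(mean) < 0 on the per-stream count scale);
* within an eligible taxon's series, a low observation is attributed to
  factors other than metals — and dropped from fitting — when a higher count
  occurs at a strictly higher concentration.

An exact Poisson bound can never be negative, so the "negative lower limit"
rule only makes sense under the normal approximation; the per-stream-scale
variance (var = mean) is the default, with the mean-of-replicates scale
(var = mean/n) available by option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import CountTable

__all__ = [
    "ScreenResult",
    "poisson_control_interval",
    "screen_taxa",
    "flag_nonmetal_lows",
]

Z_95 = 1.96


@dataclass
class ScreenResult:
    taxon: str
    included: bool
    reason: str  # ok | zero_control_replicate | negative_poisson_lcl | aggregate_metric
    control_mean: float
    control_lcl: float
    control_ucl: float
    excluded_points: list[tuple[str, str]] = field(default_factory=list)


def poisson_control_interval(
    control_counts, z: float = Z_95, scale: str = "per_stream"
) -> tuple[float, float]:
    """Normal-approximation Poisson interval ``mean ± z*sqrt(var)`` on control
    counts.

    ``scale="per_stream"`` uses var = mean (the variance of a single stream's
    count under Poisson); ``scale="mean"`` uses var = mean/n (the variance of
    the replicate mean).  The lower limit may be negative by construction —
    that is exactly what the exclusion rule keys on.
    """
    counts = np.asarray(control_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need >= 2 control counts")
    mean = float(counts.mean())
    if scale == "per_stream":
        var = mean
    elif scale == "mean":
        var = mean / counts.size
    else:
        raise ValueError(f"unknown scale {scale!r}")
    half = z * np.sqrt(var)
    return mean - half, mean + half


def screen_taxa(
    table: CountTable, z: float = Z_95, scale: str = "per_stream"
) -> list[ScreenResult]:
    """One screening decision per taxon (rule order: aggregate metric, zero
    control replicate, negative Poisson lower limit)."""
    control_ids = table.control_ids()
    if not control_ids:
        raise ValueError("count table has no control streams")
    results = []
    for taxon in table.taxa():
        controls = table.counts_by_stream(taxon.name, control_ids)
        mean = float(controls.mean())
        lcl, ucl = poisson_control_interval(controls, z=z, scale=scale) \
            if mean > 0 else (0.0, 0.0)
        if taxon.metric_flag:
            included, reason = False, "aggregate_metric"
        elif np.any(controls == 0):
            included, reason = False, "zero_control_replicate"
        elif lcl < 0:
            included, reason = False, "negative_poisson_lcl"
        else:
            included, reason = True, "ok"
        results.append(ScreenResult(taxon.name, included, reason, mean, lcl, ucl))
    return results


def flag_nonmetal_lows(
    concs, counts, control_lcl: float, stream_ids=None
) -> list[tuple[str, str]]:
    """Flag observations whose low count is attributable to factors other
    than metals.

    Within one ordered treatment series, an observation is flagged (and
    dropped from fitting) iff its count is below the control lower limit AND
    some observation at a strictly higher concentration has a count at or
    above that limit.  A trailing run of low counts is retained as the
    response.
    """
    concs = np.asarray(concs, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if stream_ids is None:
        stream_ids = [str(i) for i in range(len(concs))]
    flagged = []
    for i in range(len(concs)):
        if counts[i] >= control_lcl:
            continue
        higher = (concs > concs[i]) & (counts >= control_lcl)
        if np.any(higher):
            flagged.append(
                (stream_ids[i],
                 f"count {counts[i]:g} < control LCL {control_lcl:.3g} with"
                 f" count >= LCL at a higher concentration")
            )
    return flagged
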