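"""Hardness-based chronic criteria, cumulative criterion units, and species
sensitivity distributions.

Chronic aquatic-life criteria for hardness-dependent metals follow the USEPA
power-law form on natural logs,

    CCC(H) = exp(m * ln H + b) * CF(H),   CF(H) = cf_const - cf_slope * ln H,

with H the hardness in mg/L as CaCO3 and CF the total-to-dissolved
conversion factor (cf_slope = 0 for hardness-independent CF).  Coefficient
sets ship as editable config because criteria versions change over time;
defaults cover Cd, Ni and Zn.  Cu's criterion is model-based rather than a
hardness equation, so a Cu CCC must be supplied by the user.

Mixtures are summarized as cumulative criterion units,
CCU = sum_i C_i / CCC_i: 1.0 means the mixture sits exactly at the criteria.

SSDs are fitted lognormally by moments of the log10 species values (geometric
mean collapsing duplicate species, Hazen plotting positions for display,
n-1 standard deviation), giving HC5 = 10**(mu - 1.6449 * sd) and percentile
placement of new effect concentrations via the lognormal CDF.  Hardness and
bioavailability adjustments of effect concentrations before placement are
simple multiplicative hooks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "CriterionCoefficients",
    "SSDFit",
    "DEFAULT_CRITERIA",
    "chronic_criterion",
    "ccu",
    "hardness_adjust_ec",
    "bioavailability_adjust_ec",
    "build_ssd",
    "ssd_percentile",
]

#: standard normal 5th percentile, used for HC5
Z_HC5 = 1.6449


@dataclass(frozen=True)
class CriterionCoefficients:
    """Hardness-equation coefficients for one metal's chronic criterion."""

    metal: str
    m_slope: float  # ln-ln hardness slope
    b_int: float  # intercept on the ln scale
    cf_const: float = 1.0
    cf_slope: float = 0.0  # CF = cf_const - cf_slope * ln(H)
    hardness_range: tuple[float, float] = (5.0, 400.0)


#: USEPA hardness-based chronic criterion coefficient sets (dissolved).
#: Cu's criterion is bioavailability-model based and must be supplied as a
#: plain CCC value by the user.
DEFAULT_CRITERIA: dict[str, CriterionCoefficients] = {
    "Cd": CriterionCoefficients("Cd", 0.7977, -3.909, 1.101672, 0.041838),
    "Ni": CriterionCoefficients("Ni", 0.846, 0.0584, 0.997, 0.0),
    "Zn": CriterionCoefficients("Zn", 0.8473, 0.884, 0.986, 0.0),
}


def chronic_criterion(coeffs: CriterionCoefficients, hardness: float) -> float:
    """Chronic criterion (µg/L dissolved) at the given hardness (mg/L CaCO3).

    Unrounded; round only at reporting.
    """
    if hardness <= 0:
        raise ValueError("hardness must be > 0")
    lo, hi = coeffs.hardness_range
    if not (lo <= hardness <= hi):
        raise ValueError(
            f"hardness {hardness} outside valid range {coeffs.hardness_range}"
            f" for {coeffs.metal}"
        )
    ln_h = np.log(hardness)
    cf = coeffs.cf_const - coeffs.cf_slope * ln_h
    return float(np.exp(coeffs.m_slope * ln_h + coeffs.b_int) * cf)


def ccu(concs: dict[str, float], criteria: dict[str, float]) -> float:
    """Cumulative criterion units: sum of C_i / CCC_i over metals present."""
    total = 0.0
    for metal, c in concs.items():
        if c <= 0:
            continue
        if metal not in criteria:
            raise KeyError(f"no criterion supplied for metal {metal!r}")
        ccc = criteria[metal]
        if ccc <= 0:
            raise ValueError(f"criterion for {metal!r} must be > 0")
        total += c / ccc
    return total


def hardness_adjust_ec(
    ec: float, h_test: float, h_target: float, slope: float
) -> float:
    """Hardness-toxicity power-law adjustment: ec * (h_target/h_test)**slope."""
    if ec <= 0 or h_test <= 0 or h_target <= 0:
        raise ValueError("ec and hardnesses must be > 0")
    return float(ec * (h_target / h_test) ** slope)


def bioavailability_adjust_ec(ec: float, factor: float) -> float:
    """Multiplicative bioavailability adjustment (e.g. a factor computed by an
    external biotic ligand model tool)."""
    if factor <= 0:
        raise ValueError("adjustment factor must be > 0")
    return float(ec * factor)


@dataclass
class SSDFit:
    """Lognormal species sensitivity distribution fitted by moments."""

    species: list[str]  # ranked, ascending value
    values: np.ndarray  # µg/L, ascending (duplicates collapsed by geomean)
    plotting_positions: np.ndarray  # Hazen (i - 0.5)/n
    mu_log: float  # mean of log10 values
    sd_log: float  # sd of log10 values (n-1 denominator)
    hc5: float  # µg/L


def build_ssd(species_values) -> SSDFit:
    """Fit a lognormal SSD to (species, value µg/L) pairs.

    Duplicate species are collapsed by geometric mean before ranking;
    requires >= 3 distinct species with positive values.
    """
    by_species: dict[str, list[float]] = {}
    for species, value in species_values:
        if value <= 0:
            raise ValueError(f"nonpositive value for species {species!r}")
        by_species.setdefault(str(species), []).append(float(value))
    if len(by_species) < 3:
        raise ValueError("need >= 3 distinct species")
    collapsed = {
        sp: float(np.exp(np.mean(np.log(vals)))) for sp, vals in by_species.items()
    }
    order = sorted(collapsed, key=lambda sp: (collapsed[sp], sp))
    values = np.array([collapsed[sp] for sp in order])
    n = values.size
    positions = (np.arange(1, n + 1) - 0.5) / n
    logs = np.log10(values)
    mu = float(logs.mean())
    sd = float(logs.std(ddof=1))
    hc5 = float(10 ** (mu - Z_HC5 * sd))
    return SSDFit(order, values, positions, mu, sd, hc5)


def ssd_percentile(ssd: SSDFit, value: float) -> float:
    """Fraction of species expected to be affected at ``value`` (lognormal CDF
    at log10(value))."""
    if value <= 0:
        raise ValueError("value must be > 0")
    if ssd.sd_log == 0:
        lv = np.log10(value)
        return 0.5 if lv == ssd.mu_log else (0.0 if lv < ssd.mu_log else 1.0)
    return float(norm.cdf((np.log10(value) - ssd.mu_log) / ssd.sd_log))
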