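"""Synthetic mesocosm experiments with known ground truth.

The generator emulates the statistical structure of a 30-day artificial
stream metal experiment:

* a regression design — replicated controls (4 by default) plus unreplicated
  geometric concentration series for single metals and fixed-ratio mixtures;
* first-order approach-to-plateau dosing kinetics per metal,
  ``C(t) = C_bg + nominal * c_ss * (1 - exp(-k_up * t))``, with
  multiplicative lognormal sampling noise;
* per-taxon logistic survival versus the time-weighted-average dissolved
  concentration, with joint mixture survival ``(prod_i S_i)**theta`` —
  ``theta`` is a one-parameter antagonism/synergy device (1 = response
  additive, < 1 = less than additive);
* overdispersed colonization counts drawn negative-binomially around
  ``lambda0 * survival`` (NB size parameter ``dispersion_k``; large k
  recovers Poisson);
* log-linear accumulation of metals into periphyton, caddisfly tissue and
  sediment, with optional quadratic (reversal) terms and per-compartment
  mixture suppression offsets.

Every run returns the CSV-schema tables from :mod:`streammix.core_model`
plus a ground-truth record of the parameters used, so each analysis stage
can be tested against known answers.  All randomness flows from one seed
through per-table sub-seeds, so individual tables are reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    AGGREGATE_GROUP,
    CountTable,
    ExposureSeries,
    ResidueSample,
    StreamUnit,
    Study,
    WaterChemistry,
)
from .exposure_chem import time_weighted_average

__all__ = [
    "MetalSensitivity",
    "TaxonParams",
    "UptakeKinetics",
    "AccumulationParams",
    "SeriesDef",
    "DesignConfig",
    "survival_fraction",
    "logistic_survival",
    "generate_exposure_series",
    "generate_experiment",
    "default_taxa",
    "uniform_mayfly_taxa",
    "default_design",
    "DEFAULT_SAMPLE_DAYS",
]

#: Twice-weekly water sampling over the 30-d exposure (day 1 = dosing start).
DEFAULT_SAMPLE_DAYS = (1.0, 4.0, 8.0, 11.0, 15.0, 18.0, 22.0, 25.0, 29.0)


@dataclass(frozen=True)
class MetalSensitivity:
    """Logistic survival parameters of one taxon for one metal."""

    log10_ec50: float  # log10 µg/L
    slope_b: float  # steepness per log10 unit, > 0

    def __post_init__(self) -> None:
        if not self.slope_b > 0:
            raise ValueError("slope_b must be > 0")


@dataclass(frozen=True)
class TaxonParams:
    taxon: str
    group: str
    lambda0: float  # expected control abundance per stream
    dispersion_k: float  # NB size parameter; large -> Poisson
    sensitivity: dict[str, MetalSensitivity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be > 0")
        if not self.dispersion_k > 0:
            raise ValueError("dispersion_k must be > 0")


@dataclass(frozen=True)
class UptakeKinetics:
    """First-order dosing kinetics for one metal.

    ``c_ss`` scales the nominal treatment concentration to the plateau
    actually attained (1.0 = nominal reached); ``c_bg`` is the background
    concentration in the dilution water (µg/L).
    """

    c_ss: float = 1.0
    k_up: float = 0.25  # per day
    c_bg: float = 0.0  # µg/L

    def __post_init__(self) -> None:
        if not self.k_up > 0:
            raise ValueError("k_up must be > 0")

    def conc_at(self, nominal: float, t: np.ndarray | float) -> np.ndarray | float:
        return self.c_bg + nominal * self.c_ss * (1.0 - np.exp(-self.k_up * np.asarray(t, float)))


@dataclass(frozen=True)
class AccumulationParams:
    """log10(residue µg/g) = a_acc + b_acc*log10(C) + q_acc*log10(C)^2 + noise."""

    a_acc: float
    b_acc: float
    sigma_acc: float = 0.0  # sd of lognormal noise on the log10 scale
    q_acc: float = 0.0


@dataclass(frozen=True)
class SeriesDef:
    """One treatment series: metals, their fixed ratio, and the geometric
    concentration ladder of the lead (first) metal."""

    name: str
    metals: tuple[str, ...]
    top_conc: float  # nominal top concentration of the lead metal, µg/L
    ratio: dict[str, float] = field(default_factory=dict)  # lead:other mass ratio
    n_levels: int = 6
    dilution: float = 2.0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.dilution > 1:
            raise ValueError("dilution factor must be > 1")
        for m in self.metals[1:]:
            if m not in self.ratio:
                raise ValueError(f"series {self.name!r}: missing ratio for {m!r}")

    def nominal(self, level: int) -> dict[str, float]:
        """Nominal concentration of each component at 1-based ``level``."""
        lead = self.top_conc / self.dilution ** (self.n_levels - level)
        out = {self.metals[0]: lead}
        for m in self.metals[1:]:
            out[m] = lead / self.ratio[m]
        return out


@dataclass
class DesignConfig:
    n_control_replicates: int = 4
    series: list[SeriesDef] = field(default_factory=list)
    interaction_theta: float = 1.0
    kinetics: dict[str, UptakeKinetics] = field(default_factory=dict)
    accumulation: dict[tuple[str, str], AccumulationParams] = field(
        default_factory=dict
    )  # keyed (compartment, metal)
    #: log10 offset applied to accumulation in mixture streams, keyed
    #: (compartment, metal); e.g. -1.0 reproduces an order-of-magnitude
    #: suppression of accumulation in the presence of co-dosed metals.
    mixture_accumulation_offset: dict[tuple[str, str], float] = field(
        default_factory=dict
    )
    sample_days: tuple[float, ...] = DEFAULT_SAMPLE_DAYS
    exposure_noise_sd: float = 0.10  # lognormal sd (natural-log scale)
    count_mode: str = "nb"  # "nb" draws counts; "expected" rounds the mean
    hardness_mean: float = 18.1  # mg/L as CaCO3
    hardness_sd: float = 0.7
    doc_mean: float = 3.2
    doc_sd: float = 0.28
    ph_mean: float = 7.5
    ph_sd: float = 0.1
    ca_mean: float = 5.3
    ca_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_control_replicates < 2:
            raise ValueError("need >= 2 control replicates")
        if not self.interaction_theta > 0:
            raise ValueError("interaction_theta must be > 0")
        if self.count_mode not in ("nb", "expected"):
            raise ValueError("count_mode must be 'nb' or 'expected'")

    def without_noise(self) -> "DesignConfig":
        """Copy of the design with deterministic counts, exposure and residues."""
        acc = {
            k: dataclasses.replace(v, sigma_acc=0.0)
            for k, v in self.accumulation.items()
        }
        return dataclasses.replace(
            self,
            exposure_noise_sd=0.0,
            count_mode="expected",
            accumulation=acc,
            hardness_sd=0.0,
            doc_sd=0.0,
            ph_sd=0.0,
            ca_sd=0.0,
        )


def logistic_survival(conc: float, sens: MetalSensitivity) -> float:
    """Single-metal survival fraction 1/(1 + exp(b*(log10 C - log10 EC50)));
    1 at zero concentration."""
    if conc <= 0:
        return 1.0
    z = sens.slope_b * (np.log10(conc) - sens.log10_ec50)
    return float(1.0 / (1.0 + np.exp(np.clip(z, -700, 700))))


def survival_fraction(
    concs: dict[str, float], taxon: TaxonParams, theta: float = 1.0
) -> float:
    """Joint survival ``(prod_i S_i(C_i))**theta`` over the metals present.

    Metals absent from the taxon's sensitivity map are treated as non-toxic
    (S = 1); zero concentrations contribute S = 1.  Returns a value in (0, 1].
    """
    if any(c < 0 for c in concs.values()):
        raise ValueError("concentrations must be >= 0")
    prod = 1.0
    for metal, c in concs.items():
        sens = taxon.sensitivity.get(metal)
        if sens is not None:
            prod *= logistic_survival(c, sens)
    return float(prod**theta)


def generate_exposure_series(
    kinetics: UptakeKinetics,
    nominal: float,
    sample_days,
    noise_sd: float,
    rng: np.random.Generator,
    stream_id: str = "",
    metal: str = "",
    detection_limit: float | None = None,
) -> ExposureSeries:
    """Sampled dissolved concentration curve for one stream x metal."""
    t = np.asarray(sample_days, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample_days must be strictly increasing")
    conc = np.asarray(kinetics.conc_at(nominal, t), dtype=float)
    if noise_sd > 0:
        conc = conc * np.exp(rng.normal(0.0, noise_sd, size=len(t)))
    below = np.zeros(len(t), dtype=bool)
    dl = np.full(len(t), np.nan)
    if detection_limit is not None:
        below = conc < detection_limit
        dl[:] = detection_limit
        conc = np.where(below, 0.0, conc)
    return ExposureSeries(stream_id, metal, t, conc, below, dl)


def _stream_layout(design: DesignConfig) -> list[StreamUnit]:
    units = [
        StreamUnit(f"control-{i + 1}", "control", 0, True, i + 1)
        for i in range(design.n_control_replicates)
    ]
    for sd in design.series:
        for level in range(1, sd.n_levels + 1):
            units.append(StreamUnit(f"{sd.name}-{level}", sd.name, level, False, 0))
    return units


def generate_experiment(
    taxa: list[TaxonParams],
    design: DesignConfig,
    seed: int,
    add_total_mayflies: bool = True,
) -> tuple[Study, dict]:
    """Generate a complete synthetic study plus its ground-truth record.

    Counts respond to the time-weighted average of each stream's sampled
    (noisy) exposure series, which is exactly the exposure metric the
    analysis pipeline uses, so with noise switched off the pipeline is an
    exact inverse of the generator.  The interaction exponent ``theta``
    applies only in streams dosed with more than one metal: deviation from
    response addition is a mixture property.
    """
    ss = np.random.SeedSequence(seed)
    rng_exp, rng_count, rng_res, rng_chem = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    units = _stream_layout(design)
    series_by_name = {sd.name: sd for sd in design.series}
    study_metals = sorted({m for sd in design.series for m in sd.metals})

    # --- dissolved exposure series (controls receive background only)
    exposures: list[ExposureSeries] = []
    twa: dict[str, dict[str, float]] = {}
    nominal_by_stream: dict[str, dict[str, float]] = {}
    for u in units:
        nominal = {m: 0.0 for m in study_metals}
        if not u.is_control:
            nominal.update(series_by_name[u.series].nominal(u.level))
        nominal_by_stream[u.stream_id] = nominal
        twa[u.stream_id] = {}
        for m in study_metals:
            kin = design.kinetics.get(m, UptakeKinetics())
            s = generate_exposure_series(
                kin,
                nominal[m],
                design.sample_days,
                design.exposure_noise_sd,
                rng_exp,
                stream_id=u.stream_id,
                metal=m,
            )
            exposures.append(s)
            twa[u.stream_id][m] = time_weighted_average(s)

    # --- end-of-test counts
    rows = []
    for u in units:
        n_dosed = sum(1 for v in nominal_by_stream[u.stream_id].values() if v > 0)
        theta = design.interaction_theta if n_dosed > 1 else 1.0
        for tp in taxa:
            surv = survival_fraction(twa[u.stream_id], tp, theta)
            mean = tp.lambda0 * surv
            if design.count_mode == "expected":
                count = int(round(mean))
            else:
                # NB(mean, k): p = k/(k+mean)
                p = tp.dispersion_k / (tp.dispersion_k + mean)
                count = int(rng_count.negative_binomial(tp.dispersion_k, p))
            rows.append(
                {"stream_id": u.stream_id, "taxon": tp.taxon, "group": tp.group,
                 "count": count}
            )
    import pandas as pd

    counts_df = pd.DataFrame(rows)
    if add_total_mayflies:
        mask = counts_df["group"].str.startswith("Ephemeroptera")
        agg = counts_df[mask].groupby("stream_id")["count"].sum().reset_index()
        agg["taxon"] = "Total mayflies"
        agg["group"] = AGGREGATE_GROUP
        counts_df = pd.concat(
            [counts_df, agg[["stream_id", "taxon", "group", "count"]]],
            ignore_index=True,
        )
    counts = CountTable(counts_df, {u.stream_id: u for u in units})

    # --- residues (dosed streams only, per compartment x metal)
    residues: list[ResidueSample] = []
    for u in units:
        if u.is_control:
            continue
        is_mixture = len(series_by_name[u.series].metals) > 1
        for (comp, metal), ap in sorted(design.accumulation.items()):
            c = twa[u.stream_id].get(metal, 0.0)
            if metal not in series_by_name[u.series].metals or c <= 0:
                continue
            x = np.log10(c)
            log_r = ap.a_acc + ap.b_acc * x + ap.q_acc * x * x
            if is_mixture:
                log_r += design.mixture_accumulation_offset.get((comp, metal), 0.0)
            if ap.sigma_acc > 0:
                log_r += rng_res.normal(0.0, ap.sigma_acc)
            residues.append(ResidueSample(u.stream_id, comp, metal, float(10**log_r)))

    # --- water chemistry
    chem = [
        WaterChemistry(
            u.stream_id,
            float(max(design.hardness_mean + rng_chem.normal(0, design.hardness_sd), 1e-6))
            if design.hardness_sd > 0 else design.hardness_mean,
            float(design.doc_mean + rng_chem.normal(0, design.doc_sd))
            if design.doc_sd > 0 else design.doc_mean,
            float(design.ph_mean + rng_chem.normal(0, design.ph_sd))
            if design.ph_sd > 0 else design.ph_mean,
            float(design.ca_mean + rng_chem.normal(0, design.ca_sd))
            if design.ca_sd > 0 else design.ca_mean,
        )
        for u in units
    ]

    ground_truth = {
        "seed": seed,
        "theta": design.interaction_theta,
        "taxa": {
            tp.taxon: {
                "lambda0": tp.lambda0,
                "dispersion_k": tp.dispersion_k,
                "sensitivity": {
                    m: {"ec50_ugL": 10**s.log10_ec50, "slope_b": s.slope_b}
                    for m, s in tp.sensitivity.items()
                },
            }
            for tp in taxa
        },
        "kinetics": {
            m: dataclasses.asdict(design.kinetics.get(m, UptakeKinetics()))
            for m in study_metals
        },
        "accumulation": {
            f"{comp}:{metal}": dataclasses.asdict(ap)
            for (comp, metal), ap in sorted(design.accumulation.items())
        },
        "mixture_accumulation_offset": {
            f"{comp}:{metal}": off
            for (comp, metal), off in sorted(design.mixture_accumulation_offset.items())
        },
        "nominal_concs": nominal_by_stream,
        "twa_concs": twa,
    }
    return Study(counts, exposures, chem, residues), ground_truth


# ---------------------------------------------------------------------------
# Default study conditions


def default_design(theta: float = 1.0, count_mode: str = "nb") -> DesignConfig:
    """A Zn/Cu/Cd design emulating the second-year experiment: 4 control
    replicates, five 6-level geometric series (three singles, a binary and a
    ternary mixture at Zn:Cu = 16:1 and Zn:Cd = 200:1), Cd dosed with slower
    first-order kinetics than Cu and Zn."""
    series = [
        SeriesDef("Zn", ("Zn",), top_conc=1100.0),
        SeriesDef("Cu", ("Cu",), top_conc=26.0),
        SeriesDef("Cd", ("Cd",), top_conc=1.2),
        SeriesDef("Zn+Cu", ("Zn", "Cu"), top_conc=420.0, ratio={"Cu": 16.0}),
        SeriesDef(
            "Zn+Cu+Cd", ("Zn", "Cu", "Cd"), top_conc=420.0,
            ratio={"Cu": 16.0, "Cd": 200.0},
        ),
    ]
    kinetics = {
        "Zn": UptakeKinetics(c_ss=1.0, k_up=0.25, c_bg=1.3),
        "Cu": UptakeKinetics(c_ss=1.0, k_up=0.25, c_bg=0.6),
        "Cd": UptakeKinetics(c_ss=1.0, k_up=0.08, c_bg=0.01),
    }
    acc = {}
    peri_a = {"Cd": 2.8, "Cu": 2.3, "Zn": 1.85}
    tis_a = {"Cd": 1.5, "Cu": 1.2, "Zn": 1.3}
    sed_a = {"Cd": 1.8, "Cu": 1.5, "Zn": 1.1}
    for m in ("Cd", "Cu", "Zn"):
        acc[("periphyton", m)] = AccumulationParams(peri_a[m], 0.95, 0.05)
        acc[("tissue", m)] = AccumulationParams(tis_a[m], 0.70, 0.15)
        acc[("sediment", m)] = AccumulationParams(sed_a[m], 0.80, 0.10)
    return DesignConfig(
        series=series,
        kinetics=kinetics,
        accumulation=acc,
        mixture_accumulation_offset={("periphyton", "Cd"): -1.0, ("tissue", "Cd"): -1.0},
        interaction_theta=theta,
        count_mode=count_mode,
    )


def default_taxa() -> list[TaxonParams]:
    """A community with heterogeneous metal sensitivities: six mayfly taxa
    whose control abundances sum to ~200 per stream, metal-tolerant
    caddisflies and other taxa, and two sparse taxa that fail screening.
    EC50s are on the µg/L scales typical of chronic mayfly responses."""

    def s(ec50: float, b: float = 4.0) -> MetalSensitivity:
        return MetalSensitivity(float(np.log10(ec50)), b)

    tol = {"Cd": s(60.0), "Cu": s(500.0), "Zn": s(9000.0)}
    return [
        TaxonParams("Baetis tricaudatus", "Ephemeroptera/Baetidae", 25, 20,
                    {"Cd": s(0.11), "Cu": s(4.9), "Zn": s(75)}),
        TaxonParams("Diphetor hageni", "Ephemeroptera/Baetidae", 20, 20,
                    {"Cd": s(1.08), "Cu": s(6.7), "Zn": s(39)}),
        TaxonParams("Ephemerella infrequens", "Ephemeroptera/Ephemerellidae", 60, 20,
                    {"Cd": s(0.19), "Cu": s(6.9), "Zn": s(184)}),
        TaxonParams("Rhithrogena sp.", "Ephemeroptera/Heptageniidae", 45, 20,
                    {"Cd": s(1.2), "Cu": s(25), "Zn": s(61)}),
        TaxonParams("Epeorus longimanus", "Ephemeroptera/Heptageniidae", 30, 20,
                    {"Cd": s(5.0), "Cu": s(40), "Zn": s(59)}),
        TaxonParams("Paraleptophlebia sp.", "Ephemeroptera/Leptophlebiidae", 20, 20,
                    {"Cd": s(4.0), "Cu": s(31), "Zn": s(316)}),
        TaxonParams("Lepidostoma sp.", "Trichoptera/Lepidostomatidae", 15, 20,
                    {"Cd": s(0.68), "Cu": s(31), "Zn": s(2000)}),
        TaxonParams("Brachycentrus occidentalis", "Trichoptera/Brachycentridae", 40, 20, tol),
        TaxonParams("Arctopsyche grandis", "Trichoptera/Hydropsychidae", 10, 20, tol),
        TaxonParams("Atherix pachypus", "Diptera/Athericidae", 5, 20, tol),
        TaxonParams("Lebertia sp.", "Acari/Lebertiidae", 8, 20, tol),
        TaxonParams("Rheotanytarsus sp.", "Diptera/Chironomidae", 12, 20,
                    {"Cd": s(30.0), "Cu": s(200.0), "Zn": s(337)}),
        TaxonParams("Polypedilum sp.", "Diptera/Chironomidae", 1.5, 20, tol),
        TaxonParams("Micropsectra sp.", "Diptera/Chironomidae", 2.5, 20, tol),
    ]


def uniform_mayfly_taxa(
    lambda0: float = 200.0,
    dispersion_k: float = 20.0,
    ec50: dict[str, float] | None = None,
    slope_b: float = 4.0,
) -> list[TaxonParams]:
    """A single mayfly pool with one sensitivity per metal, plus a tolerant
    caddisfly.  With shared sensitivities the total-mayfly response is itself
    logistic, so pipeline-exactness tests have a closed-form truth."""
    ec50 = ec50 or {"Zn": 200.0, "Cu": 12.0, "Cd": 0.5}
    sens = {m: MetalSensitivity(float(np.log10(v)), slope_b) for m, v in ec50.items()}
    tol = {m: MetalSensitivity(float(np.log10(v * 500)), slope_b) for m, v in ec50.items()}
    return [
        TaxonParams("Mayfly pool", "Ephemeroptera/Baetidae", lambda0, dispersion_k, sens),
        TaxonParams("Brachycentrus occidentalis", "Trichoptera/Brachycentridae",
                    40.0, dispersion_k, tol),
    ]


def write_ground_truth(ground_truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth, indent=2, sort_keys=True))
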