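"""Shared domain types and the CSV interchange schemas used by every stage.

The study container mirrors the structure of a 30-day artificial-stream
("mesocosm") metal-toxicity experiment analyzed by regression rather than
ANOVA: replicated control streams plus unreplicated geometric treatment
series, end-of-test invertebrate counts per stream and taxon, dissolved-metal
time series per stream and metal, basic water chemistry, and metal residues
in periphyton, caddisfly tissue, and sediment.

CSV schemas (one file per table, UTF-8, header row required):

=============  =================================================
counts.csv     stream_id, taxon, group, count
streams.csv    stream_id, series, level, is_control, replicate
exposure.csv   stream_id, metal, day, conc_ugL, below_dl, dl_ugL
chem.csv       stream_id, hardness, doc, ph, ca
residues.csv   stream_id, compartment, metal, conc_ug_g
=============  =================================================

Flags are written as 0/1 integers.  Unknown columns are preserved on read as
opaque per-table annotations.  Metals are an open set of text codes; nothing
is hard-wired to Cd/Cu/Ni/Zn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "Taxon",
    "StreamUnit",
    "CountTable",
    "ExposureSeries",
    "WaterChemistry",
    "ResidueSample",
    "Study",
    "read_study",
    "write_study",
    "AGGREGATE_GROUP",
    "DEFAULT_DL_FRACTION",
]

#: group label marking aggregate community metrics (total mayflies, richness,
#: chlorophyll-a) that must never enter taxa screening as if they were taxa.
AGGREGATE_GROUP = "Aggregate"

#: Below-detection dissolved values are substituted at this fraction of the
#: detection limit for numeric computations (the conventional ecotoxicology
#: default); the below-detection flag is always retained.
DEFAULT_DL_FRACTION = 0.5

RESIDUE_COMPARTMENTS = ("periphyton", "tissue", "sediment")

FILE_NAMES = {
    "counts": "counts.csv",
    "streams": "streams.csv",
    "exposure": "exposure.csv",
    "chem": "chem.csv",
    "residues": "residues.csv",
}


class SchemaError(ValueError):
    """A CSV file does not conform to the documented schema."""


class ValidationError(ValueError):
    """A table violates a domain invariant (e.g. non-integer count)."""


@dataclass(frozen=True)
class Taxon:
    """A taxon or aggregate metric row.

    ``metric_flag`` marks aggregate metrics (group == "Aggregate"), which are
    fitted like taxa but excluded from per-taxon screening.
    """

    name: str
    group: str = ""

    @property
    def metric_flag(self) -> bool:
        return self.group == AGGREGATE_GROUP


@dataclass(frozen=True)
class StreamUnit:
    """One experimental stream: its treatment series and rank within it."""

    stream_id: str
    series: str
    level: int
    is_control: bool
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.is_control and self.level != 0:
            raise ValidationError(
                f"control stream {self.stream_id!r} must have level 0, got {self.level}"
            )
        if not self.is_control and self.level == 0:
            raise ValidationError(
                f"treatment stream {self.stream_id!r} must have level > 0"
            )


@dataclass
class CountTable:
    """End-of-test abundances per stream x taxon plus stream metadata.

    ``counts`` has columns (stream_id, taxon, group, count).  Absent
    (stream, taxon) pairs mean a count of zero, matching how colonization
    counts are recorded.
    """

    counts: pd.DataFrame
    streams: dict[str, StreamUnit]
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"stream_id", "taxon", "group", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise SchemaError(f"counts table missing columns: {sorted(missing)}")
        if len(self.counts) == 0:
            raise SchemaError("counts table is empty")
        vals = self.counts["count"].to_numpy()
        as_float = np.asarray(vals, dtype=float)
        if np.any(~np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
            bad = self.counts.loc[as_float != np.round(as_float), "count"].iloc[:1]
            raise ValidationError(f"counts must be integers, got {bad.tolist()}")
        if np.any(as_float < 0):
            raise ValidationError("counts must be >= 0")
        self.counts = self.counts.assign(count=as_float.astype(int))
        unknown = set(self.counts["stream_id"]) - set(self.streams)
        if unknown:
            raise SchemaError(
                f"streams referenced in counts but missing metadata: {sorted(unknown)}"
            )
        dup = self.counts.duplicated(subset=["stream_id", "taxon"])
        if dup.any():
            pair = self.counts.loc[dup, ["stream_id", "taxon"]].iloc[0].tolist()
            raise ValidationError(f"duplicate (stream, taxon) pair: {pair}")

    def taxa(self) -> list[Taxon]:
        sub = self.counts[["taxon", "group"]].drop_duplicates("taxon")
        return [Taxon(r.taxon, r.group) for r in sub.itertuples()]

    def control_ids(self) -> list[str]:
        return sorted(s.stream_id for s in self.streams.values() if s.is_control)

    def count_for(self, stream_id: str, taxon: str) -> int:
        sel = self.counts[
            (self.counts["stream_id"] == stream_id) & (self.counts["taxon"] == taxon)
        ]
        return int(sel["count"].iloc[0]) if len(sel) else 0

    def counts_by_stream(self, taxon: str, stream_ids: Iterable[str]) -> np.ndarray:
        """Counts for one taxon aligned to ``stream_ids`` (absent pairs -> 0)."""
        sub = self.counts[self.counts["taxon"] == taxon]
        lookup = dict(zip(sub["stream_id"], sub["count"]))
        return np.array([int(lookup.get(s, 0)) for s in stream_ids])

    def control_counts(self, taxon: str) -> np.ndarray:
        return self.counts_by_stream(taxon, self.control_ids())

    def total_by_group_prefix(self, prefix: str, stream_ids: Iterable[str]) -> np.ndarray:
        """Summed counts over all non-aggregate taxa whose group starts with
        ``prefix`` (e.g. 'Ephemeroptera' for total mayflies)."""
        sub = self.counts[
            self.counts["group"].str.startswith(prefix)
            & (self.counts["group"] != AGGREGATE_GROUP)
        ]
        per_stream = sub.groupby("stream_id")["count"].sum()
        return np.array([int(per_stream.get(s, 0)) for s in stream_ids])


@dataclass
class ExposureSeries:
    """Dissolved concentration of one metal in one stream over time (µg/L).

    Samples are stored sorted by day; duplicate days are rejected.  Values
    flagged below detection must carry a detection limit and are substituted
    at ``dl_fraction * detection_limit`` by :meth:`numeric_conc`.
    """

    stream_id: str
    metal: str
    days: np.ndarray
    conc: np.ndarray
    below_dl: np.ndarray | None = None
    detection_limit: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        n = len(self.days)
        if len(self.conc) != n:
            raise ValidationError("days and concentrations differ in length")
        if self.below_dl is None:
            self.below_dl = np.zeros(n, dtype=bool)
        else:
            self.below_dl = np.asarray(self.below_dl, dtype=bool)
        if self.detection_limit is None:
            self.detection_limit = np.full(n, np.nan)
        else:
            self.detection_limit = np.asarray(self.detection_limit, dtype=float)
        order = np.argsort(self.days, kind="stable")
        self.days = self.days[order]
        self.conc = self.conc[order]
        self.below_dl = self.below_dl[order]
        self.detection_limit = self.detection_limit[order]
        if n > 1 and np.any(np.diff(self.days) <= 0):
            raise ValidationError(
                f"days must be strictly increasing for stream {self.stream_id!r}"
                f" metal {self.metal!r}"
            )
        if np.any(self.days < 0):
            raise ValidationError("days must be >= 0")
        if np.any(self.conc < 0):
            raise ValidationError("concentrations must be >= 0")
        if np.any(self.below_dl & ~np.isfinite(self.detection_limit)):
            raise ValidationError(
                "below-detection samples must carry a detection limit"
            )

    def numeric_conc(self, dl_fraction: float = DEFAULT_DL_FRACTION) -> np.ndarray:
        out = self.conc.copy()
        out[self.below_dl] = dl_fraction * self.detection_limit[self.below_dl]
        return out


@dataclass(frozen=True)
class WaterChemistry:
    """Per-stream background water chemistry."""

    stream_id: str
    hardness: float  # mg/L as CaCO3
    doc: float  # mg/L
    ph: float
    calcium: float | None = None
    free_ion_fraction: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.hardness > 0:
            raise ValidationError(f"hardness must be > 0, got {self.hardness}")
        if self.free_ion_fraction is not None:
            for metal, f in self.free_ion_fraction.items():
                if not (0 < f <= 1):
                    raise ValidationError(
                        f"free ion fraction for {metal} must be in (0,1], got {f}"
                    )


@dataclass(frozen=True)
class ResidueSample:
    """Metal residue (µg/g dry weight) in one compartment of one stream."""

    stream_id: str
    compartment: str
    metal: str
    concentration: float

    def __post_init__(self) -> None:
        if self.compartment not in RESIDUE_COMPARTMENTS:
            raise ValidationError(
                f"compartment must be one of {RESIDUE_COMPARTMENTS},"
                f" got {self.compartment!r}"
            )
        if self.concentration < 0:
            raise ValidationError("residue concentration must be >= 0")


@dataclass
class Study:
    """A fully cross-referenced in-memory study."""

    counts: CountTable
    exposures: list[ExposureSeries]
    chem: list[WaterChemistry]
    residues: list[ResidueSample]

    def exposure(self, stream_id: str, metal: str) -> ExposureSeries | None:
        for s in self.exposures:
            if s.stream_id == stream_id and s.metal == metal:
                return s
        return None

    def metals(self) -> list[str]:
        return sorted({s.metal for s in self.exposures})

    def mean_hardness(self) -> float:
        return float(np.mean([c.hardness for c in self.chem]))


# ---------------------------------------------------------------------------
# CSV reading / writing


def _read_csv(path: Path, required: list[str], table: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{table} file {path} is empty") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} file {path} missing columns {missing}")
    return df


def read_study(directory: str | Path) -> Study:
    """Read a study from the documented CSV schema set in ``directory``."""
    d = Path(directory)
    streams_df = _read_csv(
        d / FILE_NAMES["streams"],
        ["stream_id", "series", "level", "is_control", "replicate"],
        "streams",
    )
    streams: dict[str, StreamUnit] = {}
    for r in streams_df.itertuples():
        sid = str(r.stream_id)
        if sid in streams:
            raise SchemaError(f"duplicate stream metadata for {sid!r}")
        streams[sid] = StreamUnit(
            sid, str(r.series), int(r.level), bool(r.is_control), int(r.replicate)
        )

    counts_df = _read_csv(
        d / FILE_NAMES["counts"], ["stream_id", "taxon", "group", "count"], "counts"
    )
    counts_df["stream_id"] = counts_df["stream_id"].astype(str)
    extra = [c for c in counts_df.columns
             if c not in ("stream_id", "taxon", "group", "count")]
    annotations = counts_df[["stream_id", "taxon"] + extra] if extra else None
    counts = CountTable(
        counts_df[["stream_id", "taxon", "group", "count"]].copy(),
        streams,
        annotations,
    )

    exposures: list[ExposureSeries] = []
    exp_path = d / FILE_NAMES["exposure"]
    if exp_path.exists():
        exp_df = _read_csv(
            exp_path,
            ["stream_id", "metal", "day", "conc_ugL", "below_dl", "dl_ugL"],
            "exposure",
        )
        exp_df["stream_id"] = exp_df["stream_id"].astype(str)
        for (sid, metal), sub in exp_df.groupby(["stream_id", "metal"], sort=True):
            if sid not in streams:
                raise SchemaError(f"exposure rows for unknown stream {sid!r}")
            days = sub["day"].to_numpy(float)
            if len(days) > 1 and np.any(np.diff(days) <= 0):
                raise ValidationError(
                    f"non-increasing days for stream {sid!r} metal {metal!r}"
                )
            exposures.append(
                ExposureSeries(
                    sid,
                    str(metal),
                    days,
                    sub["conc_ugL"].to_numpy(float),
                    sub["below_dl"].to_numpy().astype(bool),
                    sub["dl_ugL"].to_numpy(float),
                )
            )

    chem: list[WaterChemistry] = []
    chem_path = d / FILE_NAMES["chem"]
    if chem_path.exists():
        chem_df = _read_csv(chem_path, ["stream_id", "hardness", "doc", "ph"], "chem")
        for r in chem_df.itertuples():
            ca = getattr(r, "ca", None)
            chem.append(
                WaterChemistry(
                    str(r.stream_id),
                    float(r.hardness),
                    float(r.doc),
                    float(r.ph),
                    None if ca is None or pd.isna(ca) else float(ca),
                )
            )

    residues: list[ResidueSample] = []
    res_path = d / FILE_NAMES["residues"]
    if res_path.exists():
        res_df = _read_csv(
            res_path, ["stream_id", "compartment", "metal", "conc_ug_g"], "residues"
        )
        for r in res_df.itertuples():
            residues.append(
                ResidueSample(
                    str(r.stream_id), str(r.compartment), str(r.metal),
                    float(r.conc_ug_g),
                )
            )

    return Study(counts, exposures, chem, residues)


def write_study(study: Study, directory: str | Path) -> dict[str, Path]:
    """Write a study to ``directory`` using the documented CSV schemas."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    streams_rows = [
        {
            "stream_id": s.stream_id,
            "series": s.series,
            "level": s.level,
            "is_control": int(s.is_control),
            "replicate": s.replicate,
        }
        for s in sorted(study.counts.streams.values(), key=lambda s: s.stream_id)
    ]
    paths["streams"] = d / FILE_NAMES["streams"]
    pd.DataFrame(streams_rows).to_csv(paths["streams"], index=False)

    paths["counts"] = d / FILE_NAMES["counts"]
    study.counts.counts.to_csv(paths["counts"], index=False)

    exp_rows = []
    for s in study.exposures:
        for i in range(len(s.days)):
            exp_rows.append(
                {
                    "stream_id": s.stream_id,
                    "metal": s.metal,
                    "day": s.days[i],
                    "conc_ugL": repr(float(s.conc[i])),
                    "below_dl": int(s.below_dl[i]),
                    "dl_ugL": "" if np.isnan(s.detection_limit[i])
                    else repr(float(s.detection_limit[i])),
                }
            )
    paths["exposure"] = d / FILE_NAMES["exposure"]
    pd.DataFrame(exp_rows).to_csv(paths["exposure"], index=False)

    chem_rows = [
        {
            "stream_id": c.stream_id,
            "hardness": repr(c.hardness),
            "doc": repr(c.doc),
            "ph": repr(c.ph),
            "ca": "" if c.calcium is None else repr(c.calcium),
        }
        for c in study.chem
    ]
    paths["chem"] = d / FILE_NAMES["chem"]
    pd.DataFrame(chem_rows).to_csv(paths["chem"], index=False)

    res_rows = [
        {
            "stream_id": r.stream_id,
            "compartment": r.compartment,
            "metal": r.metal,
            "conc_ug_g": repr(r.concentration),
        }
        for r in study.residues
    ]
    paths["residues"] = d / FILE_NAMES["residues"]
    pd.DataFrame(res_rows).to_csv(paths["residues"], index=False)
    return paths
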