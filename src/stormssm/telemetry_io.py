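"""Detection-log ingestion and covariate construction for acoustic telemetry.

Raw inputs are per-transmission detection records (UTC timestamp, receiver,
transmitter), receiver and animal metadata, hourly environmental series and
hourly receiver diagnostics.  This module turns them into the two modelling
containers used downstream:

* :class:`HourlyDetectionMatrix` — binary transmitter x receiver x hour
  outcomes (any number of detections within an hourly bin collapses to 1);
* :class:`CovariateTable` — one row per study hour holding the environmental
  predictors (wind, significant wave height, SST, barometric pressure,
  salinity, turbidity), array-averaged receiver diagnostics (ambient noise,
  tilt), the hourly count of unique animals detected, and local hour of day,
  with each modelled column standardized to mean 0 / unit variance and the
  standardization record retained for back-transformation.

It also provides von Bertalanffy age estimation from length at tagging and
pairwise sync-tag/receiver geometry (planar Euclidean distances, with an
equirectangular projection about the array centroid when positions are given
in lon/lat; at sub-kilometre array scale the projection error is negligible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionRecord",
    "ReceiverMetadata",
    "AnimalMetadata",
    "StudyWindow",
    "HourlyDetectionMatrix",
    "CovariateTable",
    "PairGeometry",
    "VbgfParams",
    "DEFAULT_VBGF",
    "build_hourly_matrix",
    "filter_window",
    "sharks_per_hour",
    "average_diagnostics",
    "estimate_age_vbgf",
    "standardize",
    "build_pair_geometry",
    "build_covariate_table",
    "read_detections_csv",
    "read_receivers_csv",
    "read_animals_csv",
]

EARTH_RADIUS_M = 6_371_000.0

#: Modelled covariate columns (standardized for model fitting).
MODELLED_COLUMNS = (
    "wind", "waves", "sst", "baro", "sal", "turb", "noise", "tilt", "sharks",
)


@dataclass(frozen=True)
class DetectionRecord:
    """A single logged transmission: who was heard, where, and when."""

    timestamp: datetime
    receiver_id: str
    transmitter_id: str
    depth_m: float | None = None

    def __post_init__(self):
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware (UTC)")
        if not self.receiver_id or not self.transmitter_id:
            raise ValueError("receiver_id and transmitter_id must be non-empty")
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError("depth_m must be non-negative")


@dataclass(frozen=True)
class ReceiverMetadata:
    receiver_id: str
    x: float  # planar metres (or lon degrees, see ``is_lonlat``)
    y: float  # planar metres (or lat degrees)
    depth_m: float
    sync_tag_id: str | None = None
    is_lonlat: bool = False

    def __post_init__(self):
        if self.depth_m <= 0:
            raise ValueError(f"receiver {self.receiver_id}: depth_m must be > 0")

    @property
    def has_sync_tag(self) -> bool:
        return self.sync_tag_id is not None


@dataclass(frozen=True)
class AnimalMetadata:
    animal_id: str
    sex: Literal["F", "M"]
    length_cm: float
    tagging_date: datetime
    tag_family: str = ""
    age_at_event_yr: float | None = None

    def __post_init__(self):
        if self.length_cm <= 0:
            raise ValueError("length_cm must be > 0")


@dataclass(frozen=True)
class StudyWindow:
    """Contiguous hourly bins, left-closed right-open, in UTC."""

    start: datetime
    end: datetime

    def __post_init__(self):
        if self.start.tzinfo is None or self.end.tzinfo is None:
            raise ValueError("window bounds must be timezone-aware")
        if self.start >= self.end:
            raise ValueError("start must precede end")
        if self.start.minute or self.start.second or self.start.microsecond:
            raise ValueError("window start must fall on an hour boundary")

    @property
    def hours(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="h", inclusive="left")

    @property
    def n_hours(self) -> int:
        return len(self.hours)

    def contains(self, ts: datetime) -> bool:
        return self.start <= ts < self.end

    def hour_index(self, ts: datetime) -> int:
        return int((ts - self.start).total_seconds() // 3600)


def default_study_window() -> StudyWindow:
    """01 August through 10 September 2023 inclusive (984 hourly bins)."""
    return StudyWindow(
        start=datetime(2023, 8, 1, tzinfo=timezone.utc),
        end=datetime(2023, 9, 11, tzinfo=timezone.utc),
    )


def default_storm_window() -> StudyWindow:
    """Peak-disturbance window: 2023-08-20 08:00 to 2023-08-21 08:00 UTC."""
    return StudyWindow(
        start=datetime(2023, 8, 20, 8, tzinfo=timezone.utc),
        end=datetime(2023, 8, 21, 8, tzinfo=timezone.utc),
    )


@dataclass
class HourlyDetectionMatrix:
    """Binary detection outcomes y[transmitter, receiver, hour]."""

    transmitters: list[str]
    receivers: list[str]
    window: StudyWindow
    values: np.ndarray  # uint8, shape (n_trans, n_recv, n_hours)

    def __post_init__(self):
        expected = (len(self.transmitters), len(self.receivers), self.window.n_hours)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix values must be strictly binary")

    @property
    def n_hours(self) -> int:
        return self.window.n_hours

    def restrict(self, transmitters: Sequence[str]) -> "HourlyDetectionMatrix":
        idx = [self.transmitters.index(t) for t in transmitters]
        return HourlyDetectionMatrix(
            list(transmitters), list(self.receivers), self.window, self.values[idx]
        )

    def to_long_frame(self) -> pd.DataFrame:
        hours = self.window.hours
        ti, ri, hi = np.meshgrid(
            np.arange(len(self.transmitters)),
            np.arange(len(self.receivers)),
            np.arange(self.n_hours),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "transmitter": np.asarray(self.transmitters)[ti.ravel()],
                "receiver": np.asarray(self.receivers)[ri.ravel()],
                "hour_start": hours[hi.ravel()],
                "detected": self.values.ravel(),
            }
        )


@dataclass
class StandardizationRecord:
    mean: float
    sd: float

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.mean) / self.sd

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized, dtype=float) * self.sd + self.mean


def standardize(series, name: str = "series") -> tuple[np.ndarray, StandardizationRecord]:
    """Centre and scale to sample mean 0 / sample variance 1 (n-1 denominator)."""
    a = np.asarray(series, dtype=float)
    if a.size < 2:
        raise ValueError(f"{name}: need at least 2 values to standardize")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name}: non-finite values present")
    mu = float(a.mean())
    sd = float(a.std(ddof=1))
    if sd == 0.0:
        raise ValueError(f"{name}: zero variance, cannot standardize")
    rec = StandardizationRecord(mean=mu, sd=sd)
    return rec.apply(a), rec


@dataclass
class CovariateTable:
    """Hourly predictors over a study window.

    ``raw`` holds original units; ``standardized`` the modelled z-scored
    columns; ``records`` the per-column means/sds used (for back-transforming
    coefficients).  ``hour_local`` (0-23) and the raw ``sharks`` count are kept
    alongside their transformed versions.
    """

    window: StudyWindow
    raw: pd.DataFrame
    standardized: pd.DataFrame
    records: dict[str, StandardizationRecord]
    utc_offset_hours: int = -7

    def __post_init__(self):
        if len(self.raw) != self.window.n_hours:
            raise ValueError("covariate table must have one row per study hour")

    @property
    def hour_local(self) -> np.ndarray:
        """Local hour of day (default UTC-7) for the diel cycle."""
        return (self.window.hours.hour.to_numpy() + self.utc_offset_hours) % 24

    def z(self, name: str) -> np.ndarray:
        return self.standardized[name].to_numpy()

    def z_matrix(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.standardized.columns]
        if missing:
            raise KeyError(f"missing standardized covariates: {missing}")
        return self.standardized[list(names)].to_numpy()


def filter_window(records: Iterable[DetectionRecord], window: StudyWindow) -> list[DetectionRecord]:
    """Keep records with start <= timestamp < end, preserving order."""
    return [r for r in records if window.contains(r.timestamp)]


def build_hourly_matrix(
    records: Iterable[DetectionRecord],
    transmitters: Sequence[str],
    receivers: Sequence[str],
    window: StudyWindow,
    unknown_ids: Literal["drop", "error"] = "drop",
) -> HourlyDetectionMatrix:
    """Collapse raw detections into the binary hourly matrix.

    y[i, j, t] = 1 iff at least one record of transmitter i on receiver j
    falls in hourly bin t; records outside the window are dropped.
    """
    if not transmitters or not receivers:
        raise ValueError("transmitter and receiver lists must be non-empty")
    t_idx = {t: i for i, t in enumerate(transmitters)}
    r_idx = {r: i for i, r in enumerate(receivers)}
    values = np.zeros((len(transmitters), len(receivers), window.n_hours), dtype=np.uint8)
    n_unknown = 0
    for rec in records:
        if not window.contains(rec.timestamp):
            continue
        ti = t_idx.get(rec.transmitter_id)
        ri = r_idx.get(rec.receiver_id)
        if ti is None or ri is None:
            if unknown_ids == "error":
                raise KeyError(
                    f"unknown transmitter/receiver in record: "
                    f"{rec.transmitter_id}/{rec.receiver_id}"
                )
            n_unknown += 1
            continue
        values[ti, ri, window.hour_index(rec.timestamp)] = 1
    return HourlyDetectionMatrix(list(transmitters), list(receivers), window, values)


def sharks_per_hour(matrix: HourlyDetectionMatrix) -> np.ndarray:
    """Number of unique animals detected anywhere in the array, per hour."""
    return matrix.values.any(axis=1).sum(axis=0).astype(int)


def average_diagnostics(
    per_receiver: pd.DataFrame,
    window: StudyWindow,
    value_columns: Sequence[str] = ("noise_mv", "tilt_deg"),
    max_gap_hours: int = 6,
) -> pd.DataFrame:
    """Hourly arithmetic mean of receiver diagnostics across reporting units.

    ``per_receiver`` is long format with columns ``timestamp, receiver_id``
    plus the value columns; hours where a receiver did not report are simply
    excluded from that hour's mean.  Hours with *no* reporting receiver are
    linearly interpolated up to ``max_gap_hours`` consecutive hours; longer
    gaps raise.
    """
    df = per_receiver.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.floor("h")
    means = df.groupby("timestamp")[list(value_columns)].mean()
    means = means.reindex(window.hours)
    for col in value_columns:
        s = means[col]
        if s.isna().any():
            gap_sizes = s.isna().astype(int).groupby(s.notna().cumsum()).sum()
            if int(gap_sizes.max()) > max_gap_hours:
                raise ValueError(
                    f"diagnostic {col!r}: gap of {int(gap_sizes.max())} h exceeds "
                    f"max_gap_hours={max_gap_hours}"
                )
            means[col] = s.interpolate(limit_direction="both")
    means.index.name = "hour_start"
    return means


@dataclass(frozen=True)
class VbgfParams:
    """Von Bertalanffy growth parameters: L(t) = L_inf * (1 - exp(-k (t - t0)))."""

    L_inf_cm: float = 763.7
    k_per_yr: float = 0.058
    t0_yr: float = -3.53

    def __post_init__(self):
        if self.k_per_yr <= 0:
            raise ValueError("k_per_yr must be > 0")
        if self.L_inf_cm <= 0:
            raise ValueError("L_inf_cm must be > 0")


DEFAULT_VBGF = VbgfParams()

DAYS_PER_YEAR = 365.25


def estimate_age_vbgf(
    length_cm: float,
    tagging_date: datetime,
    event_date: datetime,
    params: VbgfParams = DEFAULT_VBGF,
    round_to: float | None = None,
) -> float:
    """Age at ``event_date`` from length at tagging, via the inverted growth curve.

    age_at_tagging = t0 - (1/k) * ln(1 - L / L_inf), then elapsed calendar time
    (in 365.25-day years) is added.
    """
    if length_cm >= params.L_inf_cm:
        raise ValueError(f"length {length_cm} cm >= asymptotic length {params.L_inf_cm} cm")
    if length_cm <= 0:
        raise ValueError("length_cm must be > 0")
    if event_date < tagging_date:
        raise ValueError("event_date must not precede tagging_date")
    age_at_tagging = params.t0_yr - math.log(1.0 - length_cm / params.L_inf_cm) / params.k_per_yr
    elapsed_yr = (event_date - tagging_date).days / DAYS_PER_YEAR
    age = age_at_tagging + elapsed_yr
    if round_to is not None:
        age = round(age / round_to) * round_to
    return age


@dataclass
class PairGeometry:
    """Admissible sync-tag/receiver pairs with distances and standardized statics."""

    pairs: list[tuple[str, str]]  # (sync_tag_id, receiver_id)
    distance_m: np.ndarray
    depth_m: np.ndarray
    log_distance_z: np.ndarray
    depth_z: np.ndarray
    log_distance_record: StandardizationRecord
    depth_record: StandardizationRecord

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _planar_positions(receivers: Sequence[ReceiverMetadata]) -> np.ndarray:
    xy = np.array([[r.x, r.y] for r in receivers], dtype=float)
    if receivers[0].is_lonlat:
        lon0, lat0 = xy[:, 0].mean(), xy[:, 1].mean()
        coslat = math.cos(math.radians(lat0))
        x = np.radians(xy[:, 0] - lon0) * coslat * EARTH_RADIUS_M
        y = np.radians(xy[:, 1] - lat0) * EARTH_RADIUS_M
        return np.column_stack([x, y])
    return xy


def build_pair_geometry(
    receivers: Sequence[ReceiverMetadata],
    max_distance_m: float = 800.0,
) -> PairGeometry:
    """All (sync tag, other receiver) pairs within ``max_distance_m``.

    Self-pairs (a receiver hearing its own internal tag, distance 0) are
    excluded; log-distance is natural log, standardized after the transform.
    """
    pos = _planar_positions(receivers)
    sync = [(i, r) for i, r in enumerate(receivers) if r.has_sync_tag]
    if not sync:
        raise ValueError("no sync-tag receivers in metadata")
    pairs, dist, depth = [], [], []
    for si, sr in sync:
        for rj, rr in enumerate(receivers):
            if rj == si:
                continue
            d = float(np.hypot(*(pos[si] - pos[rj])))
            if d <= 0:
                raise ValueError(
                    f"coincident stations {sr.receiver_id}/{rr.receiver_id}"
                )
            if d > max_distance_m:
                continue
            pairs.append((sr.sync_tag_id, rr.receiver_id))
            dist.append(d)
            depth.append(rr.depth_m)
    if len(pairs) < 2:
        raise ValueError("fewer than 2 admissible sync tag-receiver pairs")
    dist_a = np.asarray(dist)
    depth_a = np.asarray(depth)
    logd_z, logd_rec = standardize(np.log(dist_a), "log_distance")
    try:
        depth_z, depth_rec = standardize(depth_a, "depth")
    except ValueError:
        # flat array (all receivers at one depth): depth carries no contrast
        depth_rec = StandardizationRecord(mean=float(depth_a.mean()), sd=1.0)
        depth_z = depth_a - depth_rec.mean
    return PairGeometry(pairs, dist_a, depth_a, logd_z, depth_z, logd_rec, depth_rec)


def build_covariate_table(
    environment: pd.DataFrame,
    diagnostics: pd.DataFrame,
    sharks: np.ndarray,
    window: StudyWindow,
    utc_offset_hours: int = -7,
    max_gap_hours: int = 6,
) -> CovariateTable:
    """Assemble and standardize the hourly covariate table.

    ``environment`` columns: ``timestamp, wind_ms, waves_m, sst_c, baro_hpa,
    sal_psu, turb_fnu``; ``diagnostics`` is the long per-receiver noise/tilt
    frame (see :func:`average_diagnostics`); ``sharks`` the per-hour unique
    animal count from :func:`sharks_per_hour`.
    """
    env = environment.copy()
    env["timestamp"] = pd.to_datetime(env["timestamp"], utc=True).dt.floor("h")
    env = env.groupby("timestamp").mean().reindex(window.hours)
    rename = {
        "wind_ms": "wind", "waves_m": "waves", "sst_c": "sst",
        "baro_hpa": "baro", "sal_psu": "sal", "turb_fnu": "turb",
    }
    env = env.rename(columns=rename)[list(rename.values())]
    for col in env.columns:
        s = env[col]
        if s.isna().any():
            gap = int(s.isna().astype(int).groupby(s.notna().cumsum()).sum().max())
            if gap > max_gap_hours:
                raise ValueError(f"covariate {col!r}: gap of {gap} h exceeds {max_gap_hours}")
            env[col] = s.interpolate(limit_direction="both")

    diag = average_diagnostics(diagnostics, window, max_gap_hours=max_gap_hours)
    raw = env.copy()
    raw["noise"] = diag["noise_mv"].to_numpy()
    raw["tilt"] = diag["tilt_deg"].to_numpy()
    sharks = np.asarray(sharks, dtype=float)
    if sharks.shape != (window.n_hours,):
        raise ValueError("sharks series must have one value per study hour")
    raw["sharks"] = sharks
    raw.index = window.hours
    raw.index.name = "hour_start"

    std = pd.DataFrame(index=raw.index)
    records: dict[str, StandardizationRecord] = {}
    for col in MODELLED_COLUMNS:
        std[col], records[col] = standardize(raw[col].to_numpy(), col)
    return CovariateTable(
        window=window, raw=raw, standardized=std, records=records,
        utc_offset_hours=utc_offset_hours,
    )


# ---------------------------------------------------------------------------
# CSV readers (plain-text interchange schemas)
# ---------------------------------------------------------------------------

def read_detections_csv(path) -> list[DetectionRecord]:
    """Read ``timestamp,receiver_id,transmitter_id[,depth_m]`` (ISO-8601 UTC)."""
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    if ts.isna().any():
        raise ValueError(f"unparseable timestamps in {path}")
    depth = df["depth_m"] if "depth_m" in df.columns else pd.Series([None] * len(df))
    return [
        DetectionRecord(
            timestamp=t.to_pydatetime(),
            receiver_id=str(r),
            transmitter_id=str(x),
            depth_m=None if pd.isna(d) else float(d),
        )
        for t, r, x, d in zip(ts, df["receiver_id"], df["transmitter_id"], depth)
    ]


def read_receivers_csv(path) -> list[ReceiverMetadata]:
    """Read ``receiver_id,x,y,depth_m,sync_tag_id`` (or lon/lat columns)."""
    df = pd.read_csv(path)
    lonlat = "lon" in df.columns
    xcol, ycol = ("lon", "lat") if lonlat else ("x", "y")
    out = []
    for _, row in df.iterrows():
        sync = row.get("sync_tag_id")
        out.append(
            ReceiverMetadata(
                receiver_id=str(row["receiver_id"]),
                x=float(row[xcol]),
                y=float(row[ycol]),
                depth_m=float(row["depth_m"]),
                sync_tag_id=None if pd.isna(sync) or sync == "" else str(sync),
                is_lonlat=lonlat,
            )
        )
    return out


def read_animals_csv(path) -> list[AnimalMetadata]:
    """Read ``animal_id,sex,length_cm,tagging_date,tag_family``."""
    df = pd.read_csv(path)
    return [
        AnimalMetadata(
            animal_id=str(r["animal_id"]),
            sex=str(r["sex"]),
            length_cm=float(r["length_cm"]),
            tagging_date=pd.to_datetime(r["tagging_date"], utc=True).to_pydatetime(),
            tag_family=str(r.get("tag_family", "")),
        )
        for _, r in df.iterrows()
    ]
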