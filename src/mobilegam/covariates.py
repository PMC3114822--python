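"""Assembly of the per-minute modeling table.

Streams: mobile observations (1-min), traffic counts (15-min, disaggregated
to minutes at 1/15 of the interval count), fixed-site weather (1-min), and
road geometries.  The joined table carries the natural-log pollutant
concentration, linear covariates, distances to each road (effective distance
for elevated roads, horizontal otherwise), wind-sector labels and
within-shift elapsed time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry

log = logging.getLogger(__name__)

POLLUTANT_COLUMNS = {"ufp": "ufp_pcc", "pm25": "pm25_ugm3", "pah": "pah_ngm3"}

# Floors for abnormally low instrument readings; there are no universal
# thresholds, so these are package defaults on the instruments' native scales.
DEFAULT_FLOORS = {"ufp": 1000.0, "pm25": 1.0, "pah": 0.5}


@dataclass
class QCConfig:
    """Thresholds for the low-reading / out-of-session filter."""

    floors: dict = field(default_factory=lambda: dict(DEFAULT_FLOORS))
    max_exclusion_warn: float = 0.05


@dataclass
class ModelFrame:
    """Aligned per-minute design rows for one pollutant.

    ``data`` holds one row per usable backpack-minute with columns:
    y, traffic_<road>, wind_speed, temperature, rh, day_id, shift_id,
    operator_id, d_<road>, easting, northing, t_shift, sector_<road>,
    plus any vehicle-class/speed traffic columns for sensitivity fits.
    """

    data: pd.DataFrame
    road_ids: list
    pollutant: str
    elevated: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        return self.data[["easting", "northing"]].to_numpy()

    def subset(self, mask) -> "ModelFrame":
        return ModelFrame(self.data.loc[mask].reset_index(drop=True),
                          list(self.road_ids), self.pollutant, dict(self.elevated))


def disaggregate_traffic(intervals: pd.DataFrame) -> pd.DataFrame:
    """Spread 15-min counts uniformly over their minutes (1/15 per minute).

    Parameters
    ----------
    intervals : DataFrame
        Columns ``counter_id``, ``start_iso`` (or ``start``), and one or
        more ``count_*`` columns.  Intervals must not overlap per counter.

    Returns
    -------
    DataFrame with columns counter_id, timestamp (minute), and each count
    column divided by 15 (fractional vehicles/min).  Minutes not covered by
    any interval are simply absent (treated as missing downstream).
    """
    df = intervals.copy()
    start_col = "start_iso" if "start_iso" in df.columns else "start"
    df["start"] = pd.to_datetime(df[start_col])
    count_cols = [c for c in df.columns if c.startswith("count_")]
    dur = int(df["duration"].iloc[0]) if "duration" in df.columns else 15

    for cid, grp in df.groupby("counter_id"):
        starts = grp["start"].sort_values()
        if (starts.diff().dt.total_seconds().dropna() < dur * 60).any():
            raise ValueError(f"overlapping traffic intervals for counter {cid!r}")

    n = len(df)
    rep = df.loc[df.index.repeat(dur)].reset_index(drop=True)
    offsets = np.tile(np.arange(dur), n)
    rep["timestamp"] = rep["start"] + pd.to_timedelta(offsets, unit="min")
    for c in count_cols:
        rep[c] = rep[c] / float(dur)
    return rep[["counter_id", "timestamp"] + count_cols]


def qc_filter(observations: pd.DataFrame, sessions: pd.DataFrame,
              config: QCConfig | None = None):
    """Drop rows outside their shift's session window or with abnormally
    low pollutant readings.

    Parameters
    ----------
    observations : DataFrame with the observations-CSV columns.
    sessions : DataFrame with shift_id, start, end (timestamps).
    config : QCConfig, optional.

    Returns
    -------
    (filtered DataFrame, report DataFrame with columns reason, n_removed)

    A warning is emitted when the exclusion fraction exceeds the configured
    limit (a well-run campaign loses under 5% of its rows).
    """
    config = config or QCConfig()
    obs = observations.copy()
    obs["timestamp"] = pd.to_datetime(obs["timestamp_iso"])
    sess = sessions.copy()
    sess["start"] = pd.to_datetime(sess["start"])
    sess["end"] = pd.to_datetime(sess["end"])
    merged = obs.merge(sess[["shift_id", "start", "end"]], on="shift_id", how="left")

    outside = (merged["timestamp"] < merged["start"]) | \
              (merged["timestamp"] > merged["end"]) | merged["start"].isna()
    low = np.zeros(len(merged), dtype=bool)
    for pol, col in POLLUTANT_COLUMNS.items():
        if col in merged.columns and pol in config.floors:
            vals = merged[col]
            low |= (vals.notna() & (vals < config.floors[pol])).to_numpy()
    low &= ~outside.to_numpy()  # reasons partition the removed set

    report = pd.DataFrame({
        "reason": ["outside_session", "low_reading"],
        "n_removed": [int(outside.sum()), int(low.sum())],
    })
    frac = (outside.to_numpy() | low).mean() if len(merged) else 0.0
    if frac > config.max_exclusion_warn:
        warnings.warn(
            f"QC excluded {frac:.1%} of rows, above the "
            f"{config.max_exclusion_warn:.0%} threshold", stacklevel=2)
    keep = merged.loc[~(outside.to_numpy() | low), observations.columns]
    return keep.reset_index(drop=True), report


def median_split(frame: ModelFrame, column: str) -> np.ndarray:
    """High/low flag by the column's median; ties go to LOW."""
    vals = frame.data[column].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(f"column {column!r} has missing values")
    return vals > np.median(vals)


def assemble_frame(observations: pd.DataFrame, traffic: pd.DataFrame,
                   weather: pd.DataFrame, sessions: pd.DataFrame, roads: list,
                   pollutant: str, qc: QCConfig | None = None,
                   counters: dict | None = None):
    """QC-filter, disaggregate traffic, and build the model frame in one
    call.  Returns (ModelFrame, qc report)."""
    filtered, report = qc_filter(observations, sessions, qc)
    per_min = disaggregate_traffic(traffic)
    frame = build_model_frame(filtered, per_min, weather, roads, pollutant,
                              counters=counters)
    return frame, report


def build_model_frame(observations: pd.DataFrame, traffic_per_min: pd.DataFrame,
                      weather: pd.DataFrame, roads: list, pollutant: str,
                      counters: dict | None = None) -> ModelFrame:
    """Join all streams on the minute and derive distances and sectors.

    Parameters
    ----------
    observations : QC-filtered observations (CSV dialect columns).
    traffic_per_min : output of :func:`disaggregate_traffic`.
    weather : DataFrame with timestamp, wind_speed_ms, wind_dir_deg.
    roads : list of RoadSource (exactly the roads entering the model).
    pollutant : "ufp", "pm25" or "pah" — sets y = ln(concentration).
    counters : optional {road_id: [counter_id, ...]} overriding each road's
        attached counter subset (counts are summed over the subset).

    Rows with any unmatched stream are dropped with a logged count.
    """
    pol_col = POLLUTANT_COLUMNS[pollutant]
    obs = observations.copy()
    obs["timestamp"] = pd.to_datetime(obs["timestamp_iso"])
    if (obs[pol_col] <= 0).any():
        n_bad = int((obs[pol_col] <= 0).sum())
        log.info("dropping %d rows with non-positive %s", n_bad, pol_col)
        obs = obs[obs[pol_col] > 0]

    wx = weather.copy()
    ts_col = "timestamp_iso" if "timestamp_iso" in wx.columns else "timestamp"
    wx["timestamp"] = pd.to_datetime(wx[ts_col])
    wx = wx[["timestamp", "wind_speed_ms", "wind_dir_deg"]]

    tr = traffic_per_min.copy()
    tr["timestamp"] = pd.to_datetime(tr["timestamp"])
    count_cols = [c for c in tr.columns if c.startswith("count_")]

    n0 = len(obs)
    df = obs.merge(wx, on="timestamp", how="inner")

    # Per-road traffic: sum the configured counter subset, minute by minute.
    for road in roads:
        ids = (counters or {}).get(road.id, road.counter_ids)
        sub = tr[tr["counter_id"].isin(ids)]
        agg = sub.groupby("timestamp")[count_cols].sum()
        n_counters = sub.groupby("timestamp")["counter_id"].nunique()
        agg = agg[n_counters == len(ids)]  # require the full subset
        agg = agg.rename(columns={c: c.replace("count", f"traffic_{road.id}")
                                  for c in count_cols})
        df = df.merge(agg.reset_index(), on="timestamp", how="inner")
        df = df.rename(columns={f"traffic_{road.id}_total": f"traffic_{road.id}"})

    if df.empty:
        raise ValueError("empty join: observation, weather and traffic clocks "
                         "do not align")
    if len(df) < n0:
        log.info("dropped %d rows lacking a matching weather or traffic minute",
                 n0 - len(df))

    pts = df[["easting_m", "northing_m"]].to_numpy(dtype=float)
    elevated = {}
    for road in roads:
        elevated[road.id] = road.elevated
        if road.elevated:
            d = geometry.effective_distance_array(pts, road)
        else:
            d = geometry.nearest_distance_array(pts, road)
        df[f"d_{road.id}"] = d
        df[f"sector_{road.id}"] = geometry.wind_sector_array(
            pts, road, df["wind_speed_ms"].to_numpy(),
            df["wind_dir_deg"].to_numpy())

    df["y"] = np.log(df[pol_col].to_numpy(dtype=float))
    df = df.rename(columns={"easting_m": "easting", "northing_m": "northing",
                            "wind_speed_ms": "wind_speed", "temp_c": "temperature",
                            "rh_pct": "rh"})
    shift_start = df.groupby("shift_id")["timestamp"].transform("min")
    df["t_shift"] = (df["timestamp"] - shift_start).dt.total_seconds() / 60.0

    df = df.sort_values(["timestamp", "operator_id"], kind="mergesort")
    df = df.reset_index(drop=True)
    keep = (["timestamp", "y", "easting", "northing", "wind_speed", "temperature",
             "rh", "day_id", "shift_id", "operator_id", "t_shift"]
            + [c for c in df.columns if c.startswith(("d_", "sector_", "traffic_"))])
    if not np.isfinite(df["y"]).all():
        raise ValueError("non-finite log concentrations after join")
    return ModelFrame(df[keep], [r.id for r in roads], pollutant, elevated)
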