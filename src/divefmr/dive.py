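"""Time-depth-recorder (TDR) processing: from raw depth samples to dives,
bouts, foraging trips, and the per-trip behavioral summaries.

The hierarchy is DepthTrace -> Dive -> Bout -> Trip. Dives are submergences
reaching at least 4 m for at least 16 s (both configurable); bouts group dives
separated by short surface intervals under a bout-ending criterion (fixed or
estimated from the log-survivorship curve of inter-dive intervals); trips are
at-sea periods delimited by haul-outs, retained when longer than 6 hr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .solar import is_daytime

__all__ = [
    "DepthTrace",
    "Dive",
    "Bout",
    "Trip",
    "TrackFix",
    "BoutCriterionSpec",
    "zero_offset_correct",
    "detect_dives",
    "detect_bouts",
    "bout_criterion_survivorship",
    "segment_trips",
    "classify_day_night",
    "classify_benthic",
    "trip_metrics",
    "strategy_variables",
    "filter_track",
    "interpolate_hourly",
    "TRIP_METRIC_NAMES",
    "STRATEGY_VARIABLE_NAMES",
]

_EPOCH = np.datetime64("1970-01-01T00:00:00", "s")


def _seconds(t: np.ndarray) -> np.ndarray:
    return (np.asarray(t, dtype="datetime64[s]") - _EPOCH).astype(float)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DepthTrace:
    """An ordered depth record. ``times`` datetime64, ``depth_m`` positive-down."""

    animal_id: str
    times: np.ndarray
    depth_m: np.ndarray
    sampling_interval_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.times.shape != self.depth_m.shape:
            raise ValueError("times and depth_m must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times).astype(float) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class Dive:
    start: np.datetime64
    end: np.datetime64
    max_depth: float
    duration_s: float
    descent_rate: float
    ascent_rate: float
    bottom_time_s: float
    is_day: bool | None = None
    is_benthic: bool | None = None


@dataclass
class Bout:
    dives: list[Dive]

    @property
    def start(self) -> np.datetime64:
        return self.dives[0].start

    @property
    def end(self) -> np.datetime64:
        return self.dives[-1].end

    @property
    def duration_hr(self) -> float:
        return float((self.end - self.start).astype("timedelta64[s]").astype(float)) / 3600.0


@dataclass
class Trip:
    animal_id: str
    start: np.datetime64
    end: np.datetime64
    dives: list[Dive] = field(default_factory=list)
    bouts: list[Bout] = field(default_factory=list)

    @property
    def duration_hr(self) -> float:
        return float((self.end - self.start).astype("timedelta64[s]").astype(float)) / 3600.0


@dataclass(frozen=True)
class TrackFix:
    time: np.datetime64
    lat: float
    lon: float
    source: Literal["gps", "argos"] = "gps"

    def __post_init__(self) -> None:
        if not (-90 <= self.lat <= 90) or not (-180 <= self.lon <= 180):
            raise ValueError(f"invalid coordinates ({self.lat}, {self.lon})")


@dataclass(frozen=True)
class BoutCriterionSpec:
    """Bout-ending criterion: a fixed surface interval (s), or estimated per
    deployment by a two-process broken-stick fit to the log-survivorship curve
    of inter-dive intervals (falling back to ``fixed_s`` when the fit is
    under-determined)."""

    mode: Literal["fixed", "survivorship"] = "survivorship"
    fixed_s: float = 600.0


# ---------------------------------------------------------------------------
# zero-offset correction
# ---------------------------------------------------------------------------

def zero_offset_correct(
    trace: DepthTrace,
    window_s: float = 6 * 3600.0,
    surface_max_m: float = 10.0,
    quantile: float = 0.10,
) -> DepthTrace:
    """Remove pressure-transducer drift so surface intervals read 0 m.

    A rolling surface baseline is estimated per time window as a low quantile
    of the near-surface readings (depth < ``surface_max_m``), linearly
    interpolated across window centres, and subtracted. Corrected depths are
    floored at 0.
    """
    if len(trace.depth_m) == 0:
        raise ValueError("empty trace")
    t = _seconds(trace.times)
    depth = trace.depth_m
    edges = np.arange(t[0], t[-1] + window_s, window_s)
    centers, baselines = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (t >= lo) & (t < hi) & (depth < surface_max_m)
        if np.any(m):
            centers.append(0.5 * (lo + hi))
            baselines.append(np.quantile(depth[m], quantile))
    if not centers:
        warnings.warn("no near-surface samples; returning trace unchanged")
        return trace
    baseline = np.interp(t, centers, baselines)
    corrected = np.maximum(depth - baseline, 0.0)
    return DepthTrace(trace.animal_id, trace.times, corrected, trace.sampling_interval_s)


# ---------------------------------------------------------------------------
# dive detection
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_index, last_index) pairs."""
    if not np.any(mask):
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return [(int(a), int(b - 1)) for a, b in zip(idx[::2], idx[1::2])]


def detect_dives(
    trace: DepthTrace,
    depth_min_m: float = 4.0,
    duration_min_s: float = 16.0,
    surface_threshold_m: float = 1.0,
    bottom_fraction: float = 0.8,
) -> list[Dive]:
    """Detect dives on a zero-offset-corrected trace.

    A submergence is a maximal run of samples deeper than
    ``surface_threshold_m``; it is a dive when its maximum depth reaches
    ``depth_min_m`` and its duration is at least ``duration_min_s``. Each
    sample is taken to represent the interval [t, t + dt), so a run of n
    samples at spacing dt has duration n * dt.

    The bottom phase is the span of samples deeper than ``bottom_fraction`` of
    the dive's maximum depth; descent rate is depth at bottom-phase entry over
    the descent time (ascent symmetric).
    """
    if len(trace.depth_m) == 0:
        return []
    t = _seconds(trace.times)
    depth = trace.depth_m
    dt = trace.sampling_interval_s
    dives: list[Dive] = []
    for i0, i1 in _runs(depth > surface_threshold_m):
        seg = depth[i0 : i1 + 1]
        max_depth = float(seg.max())
        duration = t[i1] - t[i0] + dt
        if max_depth < depth_min_m or duration < duration_min_s:
            continue
        bottom = np.flatnonzero(seg >= bottom_fraction * max_depth)
        ib0, ib1 = int(bottom[0]), int(bottom[-1])
        descent_time = max(t[i0 + ib0] - t[i0], dt)
        ascent_time = max(t[i1] - t[i0 + ib1] + dt, dt)
        dives.append(
            Dive(
                start=trace.times[i0],
                end=trace.times[i1] + np.timedelta64(int(round(dt)), "s"),
                max_depth=max_depth,
                duration_s=float(duration),
                descent_rate=float(seg[ib0] / descent_time),
                ascent_rate=float(seg[ib1] / ascent_time),
                bottom_time_s=float(t[i0 + ib1] - t[i0 + ib0] + dt),
            )
        )
    return dives


# ---------------------------------------------------------------------------
# bouts
# ---------------------------------------------------------------------------

def _surface_intervals_s(dives: Sequence[Dive]) -> np.ndarray:
    starts = _seconds(np.array([d.start for d in dives]))
    ends = _seconds(np.array([d.end for d in dives]))
    return starts[1:] - ends[:-1]


def bout_criterion_survivorship(
    intervals_s: np.ndarray, fallback_s: float = 600.0, min_intervals: int = 20
) -> float:
    """Bout-ending criterion from a broken-stick fit to log survivorship.

    Inter-dive surface intervals are modelled as a mixture of a fast
    (within-bout) and a slow (between-bout) Poisson process; on the
    log-survivorship curve these appear as two straight lines. The criterion
    is the abscissa of the intersection of the two least-squares lines, with
    the breakpoint chosen to minimize total squared error. Falls back to
    ``fallback_s`` when intervals are too few or the fit degenerates.
    """
    x = np.sort(np.asarray(intervals_s, dtype=float))
    if len(x) < min_intervals or x[0] == x[-1]:
        return fallback_s
    # survivorship at each sorted interval: fraction strictly greater
    n = len(x)
    surv = (n - np.arange(1, n + 1) + 1) / n
    y = np.log(surv)
    def line_fit(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, float]:
        xm, ym = xs.mean(), ys.mean()
        denom = np.sum((xs - xm) ** 2)
        slope = np.sum((xs - xm) * (ys - ym)) / denom if denom > 0 else 0.0
        intercept = ym - slope * xm
        sse = float(np.sum((slope * xs + intercept - ys) ** 2))
        return np.array([slope, intercept]), sse

    best = None
    for b in range(3, n - 3):
        p1, sse1 = line_fit(x[:b], y[:b])
        p2, sse2 = line_fit(x[b:], y[b:])
        if best is None or sse1 + sse2 < best[0]:
            best = (sse1 + sse2, p1, p2)
    if best is None:
        return fallback_s
    _, p1, p2 = best
    if p1[0] >= 0 or p2[0] >= 0 or np.isclose(p1[0], p2[0]):
        return fallback_s
    crit = (p2[1] - p1[1]) / (p1[0] - p2[0])
    if not (x[0] < crit < x[-1]):
        return fallback_s
    return float(crit)


def detect_bouts(
    dives: Sequence[Dive], criterion: BoutCriterionSpec | float = BoutCriterionSpec()
) -> list[Bout]:
    """Partition time-ordered dives into bouts.

    Consecutive dives stay in the same bout while the surface interval
    between them does not exceed the bout-ending criterion.
    """
    dives = list(dives)
    if not dives:
        return []
    if len(dives) == 1:
        return [Bout(dives=dives)]
    gaps = _surface_intervals_s(dives)
    if isinstance(criterion, (int, float)):
        crit = float(criterion)
    elif criterion.mode == "fixed":
        crit = criterion.fixed_s
    else:
        crit = bout_criterion_survivorship(gaps, fallback_s=criterion.fixed_s)
    bouts: list[Bout] = []
    current = [dives[0]]
    for dive, gap in zip(dives[1:], gaps):
        if gap <= crit:
            current.append(dive)
        else:
            bouts.append(Bout(dives=current))
            current = [dive]
    bouts.append(Bout(dives=current))
    return bouts


# ---------------------------------------------------------------------------
# trips
# ---------------------------------------------------------------------------

def segment_trips(
    trace: DepthTrace,
    dives: Sequence[Dive],
    haulout_gap_hr: float = 0.5,
    dry_threshold_m: float = 1.0,
    min_trip_hr: float = 6.0,
    bout_criterion: BoutCriterionSpec | float = BoutCriterionSpec(),
) -> list[Trip]:
    """Split the record into foraging trips at haul-out periods.

    A haul-out is a maximal run of near-surface samples
    (depth < ``dry_threshold_m``) lasting at least ``haulout_gap_hr``. At-sea
    periods between haul-outs become trips when longer than ``min_trip_hr``
    (default 6 hr, shorter excursions are not foraging trips); each trip
    carries its dives and their bout partition.
    """
    t = _seconds(trace.times)
    dt = trace.sampling_interval_s
    dry_runs = [
        (i0, i1)
        for i0, i1 in _runs(trace.depth_m < dry_threshold_m)
        if (t[i1] - t[i0] + dt) >= haulout_gap_hr * 3600.0
    ]
    # at-sea spans between consecutive haul-outs (and record edges)
    bounds = []
    prev_end = 0
    for i0, i1 in dry_runs:
        if i0 > prev_end:
            bounds.append((prev_end, i0 - 1))
        prev_end = i1 + 1
    if prev_end < len(t):
        bounds.append((prev_end, len(t) - 1))

    dive_starts = _seconds(np.array([d.start for d in dives])) if dives else np.array([])
    trips: list[Trip] = []
    for i0, i1 in bounds:
        duration_hr = (t[i1] - t[i0] + dt) / 3600.0
        if duration_hr <= min_trip_hr:
            continue
        in_trip = [
            d
            for d, s in zip(dives, dive_starts)
            if t[i0] <= s <= t[i1]
        ]
        trips.append(
            Trip(
                animal_id=trace.animal_id,
                start=trace.times[i0],
                end=trace.times[i1] + np.timedelta64(int(round(dt)), "s"),
                dives=in_trip,
                bouts=detect_bouts(in_trip, bout_criterion),
            )
        )
    return trips


# ---------------------------------------------------------------------------
# per-dive classifications
# ---------------------------------------------------------------------------

def classify_day_night(
    times: np.ndarray,
    lat: float | None,
    lon: float | None,
    fallback: tuple[float, float] | None = None,
    threshold_deg: float = 0.0,
) -> np.ndarray:
    """Day (True) / night (False) from solar elevation at the given location.

    Falls back to ``fallback`` (e.g. the deployment-median location) with a
    warning when lat/lon are missing.
    """
    if lat is None or lon is None or not (np.isfinite(lat) and np.isfinite(lon)):
        if fallback is None:
            raise ValueError("no location available for day/night classification")
        warnings.warn("missing location; using deployment-median fallback")
        lat, lon = fallback
    return is_daytime(times, lat, lon, threshold_deg)


def classify_benthic(
    dives: Sequence[Dive],
    window: int = 5,
    idz_fraction: float = 0.9,
    flat_bottom_min: float | None = 0.35,
) -> np.ndarray:
    """Label benthic dives by the intra-depth-zone (IDZ) rule.

    A dive is benthic when its maximum depth is within ``idz_fraction`` of the
    running maximum depth over the surrounding ``window`` of dives — repeated
    dives to a common depth indicate the seafloor. When ``flat_bottom_min`` is
    set, a dive must additionally spend at least that fraction of its duration
    in the bottom phase (flat-bottom corroboration; V-shaped pelagic dives
    fail it). A single dive is benthic by convention (its window degenerates
    to itself).
    """
    if not dives:
        raise ValueError("need at least one dive")
    depths = np.array([d.max_depth for d in dives])
    n = len(depths)
    if n == 1:
        return np.array([True])
    half = window // 2
    local_max = np.array(
        [depths[max(0, i - half) : min(n, i + half + 1)].max() for i in range(n)]
    )
    benthic = depths >= idz_fraction * local_max
    if flat_bottom_min is not None:
        flat = np.array(
            [d.bottom_time_s / d.duration_s >= flat_bottom_min for d in dives]
        )
        benthic &= flat
    return benthic


# ---------------------------------------------------------------------------
# trip summaries
# ---------------------------------------------------------------------------

TRIP_METRIC_NAMES = [
    "mean_depth_m",
    "mean_duration_s",
    "mean_ascent_rate_ms",
    "mean_descent_rate_ms",
    "mean_bout_duration_hr",
    "percent_time_diving",
    "dive_rate_per_hr",
    "n_dives",
    "trip_duration_hr",
    "max_depth_m",
    "mean_bottom_time_s",
    "percent_dives_gt4min",
    "percent_dives_gt5min",
    "percent_dives_gt200m",
]

STRATEGY_VARIABLE_NAMES = [
    "mean_day_depth_m",
    "mean_night_depth_m",
    "mean_day_duration_s",
    "mean_night_duration_s",
    "day_dive_rate_per_hr",
    "night_dive_rate_per_hr",
    "percent_benthic",
    "percent_epipelagic",
    "percent_mesopelagic",
    "percent_day_dives",
    "mean_bottom_time_day_s",
    "mean_bottom_time_night_s",
    "depth_cv",
    "mean_bout_duration_hr",
]


def trip_metrics(trip: Trip) -> dict[str, float]:
    """Trip-level behavior summary (the coarse, whole-trip variable set).

    Returns an all-NaN map when the trip has no dives.
    """
    if not trip.dives:
        return {name: np.nan for name in TRIP_METRIC_NAMES}
    depths = np.array([d.max_depth for d in trip.dives])
    durs = np.array([d.duration_s for d in trip.dives])
    trip_hr = trip.duration_hr
    return {
        "mean_depth_m": float(depths.mean()),
        "mean_duration_s": float(durs.mean()),
        "mean_ascent_rate_ms": float(np.mean([d.ascent_rate for d in trip.dives])),
        "mean_descent_rate_ms": float(np.mean([d.descent_rate for d in trip.dives])),
        "mean_bout_duration_hr": float(np.mean([b.duration_hr for b in trip.bouts]))
        if trip.bouts
        else np.nan,
        "percent_time_diving": float(100.0 * durs.sum() / (trip_hr * 3600.0)),
        "dive_rate_per_hr": float(len(durs) / trip_hr),
        "n_dives": float(len(durs)),
        "trip_duration_hr": float(trip_hr),
        "max_depth_m": float(depths.max()),
        "mean_bottom_time_s": float(np.mean([d.bottom_time_s for d in trip.dives])),
        "percent_dives_gt4min": float(100.0 * np.mean(durs > 240.0)),
        "percent_dives_gt5min": float(100.0 * np.mean(durs > 300.0)),
        "percent_dives_gt200m": float(100.0 * np.mean(depths > 200.0)),
    }


def strategy_variables(trip: Trip, mesopelagic_depth_m: float = 200.0) -> dict[str, float]:
    """The fine-scale variable set used for foraging-strategy classification.

    Emphasizes the position in the water column (percent benthic /
    epipelagic / mesopelagic, partitioning to 100%) and day/night contrasts;
    dives must already carry ``is_day`` and ``is_benthic`` labels. Day or
    night entries are NaN when that subset is empty.
    """
    if not trip.dives:
        return {name: np.nan for name in STRATEGY_VARIABLE_NAMES}
    if any(d.is_day is None or d.is_benthic is None for d in trip.dives):
        raise ValueError("dives must carry is_day and is_benthic labels")
    day = [d for d in trip.dives if d.is_day]
    night = [d for d in trip.dives if not d.is_day]
    depths = np.array([d.max_depth for d in trip.dives])
    benthic = np.array([d.is_benthic for d in trip.dives])
    pelagic = ~benthic
    trip_hr = trip.duration_hr

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else np.nan

    return {
        "mean_day_depth_m": _mean([d.max_depth for d in day]),
        "mean_night_depth_m": _mean([d.max_depth for d in night]),
        "mean_day_duration_s": _mean([d.duration_s for d in day]),
        "mean_night_duration_s": _mean([d.duration_s for d in night]),
        "day_dive_rate_per_hr": float(len(day) / trip_hr),
        "night_dive_rate_per_hr": float(len(night) / trip_hr),
        "percent_benthic": float(100.0 * benthic.mean()),
        "percent_epipelagic": float(
            100.0 * (pelagic & (depths < mesopelagic_depth_m)).mean()
        ),
        "percent_mesopelagic": float(
            100.0 * (pelagic & (depths >= mesopelagic_depth_m)).mean()
        ),
        "percent_day_dives": float(100.0 * len(day) / len(trip.dives)),
        "mean_bottom_time_day_s": _mean([d.bottom_time_s for d in day]),
        "mean_bottom_time_night_s": _mean([d.bottom_time_s for d in night]),
        "depth_cv": float(depths.std(ddof=1) / depths.mean()) if len(depths) > 1 else 0.0,
        "mean_bout_duration_hr": float(np.mean([b.duration_hr for b in trip.bouts]))
        if trip.bouts
        else np.nan,
    }


# ---------------------------------------------------------------------------
# track filtering and interpolation
# ---------------------------------------------------------------------------

_EARTH_RADIUS_KM = 6371.0


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _bearing_deg(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dlam = np.deg2rad(lon2 - lon1)
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return float(np.rad2deg(np.arctan2(y, x)))


def filter_track(
    fixes: Sequence[TrackFix],
    max_speed_kmh: float = 12.0,
    max_angle_deg: float = 160.0,
) -> list[TrackFix]:
    """Speed-and-angle filter for erroneous locations.

    Iteratively removes the worst fix implying a transit speed above
    ``max_speed_kmh`` (great-circle) or a course change above
    ``max_angle_deg`` (0° = straight ahead, 180° = reversal) until none
    remain. Fewer than 3 fixes are returned unchanged.
    """
    kept = list(fixes)
    if len(kept) < 3:
        return kept
    while len(kept) >= 3:
        t = _seconds(np.array([f.time for f in kept]))
        lat = np.array([f.lat for f in kept])
        lon = np.array([f.lon for f in kept])
        dist = _haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt_hr = np.diff(t) / 3600.0
        speed = np.where(dt_hr > 0, dist / np.maximum(dt_hr, 1e-9), np.inf)
        worst_idx, worst_score = None, 0.0
        for i in range(len(kept)):
            s_in = speed[i - 1] if i > 0 else 0.0
            s_out = speed[i] if i < len(speed) else 0.0
            score = 0.0
            if max(s_in, s_out) > max_speed_kmh:
                # a genuine outlier implies fast transit on BOTH adjacent
                # segments, so sum the evidence rather than taking the max
                score = (s_in + s_out) / max_speed_kmh
            if 0 < i < len(kept) - 1 and dist[i - 1] > 1e-6 and dist[i] > 1e-6:
                turn = abs(
                    (_bearing_deg(lat[i], lon[i], lat[i + 1], lon[i + 1])
                     - _bearing_deg(lat[i - 1], lon[i - 1], lat[i], lon[i]) + 180.0)
                    % 360.0
                    - 180.0
                )
                if turn > max_angle_deg:
                    score += 1.0 + turn / max_angle_deg
            if score > worst_score:
                worst_score, worst_idx = score, i
        if worst_idx is None:
            break
        kept.pop(worst_idx)
    return kept


def interpolate_hourly(fixes: Sequence[TrackFix]) -> list[TrackFix]:
    """Linear interpolation of positions onto the hourly grid spanning the track."""
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes to interpolate")
    t = _seconds(np.array([f.time for f in fixes]))
    lat = np.array([f.lat for f in fixes])
    lon = np.array([f.lon for f in fixes])
    hour = 3600.0
    start = np.ceil(t[0] / hour) * hour
    n_points = int(np.floor((t[-1] - start) / hour + 1e-6)) + 1
    grid = start + hour * np.arange(max(n_points, 0))
    lat_i = np.interp(grid, t, lat)
    lon_i = np.interp(grid, t, lon)
    return [
        TrackFix(time=_EPOCH + np.timedelta64(int(g), "s"), lat=float(a), lon=float(o))
        for g, a, o in zip(grid, lat_i, lon_i)
    ]
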