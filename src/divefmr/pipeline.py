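"""Readers, writers, configuration, and the end-to-end pipeline driver.

The driver runs ingestion (real CSVs or the synthetic generator) ->
dive processing -> strategy classification -> DLW energetics -> population
statistics, and emits CSV outputs, a JSON statistics report, and a provenance
sidecar (constants, config, seeds). Each stage failure is wrapped in a
:class:`StageError` naming the stage; partial outputs written before the
failure are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dive as dv
from . import dlw as dw
from . import simulate as sim
from . import stats as st
from . import strategy as sg
from .constants import constants_provenance
from .fixtures import BEHAVIOR_VARIABLES, AnalysisTables, load_fixtures

__all__ = [
    "RunConfig",
    "StageError",
    "read_isotope_csv",
    "read_tdr_csv",
    "read_track_csv",
    "process_deployment",
    "analyze_tables",
    "run_pipeline",
]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved run configuration. Loadable from YAML via :meth:`from_yaml`."""

    mode: Literal["fixtures", "synthetic"] = "fixtures"
    equation: Literal["speakman", "nagy"] = "speakman"
    ratio_mode: Literal["fixed", "observed"] = "fixed"
    constants: dict[str, float] = field(default_factory=dict)
    dive_depth_min_m: float = 4.0
    dive_duration_min_s: float = 16.0
    bout_mode: Literal["fixed", "survivorship"] = "survivorship"
    bout_fixed_s: float = 600.0
    haulout_gap_hr: float = 0.5
    min_trip_hr: float = 6.0
    onshore_rate_wkg: float | None = None
    onshore_basal_multiple: float | None = 1.5
    mantel_permutations: int = 9999
    mc_draws: int = 10_000
    seed: int = 20180402
    n_animals: int = 15
    sim_overrides: dict = field(default_factory=dict)
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def onshore_spec(self) -> dw.OnshoreRateSpec:
        return dw.OnshoreRateSpec(
            rate_wkg=self.onshore_rate_wkg,
            basal_multiple=None if self.onshore_rate_wkg is not None else self.onshore_basal_multiple,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_isotope_csv(path: str | Path) -> list[dw.IsotopeStudy]:
    """Read one study-site CSV (one row per serum sample) into studies.

    Expected columns: animal_id, phase, sample_time (ISO-8601), o18_ppm,
    h2_ppm, dose_mass_g, dose_o18_frac, dose_h2_frac, mass_initial_kg,
    mass_final_kg, interval_days, time_at_sea_days. Study-level columns are
    repeated on every sample row.
    """
    df = pd.read_csv(path, parse_dates=["sample_time"])
    studies = []
    for animal_id, g in df.groupby("animal_id", sort=False):
        g = g.sort_values("sample_time")
        t0 = g["sample_time"].iloc[0]
        first = g.iloc[0]
        samples = [
            dw.IsotopeSample(
                time_days=(row.sample_time - t0).total_seconds() / 86400.0,
                o18_ppm=row.o18_ppm,
                h2_ppm=row.h2_ppm,
                phase=row.phase,
            )
            for row in g.itertuples()
        ]
        studies.append(
            dw.IsotopeStudy(
                animal_id=str(animal_id),
                dose=dw.DoseRecord(
                    dose_mass_g=first.dose_mass_g,
                    o18_fraction=first.dose_o18_frac,
                    h2_fraction=first.dose_h2_frac,
                ),
                samples=samples,
                mass_initial_kg=first.mass_initial_kg,
                mass_final_kg=first.mass_final_kg,
                interval_days=first.interval_days,
                time_at_sea_days=first.time_at_sea_days,
            )
        )
    return studies


def read_tdr_csv(path: str | Path, animal_id: str | None = None) -> dv.DepthTrace:
    """Read a TDR deployment CSV (timestamp, depth_m); gzip accepted by suffix."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    times = df["timestamp"].to_numpy(dtype="datetime64[s]")
    interval = float(np.median(np.diff(times).astype(float))) if len(times) > 1 else 1.0
    return dv.DepthTrace(
        animal_id=animal_id or Path(path).stem,
        times=times,
        depth_m=df["depth_m"].to_numpy(dtype=float),
        sampling_interval_s=interval,
    )


def read_track_csv(path: str | Path) -> list[dv.TrackFix]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return [
        dv.TrackFix(
            time=np.datetime64(row.timestamp, "s"),
            lat=row.lat,
            lon=row.lon,
            source=getattr(row, "source", "gps"),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# dive deployment processing
# ---------------------------------------------------------------------------

def process_deployment(
    trace: dv.DepthTrace,
    fixes: Sequence[dv.TrackFix] | None,
    config: RunConfig,
    fallback_latlon: tuple[float, float] = (33.25, -119.5),
) -> tuple[list[dv.Trip], pd.DataFrame, pd.DataFrame]:
    """Raw trace -> trips plus trip-metric and strategy-variable tables."""
    corrected = dv.zero_offset_correct(trace)
    dives = dv.detect_dives(
        corrected,
        depth_min_m=config.dive_depth_min_m,
        duration_min_s=config.dive_duration_min_s,
    )
    bout_spec = dv.BoutCriterionSpec(mode=config.bout_mode, fixed_s=config.bout_fixed_s)
    trips = dv.segment_trips(
        corrected,
        dives,
        haulout_gap_hr=config.haulout_gap_hr,
        min_trip_hr=config.min_trip_hr,
        bout_criterion=bout_spec,
    )
    if fixes:
        lat = float(np.median([f.lat for f in fixes]))
        lon = float(np.median([f.lon for f in fixes]))
    else:
        lat, lon = fallback_latlon
    metric_rows, strat_rows = [], []
    for i, trip in enumerate(trips):
        if trip.dives:
            starts = np.array([d.start for d in trip.dives], dtype="datetime64[s]")
            day = dv.classify_day_night(starts, lat, lon)
            benthic = dv.classify_benthic(trip.dives)
            for d, is_day, is_b in zip(trip.dives, day, benthic):
                d.is_day = bool(is_day)
                d.is_benthic = bool(is_b)
        trip_id = f"{trace.animal_id}_trip{i}"
        metric_rows.append({"trip_id": trip_id, **dv.trip_metrics(trip)})
        strat_rows.append({"trip_id": trip_id, **dv.strategy_variables(trip)})
    return trips, pd.DataFrame(metric_rows), pd.DataFrame(strat_rows)


# ---------------------------------------------------------------------------
# population statistics on the study tables
# ---------------------------------------------------------------------------

def analyze_tables(
    tables: AnalysisTables,
    equation: Literal["speakman", "nagy"] = "speakman",
    mantel_permutations: int = 9999,
    seed: int = 20180402,
) -> dict:
    """The population statistics block computed from the joined study tables.

    Covers: per-island means of whole-interval and at-sea FMR, the one-way
    island ANOVA on at-sea FMR, the two-way (island + strategy) ANOVA on water
    influx, Pearson correlations of water influx with mass-change rate and of
    at-sea FMR with influx, the five-variable principal-components regression
    of at-sea FMR with the strategy interaction, and a Mantel test between the
    variance-weighted PC-score distances and at-sea FMR distances.
    """
    m = tables.merged
    suffix = {"speakman": "speakman", "nagy": "nagy"}[equation]
    at_sea = m[f"at_sea_fmr_wkg_{suffix}"].to_numpy(float)
    total = m[f"fmr_wkg_{suffix}"].to_numpy(float)
    island = m["island"].to_numpy()
    strategy_col = m["strategy"].to_numpy()
    influx = m["influx_ml_kg_day"].to_numpy(float)

    out: dict = {"equation": equation}
    for isl in ("SNI", "SMI"):
        mask = island == isl
        out[f"{isl.lower()}_mean_fmr_wkg"] = float(total[mask].mean())
        out[f"{isl.lower()}_sd_fmr_wkg"] = float(total[mask].std(ddof=1))
        out[f"{isl.lower()}_mean_at_sea_fmr_wkg"] = float(at_sea[mask].mean())
        out[f"{isl.lower()}_sd_at_sea_fmr_wkg"] = float(at_sea[mask].std(ddof=1))

    out["island_anova_at_sea_fmr"] = st.anova(at_sea, island, ["island"])["island"]
    out["influx_anova"] = st.anova(
        influx, [island, strategy_col], ["island", "strategy"]
    )
    for strat in ("Mixed", "Deep"):
        mask = strategy_col == strat
        out[f"influx_mean_{strat.lower()}"] = float(influx[mask].mean())
        out[f"influx_sd_{strat.lower()}"] = float(influx[mask].std(ddof=1))

    mass_change_rate = (
        (m["mass_final_kg"] - m["mass_initial_kg"]) / m["interval_days"]
    ).to_numpy(float)
    r, p = st.pearson_cor(influx, mass_change_rate)
    out["influx_vs_mass_change"] = {"r": r, "p": p}
    r, p = st.pearson_cor(at_sea, influx)
    out["at_sea_fmr_vs_influx"] = {"r": r, "p": p}

    pcr = st.pc_regression(m[BEHAVIOR_VARIABLES], at_sea, strategy_col)
    out["pca_variance_pc1"] = float(pcr.explained_variance[0])
    out["pca_variance_2pc_percent"] = 100.0 * pcr.cumulative_variance_2pc
    out["pc1_strategy_interaction_p"] = pcr.interaction_p
    out["pc_regression"] = {
        f"{comp}_{group}": fit for (comp, group), fit in pcr.fits.items()
    }
    out["loadings_rotated"] = {
        var: list(map(float, row))
        for var, row in zip(pcr.variable_names, pcr.loadings_rotated)
    }

    d_behavior = st.weighted_score_distance(pcr.scores, pcr.explained_variance[:2])
    d_energy = np.abs(at_sea[:, None] - at_sea[None, :])
    mantel = st.mantel_test(d_behavior, d_energy, n_perm=mantel_permutations, seed=seed)
    out["mantel"] = {"r": mantel.r, "p_sim": mantel.p_sim, "n_perm": mantel.n_perm}
    return out


# ---------------------------------------------------------------------------
# simulation experiments (round-trip validation on synthetic cohorts)
# ---------------------------------------------------------------------------

def dlw_roundtrip_experiment(n_studies: int = 200, seed: int = 1) -> dict:
    """Noise-free DLW recovery: max relative error of rCO2 and influx."""
    cfg = sim.SimConfig(seed=seed, n_animals=n_studies)
    err_rco2, err_influx = [], []
    for i in range(n_studies):
        study, truth = sim.simulate_isotope_study(cfg, i, noise=False)
        res = dw.process_study(study)
        err_rco2.append(
            abs(res.rco2_speakman_ml_g_hr - truth.rco2_ml_g_hr) / truth.rco2_ml_g_hr
        )
        err_influx.append(
            abs(res.influx_ml_kg_day - truth.influx_ml_kg_day) / truth.influx_ml_kg_day
        )
    return {
        "n": n_studies,
        "max_rel_err_rco2": float(max(err_rco2)),
        "max_rel_err_influx": float(max(err_influx)),
    }


def dlw_coverage_experiment(
    n_studies: int = 500, seed: int = 1, n_draws: int = 2000
) -> dict:
    """Fraction of noisy studies whose Monte-Carlo 95% interval covers truth."""
    cfg = sim.SimConfig(seed=seed, n_animals=n_studies)
    covered = 0
    for i in range(n_studies):
        study, truth = sim.simulate_isotope_study(cfg, i, noise=True)
        lo, hi = dw.rco2_uncertainty(
            study, cfg.analytical_sd_ppm, n_draws=n_draws, seed=seed + i
        )
        covered += lo <= truth.rco2_ml_g_hr <= hi
    return {"n": n_studies, "coverage": covered / n_studies}


def strategy_recovery_experiment(
    n_animals: int = 40,
    seed: int = 1,
    sampling_interval_s: float = 5.0,
    trip_duration_days_range: tuple[float, float] = (1.0, 2.0),
    n_trips_range: tuple[int, int] = (1, 2),
) -> dict:
    """End-to-end strategy recovery on a synthetic cohort.

    Simulates dive records, runs the full dive-processing chain, fits the
    strategy model on all trips (two occupied strategies are planted, so the
    tree is cut at 2), assigns each animal its dominant strategy, and scores
    accuracy against the planted labels. Also reports the per-strategy
    percentages of long (>4 min) and deep (>200 m) dives for calibration
    against the published regimes.
    """
    cfg = sim.SimConfig(
        seed=seed,
        n_animals=n_animals,
        sampling_interval_s=sampling_interval_s,
        trip_duration_days_range=trip_duration_days_range,
        n_trips_range=n_trips_range,
    )
    run_cfg = RunConfig(seed=seed)
    rows, row_animal, row_truth = [], [], []
    regime_stats: dict[str, dict[str, list[float]]] = {
        s: {"gt4": [], "gt200": []} for s in ("mixed", "deep")
    }
    for i in range(n_animals):
        trace, fixes, truth = sim.simulate_dive_record(cfg, i)
        trips, metrics, strat = process_deployment(trace, fixes, run_cfg)
        dives = [d for t in trips for d in t.dives]
        durs = np.array([d.duration_s for d in dives])
        deps = np.array([d.max_depth for d in dives])
        regime_stats[truth.strategy]["gt4"].append(100.0 * np.mean(durs > 240.0))
        regime_stats[truth.strategy]["gt200"].append(100.0 * np.mean(deps > 200.0))
        for _, row in strat.iterrows():
            rows.append(row.drop("trip_id").to_dict())
            row_animal.append(trace.animal_id)
            row_truth.append(truth.strategy)
    table = pd.DataFrame(rows)
    table = table.fillna(table.mean(numeric_only=True))
    model = sg.fit_strategy_model(table, k_clusters=2)
    assignments = [
        sg.predict_strategy(model, row.to_dict(), trip_id=str(i))
        for i, (_, row) in enumerate(table.iterrows())
    ]
    per_animal: dict[str, list] = {}
    truth_by_animal: dict[str, str] = {}
    for a, aid, tr in zip(assignments, row_animal, row_truth):
        per_animal.setdefault(aid, []).append(a)
        truth_by_animal[aid] = tr
    correct = sum(
        sg.dominant_strategy(asgn) == truth_by_animal[aid]
        for aid, asgn in per_animal.items()
    )
    return {
        "n_animals": n_animals,
        "n_trips": len(table),
        "accuracy": correct / len(per_animal),
        "trip_accuracy": float(
            np.mean([a.strategy == tr for a, tr in zip(assignments, row_truth)])
        ),
        "regimes": {
            s: {k: float(np.mean(v)) for k, v in d.items()}
            for s, d in regime_stats.items()
        },
    }


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _write_json(path: Path, obj: object) -> None:
    path.write_text(json.dumps(obj, indent=1, default=float))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns (and optionally writes) the
    report bundle: per-animal energetics, behavior tables, strategy
    assignments, the statistics block, and provenance."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "equation": config.equation,
            "constants": constants_provenance(),
        }
    }

    if config.mode == "fixtures":
        try:
            tables = load_fixtures()
        except Exception as e:  # noqa: BLE001
            raise StageError("ingest", str(e)) from e
        try:
            bundle["statistics"] = analyze_tables(
                tables,
                equation=config.equation,
                mantel_permutations=config.mantel_permutations,
                seed=config.seed,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("stats", str(e)) from e
        if out_dir:
            tables.table1.to_csv(out_dir / "energetics.csv", index=False)
            tables.table2.to_csv(out_dir / "behavior.csv", index=False)
            _write_json(out_dir / "statistics.json", bundle["statistics"])
            _write_json(out_dir / "provenance.json", bundle["provenance"])
        return bundle

    # synthetic mode: full chain with ground truth available
    cfg = sim.SimConfig(
        seed=config.seed, n_animals=config.n_animals, **config.sim_overrides
    )
    try:
        animals = sim.simulate_cohort(cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e

    energetics_rows, strat_tables, truth_rows = [], [], []
    onshore = config.onshore_spec()
    for a in animals:
        try:
            res = dw.process_study(
                a.study,
                onshore=onshore,
                ratio_mode=config.ratio_mode,
                constants=config.constants or None,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("dlw", f"{a.animal_id}: {e}") from e
        try:
            trips, metrics, strat = process_deployment(a.trace, a.fixes, config)
        except Exception as e:  # noqa: BLE001
            raise StageError("dive", f"{a.animal_id}: {e}") from e
        strat["animal_id"] = a.animal_id
        strat_tables.append(strat)
        energetics_rows.append({"animal_id": a.animal_id, **dataclasses.asdict(res)})
        truth_rows.append(
            {"animal_id": a.animal_id, "strategy_true": a.strategy,
             **dataclasses.asdict(a.isotope_truth)}
        )

    trips_table = pd.concat(strat_tables, ignore_index=True).dropna(axis=1, how="all")
    feature_cols = [c for c in trips_table.columns if c not in ("trip_id", "animal_id")]
    trips_table[feature_cols] = trips_table[feature_cols].fillna(
        trips_table[feature_cols].mean(numeric_only=True)
    )
    try:
        model = sg.fit_strategy_model(
            trips_table[feature_cols], k_clusters=2, min_cluster_size=1
        )
        assignments = [
            sg.predict_strategy(model, row[feature_cols].to_dict(), row["trip_id"])
            for _, row in trips_table.iterrows()
        ]
        per_animal = {}
        for a, row in zip(assignments, trips_table.itertuples()):
            per_animal.setdefault(row.animal_id, []).append(a)
        strategies = {aid: sg.dominant_strategy(asgn) for aid, asgn in per_animal.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError("strategy", str(e)) from e

    energetics = pd.DataFrame(energetics_rows)
    bundle["energetics"] = energetics
    bundle["strategies"] = strategies
    bundle["truth"] = pd.DataFrame(truth_rows)
    if out_dir:
        energetics.to_csv(out_dir / "energetics.csv", index=False)
        trips_table.to_csv(out_dir / "strategy_vars.csv", index=False)
        _write_json(out_dir / "strategies.json", strategies)
        _write_json(out_dir / "provenance.json", bundle["provenance"])
    return bundle
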