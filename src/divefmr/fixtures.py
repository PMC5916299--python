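"""Packaged per-animal reference tables for the 15-female California sea lion
cohort (9 from San Nicolas Island, 6 from San Miguel Island, November–December
2014): whole-interval energetics (masses, measurement interval, time at sea,
total body water, water influx, CO2 production and FMR by both equations) and
at-sea FMR with the five trip-level behavioral means and the foraging-strategy
label (11 mixed, 4 deep).

The at-sea FMR column is carried as data: the onshore-time correction that
produced it is not recomputable from the whole-interval table (see the methods
note), so downstream statistics treat it as an input. Files are
checksum-verified on load and never mutated by any pipeline stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["AnalysisTables", "load_fixtures", "BEHAVIOR_VARIABLES"]

#: The five behavioral means used in the principal-components regression.
BEHAVIOR_VARIABLES = [
    "mean_depth_m",
    "mean_duration_s",
    "mean_ascent_rate_ms",
    "mean_descent_rate_ms",
    "mean_bout_duration_hr",
]


@dataclass(frozen=True)
class AnalysisTables:
    """The joined study tables: ``table1`` energetics, ``table2`` behavior."""

    table1: pd.DataFrame
    table2: pd.DataFrame

    @property
    def merged(self) -> pd.DataFrame:
        return self.table1.merge(self.table2, on="animal_id", validate="1:1")

    def __post_init__(self) -> None:
        if len(self.table1) != 15 or len(self.table2) != 15:
            raise ValueError("expected 15 animals in each table")
        counts = self.table2["strategy"].value_counts()
        if counts.get("Mixed", 0) != 11 or counts.get("Deep", 0) != 4:
            raise ValueError("expected 11 mixed and 4 deep strategy animals")
        if set(self.table1.animal_id) != set(self.table2.animal_id):
            raise ValueError("animal ids do not match across tables")


def _read_verified(name: str, checksums: dict[str, str]) -> pd.DataFrame:
    ref = resources.files("divefmr") / "data" / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[name]:
        raise RuntimeError(
            f"fixture {name} failed checksum verification "
            f"(expected {checksums[name][:12]}…, got {digest[:12]}…)"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    if "pup" in df.columns:
        df["pup"] = df["pup"].astype("category")
    return df


def load_fixtures() -> AnalysisTables:
    """Load the packaged 15-animal tables, verifying checksums."""
    checksums = json.loads(
        (resources.files("divefmr") / "data" / "checksums.json").read_text()
    )
    return AnalysisTables(
        table1=_read_verified("table1_energetics.csv", checksums),
        table2=_read_verified("table2_behavior.csv", checksums),
    )
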