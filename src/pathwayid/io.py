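"""File formats: tidy concentration tables and pathway YAML documents.

Units are pinned by the schema to avoid drift: times in days,
concentrations in µg L^-1, TSS in gTSS L^-1 (matching d^-1 abiotic and
L gTSS^-1 d^-1 biotic rate constants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .network import PathwayNetwork, Trajectory, build_network

__all__ = [
    "Dataset",
    "read_timeseries",
    "write_timeseries",
    "read_network",
    "write_network",
    "network_to_config",
    "trajectory_to_frame",
]

log = logging.getLogger("pathwayid")

REQUIRED_COLUMNS = ("time_d", "compound", "phase", "concentration_ugL")
SCHEMA_VERSION = "pathway-v1"


@dataclass
class Dataset:
    """Measured (or synthetic) concentration series per compound and phase."""

    table: pd.DataFrame
    tss: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if (self.table["concentration_ugL"] < 0).any():
            bad = self.table[self.table["concentration_ugL"] < 0].index[0]
            raise ValueError(f"negative concentration at row {bad}")
        dup = self.table.duplicated(subset=["time_d", "compound", "phase"])
        if dup.any():
            raise ValueError(f"duplicate (time, compound, phase) at row {dup.idxmax()}")
        unsorted = (
            self.table.groupby(["phase", "compound"], sort=False)["time_d"]
            .apply(lambda s: not s.is_monotonic_increasing)
            .any()
        )
        if unsorted:
            log.warning("unsorted times in dataset; sorting")
        self.table = self.table.sort_values(["phase", "compound", "time_d"]).reset_index(
            drop=True
        )

    def compounds(self, phase: str) -> list[str]:
        return sorted(self.table.loc[self.table["phase"] == phase, "compound"].unique())

    def series(self, compound: str, phase: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[(self.table["compound"] == compound) & (self.table["phase"] == phase)]
        if sub.empty:
            raise KeyError(f"no series for {compound!r} in phase {phase!r}")
        return sub["time_d"].to_numpy(float), sub["concentration_ugL"].to_numpy(float)

    def phase_frame(self, phase: str) -> pd.DataFrame:
        return self.table[self.table["phase"] == phase].copy()


def read_timeseries(path: str | Path) -> Dataset:
    """Read a tidy CSV (time_d, compound, phase, concentration_ugL).

    TSS is taken from a ``tss_gL`` column (constant) or a ``# tss=``
    header comment; defaults to 1 gTSS/L with a warning.
    """
    path = Path(path)
    tss = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "tss=" in first:
        tss = float(first.split("tss=")[1].split()[0])
    table = pd.read_csv(path, comment="#")
    if "tss_gL" in table.columns:
        vals = table["tss_gL"].unique()
        if len(vals) != 1:
            raise ValueError("tss_gL column must be constant")
        tss = float(vals[0])
        table = table.drop(columns=["tss_gL"])
    if tss is None:
        log.warning("no TSS in %s; defaulting to 1 gTSS/L", path)
        tss = 1.0
    return Dataset(table=table, tss=tss)


def write_timeseries(ds: Dataset, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tss={ds.tss:g} gTSS/L, schema={SCHEMA_VERSION}\n")
        ds.table.to_csv(fh, index=False)


def network_to_config(net: PathwayNetwork) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "tss": net.tss,
        "compounds": [
            {
                "id": c.id,
                "observed": c.observed,
                "c0_abiotic": c.c0_abiotic,
                "c0_biotic": c.c0_biotic,
            }
            for c in net.compounds
        ],
        "edges": [
            {
                "source": e.source,
                "product": e.product,
                "phase": e.phase,
                "param": e.param_id,
                "stoich": e.stoich,
                **({"frozen": e.frozen_value} if e.frozen_value is not None else {}),
            }
            for e in net.edges
        ],
    }


def read_network(path: str | Path) -> PathwayNetwork:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if config.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValueError(f"unsupported pathway schema {config.get('schema')!r}")
    return build_network(config)


def write_network(net: PathwayNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_config(net), fh, sort_keys=False)


def trajectory_to_frame(traj: Trajectory, phase: str) -> pd.DataFrame:
    """Tidy frame (time_d, compound, concentration_ugL, phase) of a trajectory."""
    rows = []
    for cid in traj.compound_ids:
        series = traj.series(cid)
        for t, c in zip(traj.times, series):
            rows.append({"time_d": t, "compound": cid, "phase": phase, "concentration_ugL": c})
    return pd.DataFrame(rows)
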