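"""Synthetic batch-experiment data with the structure the method assumes.

The generator simulates a pathway under known rate constants for each
experiment phase (abiotic-only dynamics for abiotic batches, combined
abiotic+biotic dynamics for biotic batches) and corrupts the result
with measurement noise above a detection floor.  The generating truth
travels with the dataset so recovery can be scored.

The ready-made heroin/codeine fixture mirrors the six-biomarker
wastewater pathway: heroin (HER) deacetylates to 6-monoacetylmorphine
(6MAM) and further to morphine (MOR); codeine (COE) branches to MOR and
norcodeine (NCOE); morphine glucuronide (MORG) deconjugates to MOR
biotically but shows no abiotic transformation (rate frozen at zero);
HER and MORG additionally carry biotic branches to unknown
transformation products.  The fixture's rate constants are package
defaults chosen for well-separated timescales (fast HER hydrolysis,
slow MOR turnover); they are not literature estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset
from .network import PathwayNetwork, build_network, simulate

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "generate_dataset",
    "heroin_codeine_fixture",
    "heroin_codeine_network",
    "human_metabolism_network",
    "two_branch_network",
    "two_branch_fixture",
    "HEROIN_TRUE_PARAMS",
    "TWO_BRANCH_TRUE_PARAMS",
    "DEFAULT_TIMES",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-error model: additive or proportional Gaussian.

    ``sigma`` is µg/L for additive noise, a fraction for proportional.
    Values below ``floor`` are reported at the floor (detection limit).
    """

    kind: str = "proportional"
    sigma: float = 0.05
    floor: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def corrupt(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            noisy = values.copy()
        elif self.kind == "additive":
            noisy = values + rng.normal(0.0, self.sigma, size=values.shape)
        else:
            noisy = values * (1.0 + rng.normal(0.0, self.sigma, size=values.shape))
        return np.maximum(noisy, self.floor)


@dataclass
class SyntheticDataset:
    dataset: Dataset
    true_params: dict[str, float]
    noise: NoiseModel
    seed: int
    floor_fraction: float = 0.0


# sampling schedule (days): dense early points to catch fast hydrolysis
DEFAULT_TIMES = np.array(
    [0.0, 0.03, 0.06, 0.10, 0.15, 0.20, 0.30, 0.45, 0.65, 1.0, 1.5, 2.25, 3.5]
)


def generate_dataset(
    net: PathwayNetwork,
    true_params: dict[str, float],
    times: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate each experiment phase and corrupt with measurement noise.

    Abiotic batches activate only the abiotic edges; biotic batches run
    the combined model.  Regeneration with the same seed is
    bit-identical.
    """
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)
    rows = []
    n_floor = 0
    n_total = 0
    phases = []
    if any(e.phase == "abiotic" for e in net.edges):
        phases.append(("abiotic", "abiotic"))
    if any(e.phase == "biotic" for e in net.edges):
        phases.append(("biotic", "combined"))
    for data_phase, sim_phase in phases:
        traj = simulate(net, true_params, sim_phase, times)
        for cid in net.observed_ids:
            clean = traj.series(cid)
            noisy = noise.corrupt(clean, rng)
            n_floor += int(np.sum(noisy <= noise.floor))
            n_total += noisy.size
            for t, c in zip(times, noisy):
                rows.append(
                    {
                        "time_d": t,
                        "compound": cid,
                        "phase": data_phase,
                        "concentration_ugL": c,
                    }
                )
    floor_frac = n_floor / max(n_total, 1)
    if floor_frac > 0.5:
        import warnings

        warnings.warn(
            f"{floor_frac:.0%} of synthetic values hit the detection floor",
            RuntimeWarning,
            stacklevel=2,
        )
    ds = Dataset(table=pd.DataFrame(rows), tss=net.tss)
    return SyntheticDataset(
        dataset=ds,
        true_params=dict(true_params),
        noise=noise,
        seed=seed,
        floor_fraction=floor_frac,
    )


# --------------------------------------------------------------------------
# heroin / codeine fixture
# --------------------------------------------------------------------------

_HEROIN_COMPOUNDS = [
    {"id": "HER", "c0_abiotic": 100.0, "c0_biotic": 100.0},
    {"id": "6MAM", "c0_abiotic": 20.0, "c0_biotic": 20.0},
    {"id": "MOR", "c0_abiotic": 30.0, "c0_biotic": 30.0},
    {"id": "MORG", "c0_abiotic": 60.0, "c0_biotic": 60.0},
    {"id": "COE", "c0_abiotic": 80.0, "c0_biotic": 80.0},
    {"id": "NCOE", "c0_abiotic": 10.0, "c0_biotic": 10.0},
    {"id": "TP_A", "observed": False},
    {"id": "TP_B", "observed": False},
]

# 7 abiotic edges (one frozen at zero) and 9 biotic edges; the two
# biotic branches to TP_B for HER and MORG are the "discovered" pathways
_HEROIN_EDGES = [
    {"source": "HER", "product": "6MAM", "phase": "abiotic", "param": "k_abio_HER"},
    {"source": "6MAM", "product": "MOR", "phase": "abiotic", "param": "k_abio_6MAM"},
    {"source": "MOR", "product": "TP_A", "phase": "abiotic", "param": "k_abio_MOR"},
    {"source": "MORG", "product": "MOR", "phase": "abiotic", "param": "k_abio_MORG",
     "frozen": 0.0},
    {"source": "COE", "product": "MOR", "phase": "abiotic", "param": "k_abio_COE_1"},
    {"source": "COE", "product": "NCOE", "phase": "abiotic", "param": "k_abio_COE_2"},
    {"source": "NCOE", "product": "TP_A", "phase": "abiotic", "param": "k_abio_NCOE"},
    {"source": "HER", "product": "6MAM", "phase": "biotic", "param": "k_bio_HER_1"},
    {"source": "HER", "product": "TP_B", "phase": "biotic", "param": "k_bio_HER_2"},
    {"source": "6MAM", "product": "MOR", "phase": "biotic", "param": "k_bio_6MAM"},
    {"source": "MOR", "product": "TP_B", "phase": "biotic", "param": "k_bio_MOR"},
    {"source": "MORG", "product": "MOR", "phase": "biotic", "param": "k_bio_MORG_1"},
    {"source": "MORG", "product": "TP_B", "phase": "biotic", "param": "k_bio_MORG_2"},
    {"source": "COE", "product": "MOR", "phase": "biotic", "param": "k_bio_COE_1"},
    {"source": "COE", "product": "NCOE", "phase": "biotic", "param": "k_bio_COE_2"},
    {"source": "NCOE", "product": "TP_B", "phase": "biotic", "param": "k_bio_NCOE"},
]

HEROIN_TRUE_PARAMS = {
    "k_abio_HER": 6.0,      # d^-1, fast deacetylation
    "k_abio_6MAM": 1.2,
    "k_abio_MOR": 0.25,     # slow morphine turnover
    "k_abio_COE_1": 0.5,
    "k_abio_COE_2": 0.9,
    "k_abio_NCOE": 0.4,
    "k_bio_HER_1": 10.0,    # L gTSS^-1 d^-1
    "k_bio_HER_2": 6.0,
    "k_bio_6MAM": 2.5,
    "k_bio_MOR": 1.0,
    "k_bio_MORG_1": 3.0,
    "k_bio_MORG_2": 1.5,
    "k_bio_COE_1": 2.0,
    "k_bio_COE_2": 3.5,
    "k_bio_NCOE": 1.25,
}


def heroin_codeine_network() -> PathwayNetwork:
    """The six-biomarker pathway with both discovered biotic branches."""
    return build_network(
        {"tss": 0.4, "compounds": _HEROIN_COMPOUNDS, "edges": _HEROIN_EDGES}
    )


def human_metabolism_network() -> PathwayNetwork:
    """The pathway as known from human metabolism alone.

    HER transforms biotically only to 6MAM and MORG only to MOR: the
    two branches to unknown TPs are absent, so each of those compounds
    has a single biotic rate constant.  Fitting this network to data
    produced by the full pathway is the canonical mis-specification
    experiment.
    """
    edges = []
    for e in _HEROIN_EDGES:
        if e["param"] in ("k_bio_HER_2", "k_bio_MORG_2"):
            continue
        e = dict(e)
        if e["param"] == "k_bio_HER_1":
            e["param"] = "k_bio_HER"
        if e["param"] == "k_bio_MORG_1":
            e["param"] = "k_bio_MORG"
        edges.append(e)
    return build_network(
        {"tss": 0.4, "compounds": _HEROIN_COMPOUNDS, "edges": edges}
    )


def heroin_codeine_fixture(
    seed: int = 0,
    noise: NoiseModel | None = None,
    times: np.ndarray | None = None,
) -> tuple[PathwayNetwork, SyntheticDataset]:
    """The ready-made six-biomarker fixture: network plus noisy data."""
    net = heroin_codeine_network()
    synth = generate_dataset(
        net, HEROIN_TRUE_PARAMS, times=times, noise=noise, seed=seed
    )
    return net, synth


# --------------------------------------------------------------------------
# minimal two-branch fixture (branch-collinearity experiments)
# --------------------------------------------------------------------------

TWO_BRANCH_TRUE_PARAMS = {
    "k_abio_PAR_1": 1.2,
    "k_abio_PAR_2": 0.8,
    "k_abio_M1": 0.5,
    "k_abio_M2": 0.3,
}


def two_branch_network() -> PathwayNetwork:
    """A parent with two observed first-order branches (abiotic only)."""
    return build_network(
        {
            "tss": 1.0,
            "compounds": [
                {"id": "PAR", "c0_abiotic": 100.0},
                {"id": "M1", "c0_abiotic": 10.0},
                {"id": "M2", "c0_abiotic": 10.0},
                {"id": "TP", "observed": False},
            ],
            "edges": [
                {"source": "PAR", "product": "M1", "phase": "abiotic",
                 "param": "k_abio_PAR_1"},
                {"source": "PAR", "product": "M2", "phase": "abiotic",
                 "param": "k_abio_PAR_2"},
                {"source": "M1", "product": "TP", "phase": "abiotic",
                 "param": "k_abio_M1"},
                {"source": "M2", "product": "TP", "phase": "abiotic",
                 "param": "k_abio_M2"},
            ],
        }
    )


def two_branch_fixture(
    seed: int = 0, noise: NoiseModel | None = None
) -> tuple[PathwayNetwork, SyntheticDataset]:
    net = two_branch_network()
    times = np.array([0.0, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.5, 7.0])
    synth = generate_dataset(
        net, TWO_BRANCH_TRUE_PARAMS, times=times, noise=noise, seed=seed
    )
    return net, synth
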