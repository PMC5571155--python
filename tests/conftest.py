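import numpy as np
import pytest

from pathwayid.calibration import CalibrationConfig
from pathwayid.sampler import SamplerConfig
from pathwayid.synthetic import (
    heroin_codeine_fixture,
    heroin_codeine_network,
    two_branch_fixture,
)


@pytest.fixture(scope="session")
def heroin_network():
    return heroin_codeine_network()


@pytest.fixture(scope="session")
def heroin_data():
    """Seeded noisy dataset from the six-biomarker fixture."""
    _net, synth = heroin_codeine_fixture(seed=1)
    return synth


@pytest.fixture(scope="session")
def branch_fixture():
    return two_branch_fixture(seed=42)


@pytest.fixture()
def small_config():
    return CalibrationConfig(sampler=SamplerConfig(n_chains=5, max_evals=3000, seed=11))


@pytest.fixture(scope="session")
def chain_network():
    """Linear 3-compound abiotic chain A -> B -> C -> sink."""
    from pathwayid.network import build_network

    return build_network(
        {
            "compounds": [
                {"id": "A", "c0_abiotic": 10.0},
                {"id": "B", "c0_abiotic": 0.0},
                {"id": "C", "c0_abiotic": 0.0},
                {"id": "TP", "observed": False},
            ],
            "edges": [
                {"source": "A", "product": "B", "phase": "abiotic", "param": "kA"},
                {"source": "B", "product": "C", "phase": "abiotic", "param": "kB"},
                {"source": "C", "product": "TP", "phase": "abiotic", "param": "kC"},
            ],
        }
    )


def random_acyclic_network(rng: np.random.Generator, n_compounds: int = 5):
    """Random acyclic two-phase first-order network plus true rates."""
    from pathwayid.network import build_network

    ids = [f"X{i}" for i in range(n_compounds)]
    compounds = [
        {"id": cid, "c0_abiotic": float(rng.uniform(5, 100)),
         "c0_biotic": float(rng.uniform(5, 100))}
        for cid in ids
    ] + [{"id": "SINK", "observed": False}]
    edges, params = [], {}
    k = 0
    for i in range(n_compounds):
        targets = list(range(i + 1, n_compounds)) + ["SINK"]
        for phase in ("abiotic", "biotic"):
            n_out = int(rng.integers(0, 3))
            for t in rng.choice(len(targets), size=min(n_out, len(targets)), replace=False):
                prod = targets[int(t)]
                pid = f"k{k}"
                k += 1
                edges.append(
                    {
                        "source": ids[i],
                        "product": prod if prod == "SINK" else ids[prod],
                        "phase": phase,
                        "param": pid,
                    }
                )
                params[pid] = float(rng.uniform(0.05, 8.0))
    if not edges:  # ensure at least one edge
        edges.append({"source": ids[0], "product": "SINK", "phase": "abiotic", "param": "k0"})
        params["k0"] = 1.0
    net = build_network({"tss": float(rng.uniform(0.2, 1.5)),
                         "compounds": compounds, "edges": edges})
    return net, params
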