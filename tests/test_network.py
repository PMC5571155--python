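"""Network construction, ODE simulation and mass-balance consistency."""

import numpy as np
import pytest
from scipy.linalg import expm

from pathwayid.network import (
    NetworkError,
    build_network,
    enumerate_rate_parameters,
    mass_balance_flux,
    rate_matrix,
    simulate,
)
from tests.conftest import random_acyclic_network


def _single_compound_net(k_id="k1"):
    return build_network(
        {
            "compounds": [{"id": "A", "c0_abiotic": 1.0}, {"id": "TP", "observed": False}],
            "edges": [{"source": "A", "product": "TP", "phase": "abiotic", "param": k_id}],
        }
    )


class TestBuildNetwork:
    def test_heroin_fixture_structure(self, heroin_network):
        abio, bio = enumerate_rate_parameters(heroin_network)
        assert len(abio) == 7
        assert len(bio) == 9
        assert len(heroin_network.observed_ids) == 6
        sinks = [c.id for c in heroin_network.compounds if not c.observed]
        assert sinks == ["TP_A", "TP_B"]
        # the frozen abiotic rate is counted among the seven
        assert heroin_network.frozen_params() == {"k_abio_MORG": 0.0}

    def test_minimal_network(self):
        net = _single_compound_net()
        assert net.compound_ids == ["A", "TP"]
        assert enumerate_rate_parameters(net) == (["k1"], [])

    @pytest.mark.parametrize(
        "edge, match",
        [
            ({"source": "A", "product": "A", "phase": "abiotic", "param": "k"}, "self-loop"),
            ({"source": "A", "product": "Z", "phase": "abiotic", "param": "k"}, "unknown"),
            ({"source": "A", "product": "TP", "phase": "ethereal", "param": "k"}, "phase"),
        ],
    )
    def test_invalid_edges_rejected(self, edge, match):
        with pytest.raises(NetworkError, match=match):
            build_network(
                {
                    "compounds": [{"id": "A"}, {"id": "TP", "observed": False}],
                    "edges": [edge],
                }
            )

    def test_cycle_rejected(self):
        with pytest.raises(NetworkError, match="cycle"):
            build_network(
                {
                    "compounds": [{"id": "A"}, {"id": "B"}],
                    "edges": [
                        {"source": "A", "product": "B", "phase": "abiotic", "param": "k1"},
                        {"source": "B", "product": "A", "phase": "abiotic", "param": "k2"},
                    ],
                }
            )

    def test_duplicate_param_rejected(self):
        with pytest.raises(NetworkError, match="duplicate param_id"):
            build_network(
                {
                    "compounds": [{"id": "A"}, {"id": "B"}, {"id": "C"}],
                    "edges": [
                        {"source": "A", "product": "B", "phase": "abiotic", "param": "k"},
                        {"source": "B", "product": "C", "phase": "abiotic", "param": "k"},
                    ],
                }
            )

    def test_empty_network_enumeration(self):
        net = build_network({"compounds": [{"id": "A"}], "edges": []})
        assert enumerate_rate_parameters(net) == ([], [])


class TestSimulate:
    def test_exponential_decay_halflife(self):
        net = _single_compound_net()
        traj = simulate(net, {"k1": np.log(2)}, "abiotic", np.array([1.0]))
        assert traj.series("A")[0] == pytest.approx(0.5, rel=1e-9)

    def test_two_compartment_chain_matches_bateman(self, chain_network):
        # independent closed form for A -> B with distinct rates
        kA, kB, kC = 1.3, 0.4, 0.05
        t = np.linspace(0.01, 5, 40)
        traj = simulate(chain_network, {"kA": kA, "kB": kB, "kC": kC}, "abiotic", t)
        a0 = 10.0
        expected_b = a0 * kA / (kB - kA) * (np.exp(-kA * t) - np.exp(-kB * t))
        np.testing.assert_allclose(traj.series("B"), expected_b, rtol=1e-6)

    def test_zero_rates_hold_concentrations(self, chain_network):
        t = np.array([0.5, 1.0, 2.0])
        traj = simulate(chain_network, {"kA": 0.0, "kB": 0.0, "kC": 0.0}, "abiotic", t)
        np.testing.assert_allclose(traj.series("A"), 10.0)
        np.testing.assert_allclose(traj.series("B"), 0.0)

    def test_missing_parameter_raises(self, chain_network):
        with pytest.raises(KeyError):
            simulate(chain_network, {"kA": 1.0}, "abiotic", np.array([1.0]))

    def test_negative_rate_raises(self, chain_network):
        with pytest.raises(ValueError, match="negative"):
            simulate(
                chain_network, {"kA": -1.0, "kB": 0.1, "kC": 0.1}, "abiotic", np.array([1.0])
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_exponential_oracle_random_networks(self, seed):
        """simulate() equals expm of the rate matrix on random DAGs."""
        rng = np.random.default_rng(seed)
        net, params = random_acyclic_network(rng)
        times = np.sort(rng.uniform(0.05, 4.0, size=6))
        for phase in ("abiotic", "biotic", "combined"):
            traj = simulate(net, params, phase, times)
            a = rate_matrix(net, params, phase)
            c0 = net.c0(phase)
            ref = np.column_stack([expm(a * t) @ c0 for t in times])
            scale = max(np.abs(ref).max(), 1.0)
            assert np.max(np.abs(traj.concentrations - ref)) / scale < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conserved_with_unit_stoichiometry(self, seed):
        rng = np.random.default_rng(100 + seed)
        net, params = random_acyclic_network(rng)
        traj = simulate(net, params, "combined", np.linspace(0.1, 5, 15))
        total0 = net.c0("biotic").sum()
        np.testing.assert_allclose(traj.total_mass(), total0, rtol=1e-6)

    def test_linearity_in_initial_concentration(self, chain_network):
        params = {"kA": 1.0, "kB": 0.3, "kC": 0.1}
        t = np.linspace(0.1, 3, 10)
        base = simulate(chain_network, params, "abiotic", t).concentrations
        scaled = simulate(
            chain_network, params, "abiotic", t, c0=3.0 * chain_network.c0("abiotic")
        ).concentrations
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-9)

    def test_no_formation_implies_monotone_decay(self, heroin_network):
        from pathwayid.synthetic import HEROIN_TRUE_PARAMS

        traj = simulate(
            heroin_network, HEROIN_TRUE_PARAMS, "combined", np.linspace(0, 3, 30)
        )
        her = traj.series("HER")  # root compound: no formation edges
        assert np.all(np.diff(her) <= 1e-12)

    def test_ode_fallback_agrees_with_expm(self, heroin_network):
        from pathwayid.synthetic import HEROIN_TRUE_PARAMS

        t = np.linspace(0.05, 2, 10)
        a = simulate(heroin_network, HEROIN_TRUE_PARAMS, "combined", t, method="expm")
        b = simulate(heroin_network, HEROIN_TRUE_PARAMS, "combined", t, method="ode")
        assert np.max(np.abs(a.concentrations - b.concentrations)) < 1e-5


class TestMassBalanceFlux:
    def test_self_consistent_data_has_tiny_residuals(self, chain_network):
        params = {"kA": 1.0, "kB": 0.3, "kC": 0.1}
        traj = simulate(chain_network, params, "abiotic", np.linspace(0, 4, 400))
        resid = mass_balance_flux(chain_network, traj, params, "abiotic")
        # central differences on a dense grid (endpoints are one-sided
        # and first-order accurate, so judge the interior only)
        assert max(np.abs(r[1:-1]).max() for r in resid.values()) < 1e-2

    def test_missing_branch_leaves_signed_deficit(self):
        """Data with an extra branch, judged by the branchless model."""
        full = build_network(
            {
                "compounds": [
                    {"id": "A", "c0_abiotic": 100.0},
                    {"id": "B", "c0_abiotic": 0.0},
                    {"id": "TP", "observed": False},
                ],
                "edges": [
                    {"source": "A", "product": "B", "phase": "abiotic", "param": "k1"},
                    {"source": "A", "product": "TP", "phase": "abiotic", "param": "k2"},
                    {"source": "B", "product": "TP", "phase": "abiotic", "param": "kB"},
                ],
            }
        )
        branchless = build_network(
            {
                "compounds": [
                    {"id": "A", "c0_abiotic": 100.0},
                    {"id": "B", "c0_abiotic": 0.0},
                    {"id": "TP", "observed": False},
                ],
                "edges": [
                    {"source": "A", "product": "B", "phase": "abiotic", "param": "k1"},
                    {"source": "B", "product": "TP", "phase": "abiotic", "param": "kB"},
                ],
            }
        )
        t = np.linspace(0, 3, 200)
        data = simulate(full, {"k1": 1.0, "k2": 0.7, "kB": 0.4}, "abiotic", t)
        # branchless model with A's removal matched to the observed total
        resid = mass_balance_flux(branchless, data, {"k1": 1.7, "kB": 0.4}, "abiotic")
        # B receives less than the branchless model implies: one-signed deficit
        interior = resid["B"][5:-5]
        assert np.all(interior < 0)

    def test_constant_concentrations_zero_rates(self, chain_network):
        params = {"kA": 0.0, "kB": 0.0, "kC": 0.0}
        traj = simulate(chain_network, params, "abiotic", np.linspace(0, 2, 10))
        resid = mass_balance_flux(chain_network, traj, params, "abiotic")
        for r in resid.values():
            np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_too_few_points_rejected(self, chain_network):
        params = {"kA": 1.0, "kB": 0.3, "kC": 0.1}
        traj = simulate(chain_network, params, "abiotic", np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="3 time points"):
            mass_balance_flux(chain_network, traj, params, "abiotic")
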