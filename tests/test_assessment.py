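"""Accuracy metrics, prediction bands, identifiability and SRC sensitivity."""

import numpy as np
import pytest

from pathwayid.assessment import (
    aril_coverage_iltc,
    lcc_matrix,
    mc_prediction_bands,
    relative_ci_check,
    rmse_mae,
    src_gsa,
)
from pathwayid.priors import summarize_posterior


class TestRmseMae:
    def test_identical_series_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse_mae(y, y) == (0.0, 0.0)

    def test_unit_errors(self):
        assert rmse_mae(np.array([0.0, 0.0]), np.array([1.0, -1.0])) == (1.0, 1.0)

    def test_hand_computed_example(self):
        rmse, mae = rmse_mae(np.array([0.0, 0.0]), np.array([0.0, 3.0]))
        assert rmse == pytest.approx(np.sqrt(4.5))
        assert mae == pytest.approx(1.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse_mae(np.array([1.0]), np.array([1.0, 2.0]))


class TestArilCoverageIltc:
    def test_hand_computed_band(self):
        yhat = np.ones(5)
        aril, cov, iltc = aril_coverage_iltc(0.9 * yhat, 1.1 * yhat, yhat)
        assert aril == pytest.approx(0.2)
        assert cov == 1.0
        assert iltc == pytest.approx(0.2)

    def test_all_points_outside_flags_infinite(self):
        yhat = np.full(4, 10.0)
        aril, cov, iltc = aril_coverage_iltc(np.zeros(4), np.ones(4), yhat)
        assert cov == 0.0
        assert np.isinf(iltc)

    def test_zero_width_band_on_exact_data(self):
        yhat = np.array([1.0, 2.0])
        aril, cov, iltc = aril_coverage_iltc(yhat, yhat, yhat)
        assert (aril, cov, iltc) == (0.0, 1.0, 0.0)

    def test_iltc_equals_aril_at_full_coverage_and_grows_below(self):
        yhat = np.array([1.0, 1.0, 1.0, 1.0])
        aril_full, cov_full, iltc_full = aril_coverage_iltc(
            0.5 * yhat, 1.5 * yhat, yhat
        )
        assert iltc_full == aril_full
        # same band width, half the points covered -> ILTC doubles
        lower = np.array([0.5, 0.5, 1.2, 1.2])
        upper = lower + 1.0
        aril, cov, iltc = aril_coverage_iltc(lower, upper, yhat)
        assert cov == 0.5
        assert iltc == pytest.approx(aril / 0.5)

    def test_boundary_points_count_as_covered(self):
        yhat = np.array([1.0, 2.0])
        _a, cov, _i = aril_coverage_iltc(np.array([1.0, 1.0]), np.array([3.0, 2.0]), yhat)
        assert cov == 1.0


class TestLccMatrix:
    def test_independent_draws_nearly_uncorrelated(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(10_000, 3))
        frame, flags = lcc_matrix(x, ["a", "b", "c"])
        off = frame.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        assert flags == []

    def test_duplicated_column_flagged_positive(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(500, 1))
        frame, flags = lcc_matrix(np.column_stack([x, x]), ["a", "b"])
        assert frame.loc["a", "b"] == pytest.approx(1.0)
        assert flags[0][:2] == ("a", "b")

    def test_affine_rescaling_leaves_lcc_unchanged(self):
        rng = np.random.default_rng(9)
        x = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=2_000)
        f1, _ = lcc_matrix(x, ["a", "b"])
        f2, _ = lcc_matrix(x * np.array([10.0, 0.01]) + 5.0, ["a", "b"])
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-12)

    def test_zero_variance_column_rejected(self):
        x = np.column_stack([np.ones(200), np.arange(200.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            lcc_matrix(x, ["a", "b"])


class TestRelativeCiCheck:
    @staticmethod
    def _summary(median, lo, hi):
        from pathwayid.priors import PosteriorSummary

        return PosteriorSummary(
            param_id="k", samples=np.array([median]), median=median, cri95=(lo, hi)
        )

    def test_forty_percent_interval_identifiable(self):
        assert relative_ci_check(self._summary(1.0, 0.6, 1.4)) is True

    def test_sixty_percent_lower_arm_not_identifiable(self):
        assert relative_ci_check(self._summary(1.0, 0.4, 1.2)) is False

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            relative_ci_check(self._summary(0.0, -0.1, 0.1))


class TestSrcGsa:
    def test_dominant_and_inert_parameters_separated(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 1, size=(5_000, 2))
        y = 2.0 * theta[:, 0] + rng.normal(0, 0.05, 5_000)
        src, r2 = src_gsa(theta, y, ["t1", "t2"])
        assert src["t1"] == pytest.approx(np.corrcoef(theta[:, 0], y)[0, 1], abs=0.02)
        assert abs(src["t2"]) < 0.05
        assert r2 > 0.9

    def test_src_squares_sum_to_r2_for_uncorrelated_inputs(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=(20_000, 3))
        y = 1.5 * theta[:, 0] - 0.7 * theta[:, 1] + rng.normal(0, 1.0, 20_000)
        src, r2 = src_gsa(theta, y)
        assert float(np.sum(src**2)) == pytest.approx(r2, abs=0.01)

    def test_collinear_design_rejected(self):
        x = np.random.default_rng(0).normal(size=(500, 1))
        with pytest.raises(ValueError, match="collinear"):
            src_gsa(np.column_stack([x, 2.0 * x]), x[:, 0])


class TestPredictionBands:
    def test_point_mass_posterior_gives_zero_width_band(self, chain_network):
        from pathwayid.network import simulate

        params = {"kA": 1.0, "kB": 0.3, "kC": 0.1}
        ids = list(params)
        samples = np.tile([params[p] for p in ids], (300, 1))
        times = np.linspace(0.1, 3, 8)
        bands = mc_prediction_bands(chain_network, samples, ids, "abiotic", times,
                                    n_draws=300, seed=1)
        traj = simulate(chain_network, params, "abiotic", times)
        for cid in chain_network.observed_ids:
            np.testing.assert_allclose(bands.lower[cid], bands.upper[cid])
            np.testing.assert_allclose(bands.lower[cid], traj.series(cid), rtol=1e-9)

    def test_wider_posterior_widens_bands_pointwise(self, chain_network):
        rng = np.random.default_rng(6)
        ids = ["kA", "kB", "kC"]
        center = np.array([1.0, 0.3, 0.1])
        narrow = center * rng.uniform(0.95, 1.05, size=(400, 3))
        wide = center * rng.uniform(0.90, 1.10, size=(400, 3))
        times = np.linspace(0.1, 3, 8)
        b_narrow = mc_prediction_bands(chain_network, narrow, ids, "abiotic", times,
                                       n_draws=400, seed=2)
        b_wide = mc_prediction_bands(chain_network, wide, ids, "abiotic", times,
                                     n_draws=400, seed=2)
        for cid in ("A", "B"):
            w_n = b_narrow.upper[cid] - b_narrow.lower[cid]
            w_w = b_wide.upper[cid] - b_wide.lower[cid]
            assert np.all(w_w >= w_n - 1e-9)

    def test_too_few_draws_rejected(self, chain_network):
        with pytest.raises(ValueError, match="200"):
            mc_prediction_bands(chain_network, np.ones((10, 3)), ["kA", "kB", "kC"],
                                "abiotic", np.array([1.0]), n_draws=10)
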