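"""Prediction accuracy, uncertainty, identifiability and sensitivity.

Metrics mirror common practice in water-quality model evaluation:

* RMSE / MAE — goodness of fit of the calibrated model's predictions;
* ARIL — average relative interval length of the Monte-Carlo 95%
  prediction band, normalised by the measured value;
* coverage — fraction of measurements inside the band (closed interval);
* ILTC = ARIL / coverage — lower is better: narrow bands that still
  cover the data;
* LCC — Pearson correlations between posterior parameter samples;
  |LCC| > 0.7 flags a non-identifiable pair;
* the relative-CrI rule — a parameter is identifiable when its 95% CrI
  stays within 50% of the median on both sides;
* SRC — standardised regression coefficients as a linear global
  sensitivity measure of a scalar model output to the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import PathwayNetwork, simulate
from .priors import PosteriorSummary

__all__ = [
    "PredictionBands",
    "AssessmentReport",
    "rmse_mae",
    "mc_prediction_bands",
    "aril_coverage_iltc",
    "lcc_matrix",
    "relative_ci_check",
    "src_gsa",
    "assess_predictions",
]


def rmse_mae(measured: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    yhat = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if yhat.size == 0 or yhat.shape != y.shape:
        raise ValueError("series must be non-empty and aligned")
    err = y - yhat
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


@dataclass
class PredictionBands:
    times: np.ndarray
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    median: dict[str, np.ndarray]

    def at(self, cid: str, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.times, np.asarray(times, dtype=float))
        return self.lower[cid][idx], self.upper[cid][idx]


def mc_prediction_bands(
    net: PathwayNetwork,
    samples: np.ndarray,
    param_ids: Sequence[str],
    phase: str,
    times: np.ndarray,
    n_draws: int = 500,
    seed: int = 0,
    extra_params: Mapping[str, float] | None = None,
) -> PredictionBands:
    """Pointwise 95% envelopes of trajectories under posterior draws.

    Joint posterior rows are resampled (with replacement when the
    posterior is smaller than ``n_draws``) so parameter correlations
    survive into the bands.  More than 1% simulation failures aborts.
    """
    if n_draws < 200:
        raise ValueError("need at least 200 Monte Carlo draws")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, samples.shape[0], size=n_draws)
    times = np.asarray(times, dtype=float)
    trajs = np.empty((n_draws, len(net.compound_ids), times.size))
    failures = 0
    for k, r in enumerate(rows):
        params = dict(zip(param_ids, samples[r]))
        if extra_params:
            params.update(extra_params)
        try:
            trajs[k] = simulate(net, params, phase, times).concentrations
        except Exception:
            failures += 1
            trajs[k] = np.nan
    if failures > 0.01 * n_draws:
        raise RuntimeError(f"{failures}/{n_draws} Monte Carlo simulations failed")
    lo, med, hi = np.nanpercentile(trajs, [2.5, 50.0, 97.5], axis=0)
    ids = net.compound_ids
    return PredictionBands(
        times=times,
        lower={c: lo[i] for i, c in enumerate(ids)},
        upper={c: hi[i] for i, c in enumerate(ids)},
        median={c: med[i] for i, c in enumerate(ids)},
    )


def aril_coverage_iltc(
    lower: np.ndarray, upper: np.ndarray, measured: np.ndarray
) -> tuple[float, float, float]:
    """ARIL, coverage and their ratio for one compound's band.

    ARIL normalises the band width by the measured value, so points
    at zero concentration are excluded from the ARIL average (they
    still count for coverage).  Zero coverage yields an infinite ILTC.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    yhat = np.asarray(measured, dtype=float)
    if not (lower.shape == upper.shape == yhat.shape) or yhat.size == 0:
        raise ValueError("band/measurement shape mismatch")
    if np.any(upper < lower):
        raise ValueError("upper band below lower band")
    nonzero = yhat > 0
    if not nonzero.any():
        raise ValueError("all measured values are zero; ARIL undefined")
    aril = float(np.mean((upper[nonzero] - lower[nonzero]) / yhat[nonzero]))
    coverage = float(np.mean((yhat >= lower) & (yhat <= upper)))
    iltc = aril / coverage if coverage > 0 else float("inf")
    return aril, coverage, iltc


def lcc_matrix(
    samples: np.ndarray,
    param_ids: Sequence[str],
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pearson correlation matrix of posterior draws with collinearity flags.

    Pairs with |LCC| above the identifiability threshold (default 0.7)
    are returned, signed, as non-identifiable.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] < 2:
        raise ValueError("need at least 2 parameters")
    if samples.shape[0] < 100:
        raise ValueError("need at least 100 joint samples")
    if np.any(samples.std(axis=0) == 0):
        dead = [p for p, s in zip(param_ids, samples.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance parameter column(s): {dead}")
    corr = np.corrcoef(samples, rowvar=False)
    frame = pd.DataFrame(corr, index=list(param_ids), columns=list(param_ids))
    flags = []
    for i in range(len(param_ids)):
        for j in range(i + 1, len(param_ids)):
            if abs(corr[i, j]) > threshold:
                flags.append((param_ids[i], param_ids[j], float(corr[i, j])))
    return frame, flags


def relative_ci_check(summary: PosteriorSummary, limit: float = 0.5) -> bool:
    """Identifiable when both CrI arms stay within ``limit`` of the median."""
    if summary.median <= 0:
        raise ValueError("relative CrI check needs a positive median")
    lo, hi = summary.cri95
    rel = max(abs(hi - summary.median), abs(summary.median - lo)) / summary.median
    return bool(rel < limit)


def src_gsa(
    parameter_samples: np.ndarray,
    output: np.ndarray,
    param_ids: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Standardised regression coefficients of a scalar output.

    Fits y ~ b0 + sum b_j x_j by least squares and reports
    SRC_j = b_j * sd(x_j) / sd(y) together with R^2.  R^2 < 0.7 means
    the linearity assumption is shaky and a warning is attached; a
    near-collinear design raises.
    """
    x = np.atleast_2d(np.asarray(parameter_samples, dtype=float))
    y = np.asarray(output, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("sample/output length mismatch")
    if param_ids is None:
        param_ids = [f"x{j}" for j in range(x.shape[1])]
    sx = x.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if np.any(sx == 0) or sy == 0:
        raise ValueError("zero-variance column in the SRC design")
    z = (x - x.mean(axis=0)) / sx
    if np.linalg.cond(z.T @ z) > 1e10:
        raise ValueError("collinear design matrix; SRC undefined")
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    src = pd.Series(coef[1:] * sx / sy, index=list(param_ids))
    if r2 < 0.7:
        import warnings

        warnings.warn(
            f"SRC linearity assumption weak (R^2 = {r2:.2f})", RuntimeWarning, stacklevel=2
        )
    return src, r2


@dataclass
class AssessmentReport:
    """Per-compound metrics plus posterior identifiability diagnostics."""

    metrics: pd.DataFrame  # compound, phase, rmse, mae, aril, coverage, iltc
    lcc: pd.DataFrame | None = None
    non_identifiable: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out = {"metrics": self.metrics.to_dict(orient="records")}
        if self.lcc is not None:
            out["lcc"] = self.lcc.to_dict()
        out["non_identifiable"] = [list(f) for f in self.non_identifiable]
        return out


def assess_predictions(
    net: PathwayNetwork,
    samples: np.ndarray,
    param_ids: Sequence[str],
    data,
    phases: Sequence[tuple[str, str]] = (("abiotic", "abiotic"), ("biotic", "combined")),
    n_draws: int = 500,
    seed: int = 0,
    extra_params: Mapping[str, float] | None = None,
    lcc_threshold: float = 0.7,
) -> AssessmentReport:
    """Full accuracy/uncertainty table for a calibrated model.

    ``phases`` maps data phase -> simulation phase.  Predictions use the
    posterior median trajectory; bands come from joint posterior draws.
    """
    rows = []
    for data_phase, sim_phase in phases:
        compounds = [c for c in net.observed_ids if c in data.compounds(data_phase)]
        if not compounds:
            continue
        tgrid = np.unique(
            np.concatenate([data.series(c, data_phase)[0] for c in compounds])
        )
        bands = mc_prediction_bands(
            net, samples, param_ids, sim_phase, tgrid,
            n_draws=n_draws, seed=seed, extra_params=extra_params,
        )
        for cid in compounds:
            t, y = data.series(cid, data_phase)
            lo, hi = bands.at(cid, t)
            idx = np.searchsorted(tgrid, t)
            pred = bands.median[cid][idx]
            rmse, mae = rmse_mae(y, pred)
            aril, cov, iltc = aril_coverage_iltc(lo, hi, y)
            rows.append(
                {
                    "compound": cid,
                    "phase": data_phase,
                    "rmse": rmse,
                    "mae": mae,
                    "aril": aril,
                    "coverage": cov,
                    "iltc": iltc,
                }
            )
    lcc = None
    flags: list = []
    if samples.shape[1] >= 2 and samples.shape[0] >= 100:
        keep = samples.std(axis=0) > 0
        if keep.sum() >= 2:
            lcc, flags = lcc_matrix(
                samples[:, keep],
                [p for p, k in zip(param_ids, keep) if k],
                threshold=lcc_threshold,
            )
    return AssessmentReport(metrics=pd.DataFrame(rows), lcc=lcc, non_identifiable=flags)
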