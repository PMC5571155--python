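"""Detection of pathway gaps and proposal of new transformation branches.

After a calibration stage, systematic disagreement between the fitted
model and the data indicates a structural defect rather than parameter
misestimation — typically a missing transformation branch.  The classic
signature: a parent compound's removal is fitted well (its own decay
constrains the total rate), but a downstream product is persistently
over-predicted because part of the parent's flux actually goes to an
unmeasured transformation product.

Three explicit triggers operationalise "systematic deviation":

* bias — the t-statistic of the mean signed residual exceeds 2;
* runs — a Wald-Wolfowitz runs test on residual signs rejects
  randomness at p < 0.05;
* mass balance — the model-implied net flux deviates from the observed
  accumulation rate with one sign at (almost) every interior time point
  and a material cumulative magnitude.

Any trigger marks the compound ``systematic``; proposals then add a
branch from each upstream source of an over-predicted product to an
unknown-TP sink, ranked by the magnitude of the product's deviation and
the source's flux contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .io import Dataset
from .network import Compound, PathwayNetwork, Trajectory, Transformation, simulate

__all__ = [
    "DeviationDiagnostic",
    "residual_diagnostics",
    "propose_branches",
    "runs_test_pvalue",
]

NEW_SINK = "TP_NEW"


def runs_test_pvalue(residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test on residual signs."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n = signs.size
    if n < 2:
        return 1.0
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        # all one sign: probability of this under random signs
        return min(1.0, 2.0 * 0.5**(n - 1))
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class DeviationDiagnostic:
    compound: str
    bias_t: float                      # mean signed residual / (sd / sqrt(n))
    mean_residual: float               # measured - predicted, µg/L
    runs_p: float
    mass_deficit: np.ndarray           # observed minus implied net flux, µg/L/d
    verdict: str                       # 'ok' | 'systematic'
    triggers: tuple[str, ...] = ()
    formation_flux: dict = field(default_factory=dict)  # source -> (phase, flux)

    @property
    def over_predicted(self) -> bool:
        return self.verdict == "systematic" and self.mean_residual < 0


def residual_diagnostics(
    net: PathwayNetwork,
    params: Mapping[str, float],
    data: Dataset,
    phase: str = "biotic",
    bias_limit: float = 2.0,
    runs_alpha: float = 0.05,
    deficit_sign_frac: float = 1.0,
    deficit_rel_mag: float = 0.05,
    rel_loq: float = 0.02,
) -> dict[str, DeviationDiagnostic]:
    """Per-compound deviation verdicts for a fitted model.

    ``phase`` names the experiment ('abiotic' or 'biotic'); biotic
    experiments are simulated with the combined model.  The mass-balance
    trigger requires every interior flux residual to share one sign and
    the time-integrated deficit to exceed ``deficit_rel_mag`` of the
    compound's concentration scale.

    Residual signs below a relative quantification limit (measured value
    under ``rel_loq`` of the series' maximum) carry no information — the
    range-normalised objective gives those points negligible weight, so
    their tiny residuals inherit the sign of the local fit bias and
    would fake long runs.  They are excluded from the bias and runs
    triggers.
    """
    sim_phase = "abiotic" if phase == "abiotic" else "combined"
    compounds = [c for c in net.observed_ids if c in data.compounds(phase)]
    if not compounds:
        raise ValueError(f"no measured compounds for phase {phase!r}")
    tgrid = np.unique(np.concatenate([data.series(c, phase)[0] for c in compounds]))
    traj = simulate(net, dict(params), sim_phase, tgrid)

    # trajectory built from the measured data, for mass-balance fluxes;
    # unmeasured states fall back to the model prediction
    conc = []
    for cid in net.compound_ids:
        if cid in compounds:
            t, y = data.series(cid, phase)
            conc.append(np.interp(tgrid, t, y))
        else:
            conc.append(traj.series(cid))
    data_traj = Trajectory(
        times=tgrid, compound_ids=net.compound_ids, concentrations=np.vstack(conc)
    )
    from .network import mass_balance_flux

    deficits = mass_balance_flux(net, data_traj, dict(params), sim_phase)

    out: dict[str, DeviationDiagnostic] = {}
    for cid in compounds:
        t, y = data.series(cid, phase)
        if y.size < 5:
            raise ValueError(f"fewer than 5 residuals for {cid!r}")
        pred = traj.series(cid)[np.searchsorted(tgrid, t)]
        r = y - pred
        quant = y >= rel_loq * y.max()
        rq = r[quant] if quant.sum() >= 5 else r
        sd = float(np.std(rq, ddof=1))
        bias_t = float(np.mean(rq) / (sd / np.sqrt(rq.size))) if sd > 0 else 0.0
        runs_p = runs_test_pvalue(rq)

        deficit = deficits[cid]
        interior = deficit[1:-1]
        triggers = []
        if abs(bias_t) > bias_limit:
            triggers.append("bias")
        if runs_p < runs_alpha:
            triggers.append("runs")
        if interior.size >= 3:
            sign_frac = max(np.mean(interior > 0), np.mean(interior < 0))
            cum = float(np.trapezoid(deficit, tgrid))
            scale = max(float(np.max(y)), 1e-12)
            if sign_frac >= deficit_sign_frac and abs(cum) > deficit_rel_mag * scale:
                triggers.append("mass_balance")

        # model-implied time-integrated formation flux per upstream source
        flux: dict[str, tuple[str, float]] = {}
        for e in net.formation_edges(cid, sim_phase):
            k = e.frozen_value if e.frozen_value is not None else params[e.param_id]
            rate = k * (net.tss if e.phase == "biotic" else 1.0)
            f = float(np.trapezoid(rate * e.stoich * traj.series(e.source), tgrid))
            key = e.source
            prev = flux.get(key, (e.phase, 0.0))
            flux[key] = (e.phase, prev[1] + f)

        out[cid] = DeviationDiagnostic(
            compound=cid,
            bias_t=bias_t,
            mean_residual=float(np.mean(r)),
            runs_p=runs_p,
            mass_deficit=deficit,
            verdict="systematic" if triggers else "ok",
            triggers=tuple(triggers),
            formation_flux=flux,
        )
    return out


def propose_branches(
    net: PathwayNetwork,
    diagnostics: Mapping[str, DeviationDiagnostic],
    phase: str = "biotic",
) -> list[tuple[PathwayNetwork, str, float]]:
    """Candidate networks adding source→unknown-TP branches.

    For every systematically over-predicted compound, each of its
    upstream sources gains a candidate branch to an unknown
    transformation product in ``phase`` (sources that already feed an
    unobserved sink in that phase are skipped: a second parallel sink
    edge would be structurally unidentifiable).  Candidates are ranked
    by |product deviation| x source flux share, largest first.  The
    caller re-fits each candidate; a genuine gap shows up as a lower
    minimal SSE.
    """
    flagged = [d for d in diagnostics.values() if d.verdict == "systematic"]
    if not flagged:
        raise ValueError("no systematic deviations; nothing to propose")
    short = "abio" if phase == "abiotic" else "bio"
    proposals: dict[str, tuple[float, str]] = {}
    for diag in flagged:
        if diag.mean_residual >= 0:
            continue  # under-prediction: not the missing-branch signature
        total_flux = sum(f for _p, f in diag.formation_flux.values()) or 1.0
        for source, (_ephase, f) in diag.formation_flux.items():
            if not net.compound(source).observed:
                continue
            has_sink_edge = any(
                not net.compound(e.product).observed
                for e in net.removal_edges(source, phase)
            )
            if has_sink_edge:
                continue
            score = abs(diag.mean_residual) * (f / total_flux)
            if source not in proposals or proposals[source][0] < score:
                proposals[source] = (score, diag.compound)
    if not proposals:
        raise ValueError("over-predicted products have no eligible upstream source")

    out = []
    for source, (score, _product) in sorted(
        proposals.items(), key=lambda kv: -kv[1][0]
    ):
        compounds = list(net.compounds)
        if NEW_SINK not in net.compound_ids:
            compounds.append(Compound(NEW_SINK, observed=False))
        new_edge = Transformation(
            source=source,
            product=NEW_SINK,
            phase=phase,
            param_id=f"k_{short}_{source}_TP",
        )
        candidate = PathwayNetwork(
            compounds=compounds, edges=list(net.edges) + [new_edge], tss=net.tss
        )
        out.append((candidate, source, score))
    return out
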