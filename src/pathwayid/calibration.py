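"""Sequential level-wise calibration of pathway models (Methods 1-3).

The pathway is decomposed into calibration levels ordered by the flow
of mass: a compound's abiotic rate constant can only be estimated once
the rates of every compound feeding it are constrained, and the biotic
rate of a compound is scheduled one level after its abiotic rate so the
abiotic posterior can serve as a subsidiary prior (biotic batch
experiments undergo both process classes, so the combined model is
simulated against biotic data).

A compound with two transformation branches is handled in two steps:
its *combinatorial* total removal rate is estimated at the compound's
own level (the branches lumped into a single sink edge), and the branch
rate constants become *primary* at the first later level at which some
observed branch product's own removal rate is itself primary — that is
the earliest point where the branch flux can be separated from the
product's further transformation.

Three calibration strategies share this machinery:

* Method 1 (sequential, sound propagation): subsidiary priors are the
  upstream posterior's fitted distribution truncated to its 95% CrI;
  branch pairs are sampled jointly under a soft constraint keeping
  their sum inside the total's 95% CrI.
* Method 2 (lumped): all abiotic parameters fitted at once against the
  abiotic data with wide uniform priors, then all biotic parameters at
  once with abiotic parameters uniform over their 95% CrI.
* Method 3 (sequential, no propagation): upstream parameters are frozen
  at their posterior medians, and a branch pair is reparameterised by
  the hard constraint member_1 = total - member_2, which makes the pair
  perfectly anti-correlated by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import Dataset
from .network import Compound, NetworkError, PathwayNetwork, Transformation, simulate
from .priors import (
    ParameterSpec,
    PointMassPrior,
    PosteriorSummary,
    UniformPrior,
    make_uniform_prior,
    propagate,
    summarize_posterior,
)
from .sampler import (
    SamplerConfig,
    SamplerResult,
    demc_sample,
    filter_by_tic,
    normalized_sse,
    sse_log_likelihood,
)

__all__ = [
    "CalibrationConfig",
    "CalibrationLevel",
    "StageResult",
    "CalibrationResult",
    "plan_levels",
    "run_level",
    "calibrate_method1",
    "calibrate_method2",
    "calibrate_method3",
    "map_fit",
]

log = logging.getLogger("pathwayid")

LUMP_SINK = "_LUMP"


@dataclass
class CalibrationConfig:
    """Prior bounds, sampler budget and filtering thresholds."""

    prior_hi_abiotic: float = 50.0
    prior_hi_biotic: float = 50.0
    # Method 2 deliberately uses wide, uninformative bounds; results are
    # known to be sensitive to this choice, which is the point of the
    # benchmark.
    method2_prior_hi_abiotic: float = 100.0
    method2_prior_hi_biotic: float = 100.0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    tic_threshold: float = 0.3
    tic_mode: str = "max"
    fit_distributions: bool = True


@dataclass
class CalibrationLevel:
    """One stage of the sequential plan (e.g. level 2, abiotic)."""

    index: int
    phase: str  # 'A' (abiotic data) or 'B' (biotic data, combined model)
    primary_ids: tuple[str, ...] = ()
    combinatorial: dict = field(default_factory=dict)  # total_id -> member ids
    splits: dict = field(default_factory=dict)  # total_id -> member ids
    frozen: dict = field(default_factory=dict)  # introduced frozen values
    subsidiary_ids: tuple[str, ...] = ()
    data_compounds: tuple[str, ...] = ()
    lumped: dict = field(default_factory=dict)  # (compound, edge phase) -> total_id
    kept_edge_params: frozenset = frozenset()
    sim_phase: str = "abiotic"

    @property
    def label(self) -> str:
        return f"{self.index}({self.phase})"

    @property
    def estimated_ids(self) -> tuple[str, ...]:
        members = tuple(m for ms in self.splits.values() for m in ms)
        return self.primary_ids + tuple(self.combinatorial) + members

    def is_noop(self) -> bool:
        return not (self.primary_ids or self.combinatorial or self.splits)


@dataclass
class StageResult:
    stage: CalibrationLevel
    param_ids: list[str]
    samples: np.ndarray  # (n_kept_after_tic, len(param_ids))
    summaries: dict
    acceptance_rate: float = float("nan")
    rhat: dict = field(default_factory=dict)
    tic_rejection: float = 0.0
    n_evals: int = 0

    def column(self, pid: str) -> np.ndarray:
        return self.samples[:, self.param_ids.index(pid)]


@dataclass
class CalibrationResult:
    method: int
    plan: list[CalibrationLevel]
    stages: list[StageResult]
    store: dict

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for pid, summ in sorted(self.store.items()):
            if isinstance(summ, PosteriorSummary):
                rows.append(
                    {
                        "param": pid,
                        "median": summ.median,
                        "cri_lo": summ.cri95[0],
                        "cri_hi": summ.cri95[1],
                        "family": summ.fitted.family if summ.fitted else None,
                        "combinatorial": bool(summ.member_ids),
                    }
                )
            else:  # frozen value
                rows.append(
                    {
                        "param": pid,
                        "median": float(summ),
                        "cri_lo": float(summ),
                        "cri_hi": float(summ),
                        "family": "frozen",
                        "combinatorial": False,
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# level planning
# --------------------------------------------------------------------------


def _topo_levels(net: PathwayNetwork, phase: str) -> dict[str, int]:
    """Longest-path level of each observed compound along ``phase`` edges."""
    obs = set(net.observed_ids)
    levels: dict[str, int] = {}
    remaining = set(obs)
    while remaining:
        progressed = False
        for cid in sorted(remaining):
            preds = [
                e.source
                for e in net.formation_edges(cid, phase)
                if e.source in obs
            ]
            if all(p in levels for p in preds):
                levels[cid] = 1 + max((levels[p] for p in preds), default=0)
                remaining.discard(cid)
                progressed = True
        if not progressed:  # pragma: no cover - acyclicity already validated
            raise NetworkError("cyclic dependency while levelling")
    return levels


def _phase_schedule(net: PathwayNetwork, phase: str, level_map: dict[str, int]):
    """Parameter scheduling for one phase.

    Returns ``singles`` (param -> level), ``frozen`` (param -> (level,
    value)) and ``branches`` (compound -> dict with total_id, members,
    total_level, split_level).
    """
    short = "abio" if phase == "abiotic" else "bio"
    singles: dict[str, int] = {}
    frozen: dict[str, tuple[int, float]] = {}
    branches: dict[str, dict] = {}
    existing = {e.param_id for e in net.edges}
    for cid in net.observed_ids:
        redges = net.removal_edges(cid, phase)
        if not redges:
            continue
        live = [e for e in redges if e.frozen_value is None]
        for e in redges:
            if e.frozen_value is not None:
                frozen[e.param_id] = (level_map[cid], e.frozen_value)
        if len(live) == 1:
            singles[live[0].param_id] = level_map[cid]
        elif len(live) >= 2:
            total_id = f"k_{short}_{cid}"
            if total_id in existing:
                total_id += "_total"
            members = tuple(sorted(e.param_id for e in live))
            obs_products = [
                e.product for e in live if net.compound(e.product).observed
            ]
            lvl = level_map[cid]
            if obs_products:
                split = max(lvl + 1, min(level_map[p] for p in obs_products))
            else:
                split = lvl + 1
            branches[cid] = {
                "total_id": total_id,
                "members": members,
                "total_level": lvl,
                "split_level": split,
            }
    return singles, frozen, branches


def plan_levels(net: PathwayNetwork) -> list[CalibrationLevel]:
    """Decompose a network into an ordered sequential calibration plan.

    The plan is a pure function of the network structure.  Abiotic
    stages of a level index precede the biotic stage of the same index;
    empty stages are omitted.
    """
    has_abio = any(e.phase == "abiotic" for e in net.edges)
    has_bio = any(e.phase == "biotic" for e in net.edges)
    abio_level = _topo_levels(net, "abiotic")
    topo_bio = _topo_levels(net, "biotic")
    if has_abio:
        bio_level = {c: max(topo_bio[c], abio_level[c] + 1) for c in topo_bio}
    else:
        bio_level = topo_bio

    schedules = {}
    if has_abio:
        schedules["A"] = _phase_schedule(net, "abiotic", abio_level)
    if has_bio:
        schedules["B"] = _phase_schedule(net, "biotic", bio_level)

    max_level = 0
    for letter, (singles, frozen, branches) in schedules.items():
        for lvl in singles.values():
            max_level = max(max_level, lvl)
        for lvl, _ in frozen.values():
            max_level = max(max_level, lvl)
        for b in branches.values():
            max_level = max(max_level, b["split_level"])

    raw_stages: list[CalibrationLevel] = []
    for idx in range(1, max_level + 1):
        for letter in ("A", "B"):
            if letter not in schedules:
                continue
            singles, frozen, branches = schedules[letter]
            stage = CalibrationLevel(
                index=idx,
                phase=letter,
                primary_ids=tuple(sorted(p for p, l in singles.items() if l == idx)),
                combinatorial={
                    b["total_id"]: b["members"]
                    for b in branches.values()
                    if b["total_level"] == idx
                },
                splits={
                    b["total_id"]: b["members"]
                    for b in branches.values()
                    if b["split_level"] == idx
                },
                frozen={p: v for p, (l, v) in frozen.items() if l == idx},
                sim_phase="abiotic" if letter == "A" else "combined",
            )
            if not (stage.is_noop() and not stage.frozen):
                raw_stages.append(stage)
    return _finalize_stages(net, raw_stages, schedules)


def _finalize_stages(
    net: PathwayNetwork,
    raw_stages: list[CalibrationLevel],
    schedules: dict,
) -> list[CalibrationLevel]:
    """Fill in data series, lumping, kept edges and subsidiaries per stage."""
    # branch bookkeeping by (compound, edge phase)
    branch_by_key: dict[tuple[str, str], dict] = {}
    for letter, (_s, _f, branches) in schedules.items():
        phase = "abiotic" if letter == "A" else "biotic"
        for cid, b in branches.items():
            branch_by_key[(cid, phase)] = b

    member_avail: set[str] = set()  # member-level params resolved so far
    total_avail: set[str] = set()  # totals estimated, not yet split
    frozen_all: dict[str, float] = {}
    out: list[CalibrationLevel] = []
    for stage in raw_stages:
        phase_letter = stage.phase
        active_phases = ("abiotic",) if phase_letter == "A" else ("abiotic", "biotic")
        # current-stage additions count as available within the stage
        cur_members = set(stage.primary_ids) | {
            m for ms in stage.splits.values() for m in ms
        }
        cur_totals = set(stage.combinatorial)
        frozen_all.update(stage.frozen)
        members_now = member_avail | cur_members
        totals_now = (total_avail | cur_totals) - set(stage.splits)

        def representation(cid: str, phase: str) -> str:
            """'member', 'total' or 'none' for the compound's removal."""
            redges = net.removal_edges(cid, phase)
            if not redges:
                return "member"  # nothing to represent
            live = [e for e in redges if e.frozen_value is None]
            if all(e.param_id in members_now for e in live):
                return "member"
            b = branch_by_key.get((cid, phase))
            if b is not None and b["total_id"] in totals_now:
                return "total"
            return "none"

        # objective compounds: removal representable, all strict ancestors
        # member-level (a lumped ancestor diverts flux away from products)
        data_compounds = []
        for cid in net.observed_ids:
            if not any(net.removal_edges(cid, p) for p in active_phases):
                continue
            rep = [representation(cid, p) for p in active_phases]
            if "none" in rep:
                continue
            ancestors = set()
            for p in active_phases:
                ancestors |= net.ancestors(cid, p)
            if all(
                representation(a, p) == "member"
                for a in ancestors
                for p in active_phases
            ):
                data_compounds.append(cid)
        data_compounds.sort()

        # ancestry closure for the effective model
        in_model = set(data_compounds)
        for cid in data_compounds:
            for p in active_phases:
                in_model |= net.ancestors(cid, p)

        lumped: dict[tuple[str, str], str] = {}
        kept: set[str] = set()
        for cid in sorted(in_model):
            for p in active_phases:
                rep = representation(cid, p)
                if rep == "total":
                    lumped[(cid, p)] = branch_by_key[(cid, p)]["total_id"]
                elif rep == "member":
                    for e in net.removal_edges(cid, p):
                        if e.frozen_value is None:
                            kept.add(e.param_id)

        needed = kept | set(lumped.values())
        current = cur_members | cur_totals
        subsidiary = tuple(sorted(needed - current - set(frozen_all)))
        out.append(
            replace(
                stage,
                subsidiary_ids=subsidiary,
                data_compounds=tuple(data_compounds),
                lumped=lumped,
                kept_edge_params=frozenset(kept),
            )
        )
        member_avail |= cur_members
        total_avail = totals_now

    # orphan check: every live parameter must be scheduled somewhere
    scheduled = set(frozen_all)
    for st in out:
        scheduled |= set(st.estimated_ids)
    live = {e.param_id for e in net.edges if e.frozen_value is None}
    orphans = live - scheduled - {
        b["total_id"] for b in branch_by_key.values()
    }
    if orphans:
        raise NetworkError(f"orphan parameters never scheduled: {sorted(orphans)}")
    return out


# --------------------------------------------------------------------------
# stage execution
# --------------------------------------------------------------------------


def _effective_network(net: PathwayNetwork, stage: CalibrationLevel) -> PathwayNetwork:
    """Network as seen at a stage: lumped totals, unresolved edges dropped."""
    active_phases = ("abiotic",) if stage.phase == "A" else ("abiotic", "biotic")
    compounds = list(net.compounds)
    if stage.lumped:
        compounds.append(Compound(LUMP_SINK, observed=False))
    edges: list[Transformation] = []
    for cid in net.compound_ids:
        for p in active_phases:
            if (cid, p) in stage.lumped:
                edges.append(
                    Transformation(
                        source=cid,
                        product=LUMP_SINK,
                        phase=p,
                        param_id=stage.lumped[(cid, p)],
                    )
                )
                continue
            for e in net.removal_edges(cid, p):
                if e.frozen_value is not None or e.param_id in stage.kept_edge_params:
                    edges.append(e)
    return PathwayNetwork(compounds=compounds, edges=edges, tss=net.tss)


def _build_specs(
    stage: CalibrationLevel,
    store: Mapping,
    config: CalibrationConfig,
    subsidiary_mode: str,
    hard_split: bool,
    prior_hi: Mapping[str, float] | None = None,
):
    """Parameter specs, soft sum constraints and hard-split bookkeeping."""

    def hi_for(pid: str) -> float:
        if prior_hi and pid in prior_hi:
            return prior_hi[pid]
        is_bio = pid.startswith("k_bio")
        if subsidiary_mode == "uniform":  # Method 2 wide bounds
            return config.method2_prior_hi_biotic if is_bio else config.method2_prior_hi_abiotic
        return config.prior_hi_biotic if is_bio else config.prior_hi_abiotic

    specs: list[ParameterSpec] = []
    sum_constraints: list[tuple[list[str], float, float]] = []
    derived: list[tuple[str, float, list[str]]] = []  # (derived pid, total, free ids)

    for pid in stage.primary_ids:
        specs.append(make_uniform_prior(pid, 0.0, hi_for(pid)))
    for total_id, members in stage.combinatorial.items():
        specs.append(
            make_uniform_prior(total_id, 0.0, hi_for(total_id), role="combinatorial",
                               member_ids=members)
        )
    for total_id, members in stage.splits.items():
        if total_id not in store:
            raise KeyError(f"combinatorial posterior {total_id!r} missing from store")
        total_post = store[total_id]
        members = tuple(sorted(members))
        if hard_split:
            total_value = total_post.median
            free_ids = list(members[1:])
            for mid in free_ids:
                specs.append(make_uniform_prior(mid, 0.0, total_value))
            derived.append((members[0], total_value, free_ids))
        else:
            lo, hi = total_post.cri95
            for mid in members:
                specs.append(make_uniform_prior(mid, 0.0, hi))
            sum_constraints.append((list(members), max(lo, 0.0), hi))
    for pid in stage.subsidiary_ids:
        if pid not in store:
            raise KeyError(f"subsidiary posterior {pid!r} missing from store")
        post = store[pid]
        if subsidiary_mode == "point":
            specs.append(ParameterSpec(pid, "subsidiary", PointMassPrior(post.median)))
        elif subsidiary_mode == "uniform":
            lo, hi = post.cri95
            specs.append(
                ParameterSpec(pid, "subsidiary", UniformPrior(max(lo, 0.0), hi))
            )
        elif subsidiary_mode == "distribution":
            specs.append(propagate(post))
        else:
            raise ValueError(f"unknown subsidiary mode {subsidiary_mode!r}")
    return specs, sum_constraints, derived


def run_level(
    stage: CalibrationLevel,
    net: PathwayNetwork,
    data: Dataset,
    store: dict,
    config: CalibrationConfig,
    subsidiary_mode: str = "distribution",
    hard_split: bool = False,
    seed: int | None = None,
    prior_hi: Mapping[str, float] | None = None,
) -> StageResult:
    """Execute one calibration stage and add its posteriors to ``store``.

    The objective covers the measured series of every compound resolved
    up to this stage; subsidiary parameters are sampled from their
    propagated priors alongside the stage's primaries, so upstream
    uncertainty flows into the new posteriors.
    """
    for pid, val in stage.frozen.items():
        store.setdefault(pid, float(val))
    if stage.is_noop():
        warnings.warn(f"stage {stage.label} has no parameters to estimate")
        return StageResult(stage=stage, param_ids=[], samples=np.empty((0, 0)), summaries={})

    specs, sum_constraints, derived = _build_specs(
        stage, store, config, subsidiary_mode, hard_split, prior_hi
    )
    spec_ids = [s.param_id for s in specs]
    eff_net = _effective_network(net, stage)
    data_phase = "abiotic" if stage.phase == "A" else "biotic"

    measured: list[np.ndarray] = []
    time_arrays: list[np.ndarray] = []
    used_compounds: list[str] = []
    for cid in stage.data_compounds:
        try:
            t, y = data.series(cid, data_phase)
        except KeyError:
            warnings.warn(f"no {data_phase} data for {cid}; dropped from objective")
            continue
        measured.append(y)
        time_arrays.append(t)
        used_compounds.append(cid)
    if not measured:
        raise ValueError(f"stage {stage.label}: no measured series available")
    n_obs = int(sum(len(y) for y in measured))

    tgrid = np.unique(np.concatenate(time_arrays))
    tindex = [np.searchsorted(tgrid, t) for t in time_arrays]

    frozen_params = {
        pid: val for pid, val in store.items() if not isinstance(val, PosteriorSummary)
    }

    def predict(theta: np.ndarray) -> list[np.ndarray]:
        params = dict(zip(spec_ids, theta))
        for dpid, total_value, free_ids in derived:
            params[dpid] = total_value - sum(params[f] for f in free_ids)
        params.update(frozen_params)
        traj = simulate(eff_net, params, stage.sim_phase, tgrid)
        return [traj.series(cid)[idx] for cid, idx in zip(used_compounds, tindex)]

    priors = [s.prior for s in specs]

    def logp(theta: np.ndarray) -> float:
        lp = 0.0
        for prior, x in zip(priors, theta):
            lp += prior.logpdf(x)
            if not np.isfinite(lp):
                return -np.inf
        for ids, lo, hi in sum_constraints:
            s = sum(theta[spec_ids.index(i)] for i in ids)
            if not lo <= s <= hi:
                return -np.inf
        for _dpid, total_value, free_ids in derived:
            if total_value - sum(theta[spec_ids.index(f)] for f in free_ids) < 0:
                return -np.inf
        try:
            preds = predict(theta)
            sse = normalized_sse(measured, preds)
        except Exception as exc:  # simulation failure
            log.warning("simulation failed at stage %s: %s", stage.label, exc)
            return -np.inf
        return lp + sse_log_likelihood(sse, n_obs)

    scfg = config.sampler if seed is None else replace(config.sampler, seed=seed)
    result: SamplerResult = demc_sample(logp, priors, scfg)

    # reconstruct full-theta draws (point-mass dims back in)
    full = np.empty((result.samples.shape[0], len(specs)))
    full[:, result.free_mask] = result.samples
    for j, s in enumerate(specs):
        if s.prior.is_point:
            full[:, j] = s.prior.lo

    filtered, _mask, rejection = filter_by_tic(
        full, predict, measured, threshold=config.tic_threshold, mode=config.tic_mode
    )

    # append hard-split derived members as explicit columns
    param_ids = list(spec_ids)
    samples = filtered
    for dpid, total_value, free_ids in derived:
        col = total_value - samples[:, [param_ids.index(f) for f in free_ids]].sum(axis=1)
        samples = np.column_stack([samples, col])
        param_ids.append(dpid)

    summaries = {}
    for pid in stage.estimated_ids:
        col = samples[:, param_ids.index(pid)]
        member_ids = stage.combinatorial.get(pid, ())
        summ = summarize_posterior(
            pid, col, fit=config.fit_distributions, member_ids=member_ids
        )
        summaries[pid] = summ
        store[pid] = summ

    return StageResult(
        stage=stage,
        param_ids=param_ids,
        samples=samples,
        summaries=summaries,
        acceptance_rate=result.acceptance_rate,
        rhat={
            pid: float(r)
            for pid, r in zip(
                [p for p, f in zip(spec_ids, result.free_mask) if f],
                result.rhat,
            )
        },
        tic_rejection=rejection,
        n_evals=result.n_evals,
    )


# --------------------------------------------------------------------------
# methods 1-3
# --------------------------------------------------------------------------


def _stage_seed(base: int, i: int) -> int:
    return int((base * 9973 + 101 * (i + 1)) % (2**31 - 1))


def calibrate_method1(
    net: PathwayNetwork, data: Dataset, config: CalibrationConfig
) -> CalibrationResult:
    """Sequential estimation with full uncertainty propagation."""
    plan = plan_levels(net)
    store: dict = {}
    stages = []
    base = config.sampler.seed
    for i, stage in enumerate(plan):
        stages.append(
            run_level(
                stage, net, data, store, config,
                subsidiary_mode="distribution", hard_split=False,
                seed=_stage_seed(base, i),
            )
        )
        log.info("method 1 stage %s done (acc=%.2f)", stage.label, stages[-1].acceptance_rate)
    return CalibrationResult(method=1, plan=plan, stages=stages, store=store)


def calibrate_method3(
    net: PathwayNetwork, data: Dataset, config: CalibrationConfig
) -> CalibrationResult:
    """Sequential estimation with upstream parameters frozen at medians."""
    plan = plan_levels(net)
    store: dict = {}
    stages = []
    base = config.sampler.seed
    for i, stage in enumerate(plan):
        stages.append(
            run_level(
                stage, net, data, store, config,
                subsidiary_mode="point", hard_split=True,
                seed=_stage_seed(base, 7919 + i),
            )
        )
    return CalibrationResult(method=3, plan=plan, stages=stages, store=store)


def _lumped_stage(net: PathwayNetwork, phase_letter: str) -> CalibrationLevel:
    """A single stage estimating every parameter of one model at once."""
    phase = "abiotic" if phase_letter == "A" else "biotic"
    live = tuple(sorted(
        e.param_id for e in net.edges if e.phase == phase and e.frozen_value is None
    ))
    frozen = {
        e.param_id: e.frozen_value
        for e in net.edges
        if e.phase == phase and e.frozen_value is not None
    }
    active = ("abiotic",) if phase_letter == "A" else ("abiotic", "biotic")
    data_compounds = tuple(sorted(
        cid for cid in net.observed_ids
        if any(net.removal_edges(cid, p) for p in active)
    ))
    kept = {
        e.param_id for e in net.edges
        if e.phase in active and e.frozen_value is None
    }
    abio_live = tuple(sorted(
        e.param_id for e in net.edges if e.phase == "abiotic" and e.frozen_value is None
    ))
    return CalibrationLevel(
        index=1,
        phase=phase_letter,
        primary_ids=live,
        frozen=frozen,
        subsidiary_ids=() if phase_letter == "A" else abio_live,
        data_compounds=data_compounds,
        kept_edge_params=frozenset(kept),
        sim_phase="abiotic" if phase_letter == "A" else "combined",
    )


def calibrate_method2(
    net: PathwayNetwork, data: Dataset, config: CalibrationConfig
) -> CalibrationResult:
    """Lumped estimation: one objective per model, wide uniform priors.

    The biotic stage carries the abiotic posteriors as uniform
    subsidiary priors over their 95% CrIs.
    """
    store: dict = {}
    stages = []
    plan = []
    base = config.sampler.seed
    for i, letter in enumerate(("A", "B")):
        if not any(
            e.phase == ("abiotic" if letter == "A" else "biotic") for e in net.edges
        ):
            continue
        stage = _lumped_stage(net, letter)
        plan.append(stage)
        stages.append(
            run_level(
                stage, net, data, store, config,
                subsidiary_mode="uniform", hard_split=False,
                seed=_stage_seed(base, 104729 + i),
            )
        )
    return CalibrationResult(method=2, plan=plan, stages=stages, store=store)


# --------------------------------------------------------------------------
# deterministic best fit (used by diagnostics and structure comparison)
# --------------------------------------------------------------------------


def map_fit(
    net: PathwayNetwork,
    data: Dataset,
    seed: int = 0,
    n_starts: int = 8,
    prior_hi_abiotic: float = 50.0,
    prior_hi_biotic: float = 50.0,
) -> tuple[dict[str, float], float]:
    """Multistart bounded least squares on the normalised residuals.

    Fits all live rate constants jointly (abiotic model against abiotic
    data, combined model against biotic data) and returns the best
    parameter map with its normalised SSE.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed)
    live = sorted(e.param_id for e in net.edges if e.frozen_value is None)
    hi = np.array(
        [prior_hi_biotic if p.startswith("k_bio") else prior_hi_abiotic for p in live]
    )

    blocks = []
    for phase_letter, data_phase, sim_phase in (
        ("A", "abiotic", "abiotic"),
        ("B", "biotic", "combined"),
    ):
        if not any(
            e.phase == ("abiotic" if phase_letter == "A" else "biotic")
            for e in net.edges
        ):
            continue
        series = []
        for cid in net.observed_ids:
            try:
                t, y = data.series(cid, data_phase)
            except KeyError:
                continue
            series.append((cid, t, y))
        if not series:
            continue
        tgrid = np.unique(np.concatenate([t for _c, t, _y in series]))
        idx = [np.searchsorted(tgrid, t) for _c, t, _y in series]
        blocks.append((sim_phase, tgrid, series, idx))

    def residuals(x: np.ndarray) -> np.ndarray:
        params = dict(zip(live, x))
        out = []
        for sim_phase, tgrid, series, idx in blocks:
            traj = simulate(net, params, sim_phase, tgrid)
            for (cid, _t, y), ix in zip(series, idx):
                pred = traj.series(cid)[ix]
                rng_y = np.ptp(y)
                out.append((y - pred) / (rng_y if rng_y > 0 else 1.0))
        return np.concatenate(out)

    best_x, best_sse = None, np.inf
    for s in range(n_starts):
        x0 = rng.uniform(0.0, 0.2 * hi) if s else np.full(len(live), 0.05) * hi
        try:
            sol = least_squares(residuals, x0, bounds=(0.0, hi), method="trf")
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if sse < best_sse:
            best_sse, best_x = sse, sol.x
    if best_x is None:
        raise RuntimeError("all least-squares starts failed")
    return dict(zip(live, best_x)), best_sse
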