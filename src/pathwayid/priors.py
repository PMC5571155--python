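"""Parameter roles, priors, posterior summaries and uncertainty propagation.

Parameters play one of three roles across a sequential calibration:

* ``primary`` — estimated for the first time, uniform prior with
  user-chosen bounds;
* ``subsidiary`` — estimated at an earlier level and carried forward;
  its prior is the best-fitting parametric distribution truncated to the
  posterior's 95% credibility interval, so both the range and the shape
  of upstream uncertainty propagate;
* ``combinatorial`` — the total removal rate of a compound with two
  transformation branches (the sum of the branch rate constants),
  estimated at the compound's own level and split into primaries later.

Posterior summaries use the central 95% credibility interval (2.5th to
97.5th percentile, linear-interpolation rule) around the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Prior",
    "UniformPrior",
    "PointMassPrior",
    "TruncatedDistributionPrior",
    "FittedDistribution",
    "ParameterSpec",
    "PosteriorSummary",
    "make_uniform_prior",
    "fit_distribution",
    "summarize_posterior",
    "propagate",
    "split_member_priors",
    "FIT_FAMILIES",
]

ROLES = ("primary", "subsidiary", "combinatorial")


class Prior:
    """Minimal prior interface: bounded support, log-density, sampling."""

    lo: float
    hi: float

    def logpdf(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def is_point(self) -> bool:
        return False


@dataclass
class UniformPrior(Prior):
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got [{self.lo}, {self.hi}]")
        self._logd = -math.log(self.hi - self.lo)

    def logpdf(self, x: float) -> float:
        return self._logd if self.lo <= x <= self.hi else -math.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=n)


@dataclass
class PointMassPrior(Prior):
    """Degenerate prior used for frozen values and Method-3 subsidiaries."""

    value: float

    def __post_init__(self) -> None:
        self.lo = self.hi = self.value

    def logpdf(self, x: float) -> float:
        return 0.0 if x == self.value else -math.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.value)

    @property
    def is_point(self) -> bool:
        return True


# scipy families for the supported subset of candidate posteriors.
# Positive-support families are fitted with the location pinned at zero:
# rate constants are non-negative and a free location destabilises the
# ML fit badly enough to dominate any BIC gain.
FIT_FAMILIES: dict[str, dict] = {
    "normal": {"dist": stats.norm, "kwds": {}, "k": 2},
    "lognormal": {"dist": stats.lognorm, "kwds": {"floc": 0.0}, "k": 2},
    "gamma": {"dist": stats.gamma, "kwds": {"floc": 0.0}, "k": 2},
    "weibull": {"dist": stats.weibull_min, "kwds": {"floc": 0.0}, "k": 2},
    "exponential": {"dist": stats.expon, "kwds": {"floc": 0.0}, "k": 1},
    "logistic": {"dist": stats.logistic, "kwds": {}, "k": 2},
    "loglogistic": {"dist": stats.fisk, "kwds": {"floc": 0.0}, "k": 2},
    "genextreme": {"dist": stats.genextreme, "kwds": {}, "k": 3},
    "beta": {"dist": stats.beta, "kwds": "rescale", "k": 2},
}


@dataclass
class FittedDistribution:
    family: str
    params: tuple
    bic: float

    def frozen(self):
        spec = FIT_FAMILIES[self.family]
        return spec["dist"](*self.params)


@dataclass
class TruncatedDistributionPrior(Prior):
    """A fitted parametric distribution restricted to [lo, hi].

    The density is renormalised so it integrates to one on the interval;
    sampling uses inverse-CDF mapping of uniform draws, which keeps the
    prior exactly supported on the credibility interval.
    """

    fitted: FittedDistribution
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("truncation interval must have positive width")
        self._frozen = self.fitted.frozen()
        c_lo, c_hi = self._frozen.cdf(self.lo), self._frozen.cdf(self.hi)
        mass = c_hi - c_lo
        if not np.isfinite(mass) or mass <= 1e-12:
            raise ValueError("fitted distribution has no mass on the interval")
        self._cdf_lo = c_lo
        self._mass = mass
        self._log_mass = math.log(mass)

    def logpdf(self, x: float) -> float:
        if not (self.lo <= x <= self.hi):
            return -math.inf
        return float(self._frozen.logpdf(x)) - self._log_mass

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.uniform(0.0, 1.0, size=n)
        x = self._frozen.ppf(self._cdf_lo + u * self._mass)
        return np.clip(x, self.lo, self.hi)


@dataclass
class ParameterSpec:
    """One rate constant entering an estimation problem."""

    param_id: str
    role: str
    prior: Prior
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "combinatorial" and len(self.member_ids) < 2:
            raise ValueError("a combinatorial parameter needs >= 2 member ids")


@dataclass
class PosteriorSummary:
    param_id: str
    samples: np.ndarray
    median: float
    cri95: tuple[float, float]
    fitted: FittedDistribution | None = None
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.cri95[0] <= self.median <= self.cri95[1]):
            raise ValueError("median must lie inside the credibility interval")

    @property
    def width(self) -> float:
        return self.cri95[1] - self.cri95[0]


def make_uniform_prior(
    param_id: str,
    lo: float,
    hi: float,
    role: str = "primary",
    member_ids: Sequence[str] = (),
) -> ParameterSpec:
    """A fresh uniform-prior spec for a primary or combinatorial parameter."""
    if lo < 0:
        raise ValueError("rate-constant priors cannot have negative bounds")
    return ParameterSpec(
        param_id=param_id,
        role=role,
        prior=UniformPrior(lo, hi),
        member_ids=tuple(member_ids),
    )


def fit_distribution(
    samples: np.ndarray,
    families: Sequence[str] | None = None,
    min_samples: int = 100,
) -> FittedDistribution:
    """Fit candidate parametric families by ML and pick the best by BIC.

    BIC = k ln n - 2 logL.  Families whose fit fails (unsupported data,
    non-convergence, non-finite likelihood) are silently skipped; at
    least one family must succeed.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) samples")
    names = list(families) if families is not None else list(FIT_FAMILIES)
    n = x.size
    best: FittedDistribution | None = None
    for name in names:
        spec = FIT_FAMILIES[name]
        dist = spec["dist"]
        try:
            if spec["kwds"] == "rescale":
                # beta on the sample range, slightly widened so the
                # endpoints carry finite density
                pad = 1e-9 + 1e-6 * np.ptp(x)
                loc, scale = x.min() - pad, np.ptp(x) + 2 * pad
                params = dist.fit(x, floc=loc, fscale=scale)
            else:
                if "floc" in spec["kwds"] and np.any(x <= 0):
                    continue
                params = dist.fit(x, **spec["kwds"])
            logl = float(np.sum(dist.logpdf(x, *params)))
            if not np.isfinite(logl):
                continue
            bic = spec["k"] * math.log(n) - 2.0 * logl
        except Exception:
            continue
        if best is None or bic < best.bic:
            best = FittedDistribution(family=name, params=tuple(params), bic=bic)
    if best is None:
        raise ValueError("no candidate family produced a finite fit")
    return best


def summarize_posterior(
    param_id: str,
    samples: np.ndarray,
    fit: bool = True,
    member_ids: Sequence[str] = (),
) -> PosteriorSummary:
    """Median, central 95% CrI and (optionally) a fitted distribution.

    Percentiles use the linear-interpolation rule so interval edges are
    reproducible — they become hard bounds for downstream priors.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty posterior sample")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate posterior for {param_id!r}")
    lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5], method="linear")
    fitted = None
    if fit:
        try:
            fitted = fit_distribution(x)
        except ValueError:
            fitted = None
    return PosteriorSummary(
        param_id=param_id,
        samples=x,
        median=float(med),
        cri95=(float(lo), float(hi)),
        fitted=fitted,
        member_ids=tuple(member_ids),
    )


def propagate(post: PosteriorSummary, point_mass: bool = False) -> ParameterSpec:
    """Turn an upstream posterior into a subsidiary prior.

    Default: the fitted distribution truncated to the 95% CrI (uniform
    on the CrI if no family fitted), so the subsidiary support never
    widens beyond what was learned upstream.  ``point_mass=True`` gives
    the no-propagation variant: the parameter frozen at its median.
    """
    if point_mass:
        prior: Prior = PointMassPrior(post.median)
    else:
        lo, hi = post.cri95
        if post.fitted is not None:
            try:
                prior = TruncatedDistributionPrior(post.fitted, lo, hi)
            except ValueError:
                prior = UniformPrior(max(lo, 0.0), hi)
        else:
            prior = UniformPrior(max(lo, 0.0), hi)
    return ParameterSpec(param_id=post.param_id, role="subsidiary", prior=prior)


def split_member_priors(total: PosteriorSummary) -> list[ParameterSpec]:
    """Primary priors for the branch members of an estimated total.

    Each member gets a uniform prior on [0, upper CrI bound of the
    total]; the joint constraint that the members sum into the total's
    CrI is enforced in the sampler, not in these marginals.
    """
    if not total.member_ids:
        raise ValueError(f"{total.param_id!r} is not a combinatorial posterior")
    hi = total.cri95[1]
    return [make_uniform_prior(mid, 0.0, hi) for mid in total.member_ids]
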