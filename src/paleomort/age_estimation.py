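"""Transition-analysis-style Bayesian age-at-death estimation.

Skeletal age indicators (e.g. pubic symphysis, auricular surface, cranial
suture sites) pass through ordered morphological stages with age. For each
trait a cumulative-link ("transition analysis") model gives the probability
of displaying each stage at a given age,

    Pr(stage >= j+1 | age) = F((age - mu_j) / s),

where mu_1 < ... < mu_{K-1} are mean ages-at-transition, s a common
dispersion, and F the logistic or normal CDF. Combining the stage
likelihoods of several traits (assumed conditionally independent given age)
with an informative prior age-at-death distribution by Bayes' theorem yields
a posterior over age for each skeleton, summarised by a point estimate
(posterior mean by default) and a highest-posterior-density interval.

The trait set and reference calibration are fully configurable: models can be
fitted to any known-age reference sample with :func:`fit_transition_models`
(an ordinal cumulative-link MLE) and serialised to plain dictionaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hazards import ENTRY_AGE, GompertzMakehamParams, cumulative_hazard, hazard

__all__ = [
    "TransitionModel",
    "AgePrior",
    "AgePosterior",
    "default_grid",
    "stage_probabilities",
    "age_posterior",
    "fit_transition_models",
]


def default_grid(lo: float = 15.0, hi: float = 110.0, step: float = 0.25) -> np.ndarray:
    """Calendar-age grid for posteriors: 15-110 years at 0.25-year steps."""
    return np.arange(lo, hi + step / 2, step)


_LINKS = {"logit": stats.logistic.cdf, "probit": stats.norm.cdf}


@dataclass(frozen=True)
class TransitionModel:
    """Cumulative-link stage-given-age model for one ordinal trait.

    thresholds are the mean calendar ages at transition between successive
    stages (strictly increasing); scale is the common dispersion in years.
    """

    trait: str
    thresholds: tuple
    scale: float
    link: str = "logit"

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if th.size < 1:
            raise ValueError(f"trait {self.trait}: need at least one threshold (two stages)")
        if np.any(np.diff(th) <= 0):
            raise ValueError(f"trait {self.trait}: thresholds must be strictly increasing")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"trait {self.trait}: scale must be > 0")
        if self.link not in _LINKS:
            raise ValueError(f"trait {self.trait}: link must be one of {sorted(_LINKS)}")
        object.__setattr__(self, "thresholds", tuple(float(v) for v in th))

    @property
    def n_stages(self) -> int:
        return len(self.thresholds) + 1

    def to_dict(self) -> dict:
        return {"trait": self.trait, "thresholds": list(self.thresholds),
                "scale": self.scale, "link": self.link}

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        return cls(trait=d["trait"], thresholds=tuple(d["thresholds"]),
                   scale=float(d["scale"]), link=d.get("link", "logit"))


def stage_probabilities(model: TransitionModel, age) -> np.ndarray:
    """Probability of each stage at the given age(s).

    For scalar age returns a vector of length n_stages summing to 1; for an
    age array of length m returns an (m, n_stages) matrix. Stages are
    numbered 1..K; entry j is Pr(stage = j+1 | age).
    """
    F = _LINKS[model.link]
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    th = np.asarray(model.thresholds)
    # Pr(stage >= j+1 | a) for each threshold j
    exceed = F((ages[:, None] - th[None, :]) / model.scale)
    upper = np.hstack([np.ones((len(ages), 1)), exceed])
    lower = np.hstack([exceed, np.zeros((len(ages), 1))])
    probs = upper - lower
    probs = np.clip(probs, 0.0, 1.0)
    return probs[0] if np.isscalar(age) or np.ndim(age) == 0 else probs


@dataclass(frozen=True)
class AgePrior:
    """Prior age-at-death distribution on a calendar-age grid.

    kind "uniform" is flat over the grid; kind "gompertz_makeham" is the
    age-at-death density of a GM mortality model conditioned on survival to
    the entry age (15 years), emulating an informative pre-industrial
    mortality profile.
    """

    kind: str = "uniform"
    params: GompertzMakehamParams | None = None
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gompertz_makeham"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "gompertz_makeham" and self.params is None:
            raise ValueError("gompertz_makeham prior requires params")
        g = np.asarray(self.grid, dtype=float)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be increasing with at least two points")
        object.__setattr__(self, "grid", g)

    def mass(self) -> np.ndarray:
        """Normalised prior mass on the grid (sums to 1)."""
        if self.kind == "uniform":
            m = np.ones_like(self.grid)
        else:
            t = self.grid - ENTRY_AGE
            m = hazard(self.params, t) * np.exp(-cumulative_hazard(self.params, t))
        return m / m.sum()


@dataclass(frozen=True)
class AgePosterior:
    """Discretised posterior over calendar age for one skeleton."""

    grid: np.ndarray
    density: np.ndarray  # posterior mass on the grid, sums to 1
    point: float  # posterior point estimate (mean by default)
    interval: tuple  # HPD credible interval (lo, hi)
    level: float

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.density))

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


def _hpd_interval(grid: np.ndarray, mass: np.ndarray, level: float) -> tuple:
    """Highest-density interval by density thresholding.

    Grid points are admitted in decreasing density order until the target
    mass is covered; the cut is refined by linear interpolation between the
    last-admitted and first-excluded densities at the interval ends.
    """
    order = np.argsort(mass)[::-1]
    csum = np.cumsum(mass[order])
    k = int(np.searchsorted(csum, level)) + 1
    sel = np.sort(order[:min(k, len(grid))])
    lo_i, hi_i = sel[0], sel[-1]
    lo, hi = grid[lo_i], grid[hi_i]
    cut = mass[order[min(k, len(grid)) - 1]]
    # refine the endpoints by interpolating to where density crosses the cut
    if lo_i > 0 and mass[lo_i - 1] < cut <= mass[lo_i]:
        f = (cut - mass[lo_i - 1]) / max(mass[lo_i] - mass[lo_i - 1], 1e-300)
        lo = grid[lo_i - 1] + f * (grid[lo_i] - grid[lo_i - 1])
    if hi_i < len(grid) - 1 and mass[hi_i + 1] < cut <= mass[hi_i]:
        f = (mass[hi_i] - cut) / max(mass[hi_i] - mass[hi_i + 1], 1e-300)
        hi = grid[hi_i] + f * (grid[hi_i + 1] - grid[hi_i])
    return (float(lo), float(hi))


def age_posterior(observed: dict, models, prior: AgePrior, level: float = 0.95,
                  point: str = "mean") -> AgePosterior:
    """Posterior over age given observed trait stages and a prior.

    Parameters
    ----------
    observed : dict
        Mapping trait name -> observed stage (1-based). Traits without an
        entry are simply omitted from the likelihood product; with no traits
        at all the posterior equals the prior.
    models : sequence of TransitionModel
        Must cover every observed trait.
    prior : AgePrior
    level : float
        HPD credibility level.
    point : {"mean", "mode"}
        Posterior point-estimate convention.
    """
    by_trait = {m.trait: m for m in models}
    missing = [k for k in observed if k not in by_trait]
    if missing:
        raise ValueError(f"no transition model for observed trait(s): {missing}")
    grid = prior.grid
    log_mass = np.log(np.maximum(prior.mass(), 1e-300))
    for trait, stage in observed.items():
        m = by_trait[trait]
        if not 1 <= int(stage) <= m.n_stages:
            raise ValueError(f"trait {trait}: stage {stage} outside 1..{m.n_stages}")
        probs = stage_probabilities(m, grid)[:, int(stage) - 1]
        log_mass = log_mass + np.log(np.maximum(probs, 1e-300))
    log_mass -= log_mass.max()
    mass = np.exp(log_mass)
    total = mass.sum()
    if not np.isfinite(total) or total <= len(grid) * 1e-250:
        raise ValueError(
            f"posterior numerically zero everywhere: incompatible stage combination {observed}"
        )
    mass /= total
    pt = float(np.sum(grid * mass)) if point == "mean" else float(grid[int(np.argmax(mass))])
    return AgePosterior(grid=grid, density=mass, point=pt,
                        interval=_hpd_interval(grid, mass, level), level=level)


def fit_transition_models(reference, traits=None, link: str = "logit",
                          min_n: int = 50) -> list:
    """Fit per-trait cumulative-link models to a known-age reference sample.

    Parameters
    ----------
    reference : pandas.DataFrame
        One row per individual with a calendar ``age`` column and one integer
        stage column per trait (1-based stages).
    traits : sequence of str, optional
        Trait columns to fit; defaults to every column except ``age``.
    link : {"logit", "probit"}
    min_n : int
        Minimum reference size.

    Returns
    -------
    list of TransitionModel

    Stages never observed in the reference are merged with their lower
    neighbour (with a warning); a trait reduced to a single observed stage is
    a validation error.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if len(reference) < min_n:
        raise ValueError(f"reference sample too small: {len(reference)} < {min_n}")
    if traits is None:
        traits = [c for c in reference.columns if c != "age"]
    out = []
    age = np.asarray(reference["age"], dtype=float)
    for trait in traits:
        raw = np.asarray(reference[trait], dtype=float)
        keep = np.isfinite(raw) & np.isfinite(age)
        stages = raw[keep].astype(int)
        a = age[keep]
        observed = np.unique(stages)
        if len(observed) < 2:
            raise ValueError(f"trait {trait}: fewer than two observed stages")
        # re-index stages densely; unobserved intermediate stages merge downward
        relabel = {s: i + 1 for i, s in enumerate(observed)}
        if len(observed) != observed.max() - observed.min() + 1:
            warnings.warn(f"trait {trait}: unobserved stage(s) merged with lower neighbour")
        y = np.array([relabel[s] for s in stages])
        model = OrderedModel(y, a[:, None], distr=link)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", disp=False)
        slope = float(res.params[0])
        cuts = model.transform_threshold_params(res.params)[1:-1]
        if slope <= 0:
            raise ValueError(f"trait {trait}: non-positive age slope; stages not ordered by age")
        scale = 1.0 / slope
        mus = tuple(float(c) * scale for c in cuts)
        out.append(TransitionModel(trait=trait, thresholds=mus, scale=scale, link=link))
    return out
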