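"""Stochastic layer: mutation timing, parent selection, trait inheritance
and the branching-process extinction filter.

Mutation events form an inhomogeneous Poisson process whose rate is the
total influx of mutated mitotic cells

    alpha(t) = sum_i alpha_i(t),    alpha_i = 2 * a_i * s(t) * p_i * l1_i * nu.

Events are generated by the integrated-hazard method: the accumulated hazard
Lambda(t) = int alpha dt is carried as an auxiliary ODE state, and an event
fires whenever Lambda crosses an Exp(1) threshold.  This is exact for
state-coupled rates and composes cleanly with adaptive integration.

A newly founded clone starts from a single mitotic cell and may die out by
chance.  Embedding the early growth in a Galton-Watson process with
offspring generating function

    f(x) = a^2 x^2 + 2 a (1-a) x + (1-a)^2

(where a is the self-renewal fraction of the clone's mitotic cells) gives
the extinction probability as the smaller root of f(x) = x, which simplifies
to p_e(a) = ((1-a)/a)^2 for a > 1/2 and p_e = 1 otherwise.  Clones are
introduced to the ODE system only if they pass a Bernoulli(1 - p_e) draw.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .model import TRAIT_BOUNDS, CloneParams, HealthyParams, SystemState, feedback_signal

_SQRT2 = math.sqrt(2.0)

__all__ = [
    "MutationConfig",
    "ExtinctionModel",
    "mutation_intensity",
    "next_event_hazard_threshold",
    "select_parent_clone",
    "sample_truncated_normal",
    "sample_offspring_traits",
    "extinction_probability",
    "clone_survives",
]


@dataclass(frozen=True)
class MutationConfig:
    """Configuration of the mutation process.

    Parameters
    ----------
    nu
        Mutation fraction per division (probability that a progeny cell
        carries a new mutation).  Default 5e-9; studied range 1e-11 .. 5e-8.
    sigma_schedule
        Standard deviation(s) of the truncated-normal trait jumps, indexed by
        the number of mutations separating the new clone from the founder: a
        clone of depth d (founder depth 1) is sampled with
        ``sigma_schedule[min(d - 2, len - 1)]``.  A scalar means a constant
        standard deviation for all mutations.  An increasing schedule models
        cooperativity of mutations.
    trait_bounds
        Admissible intervals for (a_max, p); samples are truncated to these.
    rng_seed
        Optional seed when the config is used standalone; the simulation
        engine supplies its own per-patient streams.
    """

    nu: float = 5e-9
    sigma_schedule: float | tuple[float, ...] = 0.005
    trait_bounds: dict = field(
        default_factory=lambda: {k: v for k, v in TRAIT_BOUNDS.items()}
    )
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu < 1.0:
            raise ValueError(f"nu must be in [0, 1), got {self.nu}")
        sigmas = self.sigmas()
        if len(sigmas) == 0 or any(s <= 0 for s in sigmas):
            raise ValueError(f"all sigmas must be positive, got {self.sigma_schedule}")
        for name, (lo, hi) in self.trait_bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} are not well-ordered: ({lo}, {hi})")

    def sigmas(self) -> tuple[float, ...]:
        if isinstance(self.sigma_schedule, (int, float)):
            return (float(self.sigma_schedule),)
        return tuple(float(s) for s in self.sigma_schedule)

    def sigma_for_depth(self, depth: int) -> float:
        """Jump standard deviation for a new clone of the given depth (>= 2)."""
        sigmas = self.sigmas()
        return sigmas[min(max(depth - 2, 0), len(sigmas) - 1)]


@dataclass(frozen=True)
class ExtinctionModel:
    """Galton-Watson extinction filter for newly founded clones.

    ``death_probability`` is the per-division death probability d of the
    generating-function variant f(x) = (1-d)(a^2 x^2 + 2a(1-a)x + (1-a)^2) + d;
    the default pipeline neglects cell death (d = 0).

    ``trait`` selects which self-renewal fraction enters p_e: the maximal
    (feedback-free) fraction a_max of the new clone (default), or the
    realized fraction a = a_max * s(t_birth) at the moment of emergence
    ("realized").
    """

    death_probability: float = 0.0
    trait: str = "max"

    def __post_init__(self) -> None:
        if not 0.0 <= self.death_probability <= 1.0:
            raise ValueError("death probability must be in [0, 1]")
        if self.trait not in ("realized", "max"):
            raise ValueError(f"trait must be 'realized' or 'max', got {self.trait!r}")

    def self_renewal_at_birth(self, a_max: float, signal: float) -> float:
        return a_max * signal if self.trait == "realized" else a_max


def mutation_intensity(
    state: SystemState, healthy: HealthyParams, nu: float
) -> tuple[float, np.ndarray]:
    """Total and per-clone mutation intensities (events per day).

    ``per_clone[i] = 2 * a_i * s * p_i * l1_i * nu`` -- the influx of mutated
    mitotic cells from clone i.  Zero when there are no clones or nu = 0.
    """
    if not 0.0 <= nu < 1.0:
        raise ValueError(f"nu must be in [0, 1), got {nu}")
    if state.n_clones == 0:
        return 0.0, np.empty(0)
    s = feedback_signal(
        state.healthy.post_mitotic, state.leukemic_post_mitotic_total(), healthy.k
    )
    a = np.array([cp.a_max for _, cp, _ in state.clones])
    p = np.array([cp.p for _, cp, _ in state.clones])
    l1 = np.array([max(cs.mitotic, 0.0) for _, _, cs in state.clones])
    per_clone = 2.0 * a * s * p * l1 * nu
    return float(per_clone.sum()), per_clone


def next_event_hazard_threshold(rng: np.random.Generator) -> float:
    """Exp(1) threshold for the integrated-hazard event scheme.

    An event fires when the accumulated hazard Lambda(t) advances by the
    returned amount; with Lambda integrated alongside the ODE this realizes
    the inhomogeneous Poisson process exactly.
    """
    return float(rng.exponential(1.0))


def select_parent_clone(per_clone_alpha: Sequence[float], rng: np.random.Generator) -> int:
    """Categorical draw of the mutating clone, P(i) = alpha_i / sum_j alpha_j."""
    alphas = np.asarray(per_clone_alpha, dtype=float)
    if alphas.size == 0 or np.any(alphas < 0):
        raise ValueError("need at least one non-negative rate")
    total = alphas.sum()
    if total <= 0.0:
        raise ValueError("all-zero mutation rates: no clone can mutate")
    return int(rng.choice(alphas.size, p=alphas / total))


def sample_truncated_normal(
    mean: float,
    sigma: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    max_rejections: int = 64,
) -> float:
    """One draw from N(mean, sigma^2) truncated to ``bounds``.

    Rejection from the untruncated normal (acceptance is ~1 at the sigmas
    used here); falls back to inverse-CDF sampling when the analytic
    acceptance probability is below 10%, which is numerically safe even deep
    in a tail.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"bounds not well-ordered: ({lo}, {hi})")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0.0:
        return float(min(max(mean, lo), hi))
    alpha, beta = (lo - mean) / sigma, (hi - mean) / sigma
    if alpha < -6.0 and beta > 6.0:
        acceptance = 1.0  # bounds are > 6 sigma away; truncation negligible
    else:
        acceptance = 0.5 * (math.erf(beta / _SQRT2) - math.erf(alpha / _SQRT2))
    if acceptance >= 0.1:
        for _ in range(max_rejections):
            x = rng.normal(mean, sigma)
            if lo <= x <= hi:
                return float(x)
    # inverse-CDF on the standardized truncated interval
    u = rng.uniform(stats.norm.cdf(alpha), stats.norm.cdf(beta))
    x = mean + sigma * float(stats.norm.ppf(u))
    return float(min(max(x, lo), hi))


def sample_offspring_traits(
    parent: CloneParams,
    sigma: float,
    bounds: dict | None,
    rng: np.random.Generator,
) -> CloneParams:
    """Traits of a new clone: truncated normals centered on the parent.

    Self-renewal a_max and proliferation p are drawn independently with the
    same jump standard deviation; the post-mitotic death rate is inherited
    unchanged (it is not part of the mutable trait space).
    """
    if bounds is None:
        bounds = TRAIT_BOUNDS
    a_new = sample_truncated_normal(parent.a_max, sigma, bounds["a_max"], rng)
    p_new = sample_truncated_normal(parent.p, sigma, bounds["p"], rng)
    return CloneParams(a_max=a_new, p=p_new, d=parent.d)


def extinction_probability(a, death_probability: float = 0.0):
    """Extinction probability p_e(a) of a clone started from one mitotic cell.

    For the death-free process this is the smaller root of f(x) = x with
    f(x) = a^2 x^2 + 2a(1-a)x + (1-a)^2:

        p_e(a) = (2a^2 - 2a + 1)/(2a^2) - sqrt(((2a^2-2a+1)/(2a^2))^2 - ((1-a)/a)^2)

    which equals ((1-a)/a)^2 for a > 1/2 and 1 for a <= 1/2.  With a
    per-division death probability d > 0 the generating function becomes
    f(x) = (1-d) f_0(x) + d and the smaller root in [0, 1] is returned.

    Accepts a scalar or array; values are clamped to [0, 1].
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any((a_arr < 0) | (a_arr > 1)):
        raise ValueError("self-renewal fraction must be in [0, 1]")
    if not 0.0 <= death_probability <= 1.0:
        raise ValueError("death probability must be in [0, 1]")
    d = death_probability
    scalar = a_arr.ndim == 0
    a_flat = np.atleast_1d(a_arr)

    out = np.ones_like(a_flat)
    if d == 0.0:
        pos = a_flat > 0.5
        ap = a_flat[pos]
        b = (2.0 * ap**2 - 2.0 * ap + 1.0) / (2.0 * ap**2)
        disc = np.maximum(b**2 - ((1.0 - ap) / ap) ** 2, 0.0)
        out[pos] = b - np.sqrt(disc)
    else:
        # smaller root of (1-d) a^2 x^2 + ((1-d) 2a(1-a) - 1) x + (1-d)(1-a)^2 + d = 0
        for i, ai in enumerate(a_flat):
            qa = (1.0 - d) * ai**2
            qb = (1.0 - d) * 2.0 * ai * (1.0 - ai) - 1.0
            qc = (1.0 - d) * (1.0 - ai) ** 2 + d
            disc = max(qb**2 - 4.0 * qa * qc, 0.0)
            # smaller root, written to avoid cancellation (qb < 0 here)
            out[i] = 2.0 * qc / (-qb + np.sqrt(disc))
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out.reshape(a_arr.shape)


def clone_survives(
    a: float, rng: np.random.Generator, death_probability: float = 0.0
) -> bool:
    """Bernoulli(1 - p_e(a)) survival draw for a newly founded clone.

    Surviving clones are introduced to the ODE system with one mitotic and
    zero post-mitotic cells.
    """
    p_e = extinction_probability(a, death_probability)
    return bool(rng.random() < 1.0 - p_e)
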