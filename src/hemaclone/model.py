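"""Deterministic core of the clonal-evolution model.

The model tracks one healthy hematopoietic lineage (white-cell lineage) and
a time-varying collection of leukemic clones.  Each population consists of a
mitotic compartment (stem and progenitor cells, able to divide) and a
post-mitotic compartment (mature cells / blasts).  All dividing populations
respond to a single cytokine-like feedback signal

    s(t) = 1 / (1 + k * (c2 + sum_i l2_i)),

which is a decreasing function of the total post-mitotic cell mass.  The
signal down-regulates the *realized* self-renewal fraction of every mitotic
population: a population with maximal self-renewal fraction ``a_max``
self-renews with probability ``a_max * s(t)`` per division.

Units: time is measured in days; cell counts are abstract absolute counts on
the scale implied by the feedback constant k (with the default parameters the
healthy mature steady state is c2_bar = 4.0e8).  Clinical-unit conversions
are confined to the transplantation scenario in :mod:`hemaclone.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HealthyParams",
    "CloneParams",
    "CompartmentState",
    "SystemState",
    "StateDerivative",
    "feedback_signal",
    "system_rhs",
    "healthy_steady_state",
    "net_flux_balance_check",
    "TRAIT_BOUNDS",
]

#: Admissible trait intervals: self-renewal is a fraction; proliferation is
#: bounded between one division per year and one division per day.
TRAIT_BOUNDS = {
    "a_max": (0.0, 1.0),
    "p": (1.0 / 365.0, 1.0),
}


@dataclass(frozen=True)
class HealthyParams:
    """Rate constants of the healthy hematopoietic lineage.

    Parameters
    ----------
    a_max
        Maximal self-renewal fraction of mitotic cells (dimensionless,
        in (0, 1)).  Must exceed 0.5 for a positive steady state to exist.
    p
        Proliferation rate of mitotic cells, divisions per day.
    d
        Death rate of mature (post-mitotic) cells, 1/day.
    k
        Feedback constant, 1/cells.  Sets the absolute count scale.
    """

    a_max: float = 0.87
    p: float = 0.45
    d: float = 2.3
    k: float = 1.85e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.a_max < 1.0:
            raise ValueError(f"a_max must be in (0, 1), got {self.a_max}")
        if self.p <= 0:
            raise ValueError(f"proliferation rate must be positive, got {self.p}")
        if self.d <= 0:
            raise ValueError(f"death rate must be positive, got {self.d}")
        if self.k <= 0:
            raise ValueError(f"feedback constant must be positive, got {self.k}")


@dataclass(frozen=True)
class CloneParams:
    """Rate constants of one leukemic clone.

    The mutable trait space is (a_max, p); the post-mitotic death rate d is a
    fixed parameter shared by all leukemic clones (default 0.5/day).
    """

    a_max: float
    p: float
    d: float = 0.5

    def __post_init__(self) -> None:
        lo_a, hi_a = TRAIT_BOUNDS["a_max"]
        lo_p, hi_p = TRAIT_BOUNDS["p"]
        if not lo_a <= self.a_max <= hi_a:
            raise ValueError(f"a_max must be in [{lo_a}, {hi_a}], got {self.a_max}")
        if not lo_p <= self.p <= hi_p:
            raise ValueError(
                f"proliferation rate must be in [{lo_p:.6g}, {hi_p}] per day, got {self.p}"
            )
        if self.d <= 0:
            raise ValueError(f"death rate must be positive, got {self.d}")


@dataclass
class CompartmentState:
    """Cell counts of one population: mitotic and post-mitotic compartment."""

    mitotic: float
    post_mitotic: float

    def __post_init__(self) -> None:
        if self.mitotic < 0 or self.post_mitotic < 0:
            raise ValueError(
                f"cell counts must be non-negative, got "
                f"({self.mitotic}, {self.post_mitotic})"
            )


@dataclass
class SystemState:
    """Full state of the coupled healthy + n-clone system.

    ``clones`` is an ordered collection of ``(clone_id, CloneParams,
    CompartmentState)`` for the clones currently carried in the ODE system;
    its length is n(t).  ``hazard_accum`` carries the accumulated mutation
    hazard Lambda(t) = integral of the total mutation intensity, used by the
    event generator in :mod:`hemaclone.stochastic`.
    """

    time: float
    healthy: CompartmentState
    clones: list[tuple[int, CloneParams, CompartmentState]] = field(default_factory=list)
    hazard_accum: float = 0.0

    def __post_init__(self) -> None:
        if self.hazard_accum < 0:
            raise ValueError("accumulated hazard must be non-negative")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def leukemic_post_mitotic_total(self) -> float:
        return float(sum(cs.post_mitotic for _, _, cs in self.clones))

    def total_cells(self) -> float:
        tot = self.healthy.mitotic + self.healthy.post_mitotic
        for _, _, cs in self.clones:
            tot += cs.mitotic + cs.post_mitotic
        return float(tot)


@dataclass
class StateDerivative:
    """Time derivatives matching the layout of :class:`SystemState`."""

    healthy: tuple[float, float]
    clones: list[tuple[int, tuple[float, float]]]
    hazard: float


def feedback_signal(
    healthy_post_mitotic: float,
    leukemic_post_mitotic_total: float,
    k: float,
) -> float:
    """Cytokine feedback signal s = 1 / (1 + k*(c2 + sum l2_i)).

    Strictly decreasing in each cell-count argument, equal to 1 for an empty
    system, and always in (0, 1].
    """
    if healthy_post_mitotic < 0 or leukemic_post_mitotic_total < 0:
        raise ValueError("cell counts must be non-negative")
    if k <= 0:
        raise ValueError("feedback constant must be positive")
    return 1.0 / (1.0 + k * (healthy_post_mitotic + leukemic_post_mitotic_total))


def healthy_steady_state(healthy: HealthyParams) -> tuple[float, float]:
    """Closed-form steady state (c1_bar, c2_bar) of the healthy system.

    At steady state the realized self-renewal fraction equals 1/2, i.e.
    2*a_max*s = 1, giving c2_bar = (2*a_max - 1)/k, and the mature-cell
    balance gives c1_bar = d*c2_bar/p.

    Raises
    ------
    ValueError
        If ``a_max <= 0.5`` (no positive steady state exists).
    """
    if healthy.a_max <= 0.5:
        raise ValueError(
            f"no positive steady state: a_max={healthy.a_max} <= 0.5"
        )
    c2_bar = (2.0 * healthy.a_max - 1.0) / healthy.k
    c1_bar = healthy.d * c2_bar / healthy.p
    return c1_bar, c2_bar


def _rhs_arrays(
    c1: float,
    c2: float,
    l1: np.ndarray,
    l2: np.ndarray,
    a: np.ndarray,
    p: np.ndarray,
    d: np.ndarray,
    healthy: HealthyParams,
    nu: float,
) -> tuple[float, float, np.ndarray, np.ndarray, float]:
    """Vectorized right-hand side used by the simulation engine.

    Healthy cells do not mutate; the (1 - nu) factor removing mutated progeny
    in expectation applies only to leukemic mitotic self-renewal.  Returns
    (dc1, dc2, dl1, dl2, alpha_total) where alpha_total = dLambda/dt.
    """
    s = 1.0 / (1.0 + healthy.k * (c2 + l2.sum()))
    dc1 = (2.0 * healthy.a_max * s - 1.0) * healthy.p * c1
    dc2 = 2.0 * (1.0 - healthy.a_max * s) * healthy.p * c1 - healthy.d * c2
    self_renewal_flux = 2.0 * a * s * p * l1
    dl1 = self_renewal_flux * (1.0 - nu) - p * l1
    dl2 = 2.0 * (1.0 - a * s) * p * l1 - d * l2
    alpha_total = nu * float(self_renewal_flux.sum())
    return dc1, dc2, dl1, dl2, alpha_total


def system_rhs(state: SystemState, healthy: HealthyParams, nu: float) -> StateDerivative:
    """Time derivatives of all compartments plus the mutation hazard.

    Healthy lineage::

        dc1/dt = (2*a_c*s - 1) * p_c * c1
        dc2/dt = 2*(1 - a_c*s) * p_c * c1 - d_c * c2

    Leukemic clone i (the factor (1 - nu) removes, in expectation, the
    mutated fraction of self-renewing progeny, which found new clones)::

        dl1/dt = 2*a_i*s * p_i * l1 * (1 - nu) - p_i * l1
        dl2/dt = 2*(1 - a_i*s) * p_i * l1 - d_i * l2

    The shared signal s is computed from the full state.
    """
    if not 0.0 <= nu < 1.0:
        raise ValueError(f"mutation fraction nu must be in [0, 1), got {nu}")
    ids = [cid for cid, _, _ in state.clones]
    a = np.array([cp.a_max for _, cp, _ in state.clones])
    p = np.array([cp.p for _, cp, _ in state.clones])
    d = np.array([cp.d for _, cp, _ in state.clones])
    l1 = np.array([cs.mitotic for _, _, cs in state.clones])
    l2 = np.array([cs.post_mitotic for _, _, cs in state.clones])
    dc1, dc2, dl1, dl2, alpha = _rhs_arrays(
        state.healthy.mitotic, state.healthy.post_mitotic, l1, l2, a, p, d, healthy, nu
    )
    return StateDerivative(
        healthy=(dc1, dc2),
        clones=[(cid, (float(x), float(y))) for cid, x, y in zip(ids, dl1, dl2)],
        hazard=alpha,
    )


def net_flux_balance_check(
    state: SystemState,
    healthy: HealthyParams,
    nu: float,
    rtol: float = 1e-12,
) -> bool:
    """Consistency check: mutated + retained mitotic influx = total influx.

    For each clone the self-renewal outflux 2*a*s*p*l1 splits into the
    retained part (factor 1-nu) and the mutated part (factor nu, which feeds
    the event generator instead of the ODE).  Returns False on violation.
    """
    s = feedback_signal(
        state.healthy.post_mitotic, state.leukemic_post_mitotic_total(), healthy.k
    )
    for _, cp, cs in state.clones:
        total = 2.0 * cp.a_max * s * cp.p * cs.mitotic
        retained = total * (1.0 - nu)
        mutated = total * nu
        if abs((retained + mutated) - total) > rtol * max(abs(total), 1.0):
            return False
    return True
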