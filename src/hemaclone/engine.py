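"""Per-patient hybrid simulation: deterministic ODE dynamics punctuated by
stochastic mutation events.

The disease course of one virtual patient starts from the healthy steady
state plus a founder clone of one mitotic cell at t = 0.  Between events the
coupled healthy + n-clone system (plus the accumulated mutation hazard) is
integrated with an adaptive, stiffness-switching method (LSODA) and dense
output.  Mutation times are recovered exactly from the dense hazard
trajectory: an event fires whenever Lambda(t) crosses its current Exp(1)
threshold.  At an event, a parent clone is selected proportionally to its
mutation intensity, offspring traits are drawn from truncated normals
centered on the parent, and the new clone passes a Galton-Watson survival
filter; only survivors enter the ODE system (one mitotic, zero post-mitotic
cells).  Events whose clone goes extinct at birth leave the deterministic
state untouched, so the integrator only restarts when the system actually
grows -- this keeps the event handling exact while avoiding a solver restart
for the (vast majority of) extinct-at-birth mutations.

A patient's course ends when the healthy mature-cell count falls below a
stop fraction (default 5%) of its steady-state value -- interpreted as death
from the disease -- or when the simulated age exceeds the horizon (default
100 years).  Snapshots of the full system are recorded the first time the
mature healthy count falls by each configured depletion level (default 5,
50, 95%) and at termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import RK45, solve_ivp
from scipy.optimize import brentq

from .hierarchy import CloneNode, HierarchyTree, significant_clones
from .model import (
    CloneParams,
    CompartmentState,
    HealthyParams,
    SystemState,
    healthy_steady_state,
)
from .stochastic import (
    ExtinctionModel,
    MutationConfig,
    extinction_probability,
    sample_truncated_normal,
)

__all__ = [
    "PatientConfig",
    "PatientResult",
    "MutationEvent",
    "Snapshot",
    "init_founder",
    "simulate_patient",
    "apply_stopping_and_snapshots",
    "prune_extinct_clones",
    "transplant_recovery",
    "NonRecoveryError",
]

#: Clinical-unit convention for the transplantation scenario only: model
#: counts are read as cells per kg body weight (the default steady state
#: c2_bar = 4.0e8 then matches the order of the blood neutrophil pool per
#: kg).  Transplant dose 4e6 CD34+ cells/kg with a 3:1 myeloid:erythroid
#: ratio; recovery when neutrophils reach 5e8 per liter of blood (5 L, 70 kg).
BODY_MASS_KG = 70.0
BLOOD_VOLUME_L = 5.0
TRANSPLANT_DOSE_PER_KG = 4.0e6
MYELOID_FRACTION = 0.75
RECOVERY_NEUTROPHILS_PER_L = 5.0e8


def _snapshot_label(fraction: float) -> str:
    return f"depletion_{int(round(fraction * 100)):02d}"


@dataclass(frozen=True)
class PatientConfig:
    """Everything needed to simulate one patient (except the seed)."""

    healthy: HealthyParams = field(default_factory=HealthyParams)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    extinction: ExtinctionModel = field(default_factory=ExtinctionModel)
    clone_death_rate: float = 0.5
    founder_sigma: float = 0.005
    founder_policy: str = "deterministic"  # "deterministic" | "filter" | "resample"
    founder_params: CloneParams | None = None  # fixed founder traits (no draw)
    stop_fraction: float = 0.05
    max_age: float = 36500.0
    snapshot_fractions: tuple[float, ...] = (0.05, 0.50, 0.95)
    significance_threshold: float = 0.01
    significance_mode: str = "any"  # "any" | "terminal"
    prune_epsilon: float = 0.1
    retire_fraction: float = 1e-5
    rtol: float = 1e-8
    atol: float = 1e-4
    record_trajectory: bool = True
    trajectory_dt: float = 1.0
    keep_event_log: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.stop_fraction < 1.0:
            raise ValueError("stop_fraction must be in (0, 1)")
        fr = self.snapshot_fractions
        if any(not 0.0 < f < 1.0 for f in fr) or any(
            b <= a for a, b in zip(fr, fr[1:])
        ):
            raise ValueError("snapshot fractions must be strictly increasing in (0, 1)")
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValueError("significance_threshold must be in (0, 1)")
        if not 0.0 < self.prune_epsilon <= 1.0:
            raise ValueError("prune_epsilon must be in (0, 1]")
        if not 0.0 <= self.retire_fraction < 1.0:
            raise ValueError("retire_fraction must be in [0, 1)")
        if self.founder_policy not in ("deterministic", "filter", "resample"):
            raise ValueError(f"unknown founder_policy {self.founder_policy!r}")
        if self.founder_sigma < 0:
            raise ValueError("founder_sigma must be non-negative")
        if self.clone_death_rate <= 0:
            raise ValueError("clone death rate must be positive")
        if self.max_age <= 0:
            raise ValueError("max_age must be positive")


@dataclass
class MutationEvent:
    """One firing of the mutation process (established or not)."""

    time: float
    parent_id: int
    child_id: int | None
    a_max: float
    p: float
    depth: int
    a_at_birth: float
    p_extinct: float
    survived: bool


@dataclass
class Snapshot:
    """Full system state at a depletion level or at termination."""

    label: str
    time: float
    state: SystemState
    mass_fractions: dict[int, float]
    significant: set[int]


@dataclass
class PatientResult:
    """One simulated disease course."""

    status: str  # died_of_disease | survived_horizon | founder_never_established
    death_time: float | None
    seed: int | None
    hierarchy: HierarchyTree
    snapshots: list[Snapshot]
    event_log: list[MutationEvent]
    n_mutation_events: int
    n_established: int
    founder_attempts: int
    trajectory: pd.DataFrame | None
    config: PatientConfig


class NonRecoveryError(RuntimeError):
    """Transplant scenario: the recovery threshold was never reached."""


class SolverFailure(RuntimeError):
    """ODE integration failed; carries the time and state at failure."""

    def __init__(self, message: str, time: float, state: np.ndarray):
        super().__init__(f"{message} at t={time:.3f}")
        self.time = time
        self.state = state


def init_founder(
    healthy: HealthyParams,
    founder_sigma: float,
    bounds: dict | None,
    rng: np.random.Generator,
    clone_death_rate: float = 0.5,
) -> CloneParams:
    """Draw founder-clone traits from truncated normals centered on the
    healthy-cell parameters (a_max, p)."""
    from .model import TRAIT_BOUNDS

    if bounds is None:
        bounds = TRAIT_BOUNDS
    a = sample_truncated_normal(healthy.a_max, founder_sigma, bounds["a_max"], rng)
    p = sample_truncated_normal(healthy.p, founder_sigma, bounds["p"], rng)
    return CloneParams(a_max=a, p=p, d=clone_death_rate)


def apply_stopping_and_snapshots(
    c2_of_t: Callable[[float], float],
    t_grid: np.ndarray,
    config: PatientConfig,
    c2_baseline: float,
    pending_fractions: list[float] | None = None,
) -> tuple[list[tuple[float, float]], float | None]:
    """Detect first crossings of the depletion levels along one segment.

    ``c2_of_t`` is a dense (interpolated) mature-healthy-cell trajectory and
    ``t_grid`` an increasing sample grid covering the segment (typically the
    solver's own step points).  Returns ``(records, stop_time)`` where
    records are ``(fraction, crossing_time)`` for each newly crossed level,
    in crossing order, and ``stop_time`` is the first time c2 falls below
    ``stop_fraction * c2_baseline`` (None if it does not).  For a
    non-monotone trajectory only the *first* downward crossing of each level
    is reported.
    """
    fractions = list(
        pending_fractions if pending_fractions is not None else config.snapshot_fractions
    )
    records: list[tuple[float, float]] = []
    for frac in fractions:
        target = (1.0 - frac) * c2_baseline
        t_cross = _first_downward_crossing(c2_of_t, t_grid, target)
        if t_cross is not None:
            records.append((frac, t_cross))
    records.sort(key=lambda r: r[1])
    stop_target = config.stop_fraction * c2_baseline
    stop_time = _first_downward_crossing(c2_of_t, t_grid, stop_target)
    return records, stop_time


def _first_downward_crossing(
    f: Callable[[float], float], t_grid: np.ndarray, target: float
) -> float | None:
    """First t in the grid span with f crossing from above to <= target."""
    vals = np.array([f(t) for t in t_grid]) - target
    if vals[0] <= 0.0:
        return float(t_grid[0])
    below = np.nonzero(vals <= 0.0)[0]
    if below.size == 0:
        return None
    j = below[0]
    lo, hi = float(t_grid[j - 1]), float(t_grid[j])
    if vals[j] == 0.0 or hi == lo:
        return hi
    return float(brentq(lambda t: f(t) - target, lo, hi, xtol=1e-9, rtol=1e-12))


def prune_extinct_clones(
    state: SystemState, prune_epsilon: float, healthy: HealthyParams
) -> SystemState:
    """Remove decayed clones from the live ODE system.

    A clone is pruned when both compartments are below ``prune_epsilon``
    cells *and* its net mitotic growth is negative at the current signal
    (2 a s < 1).  Since prune_epsilon <= 1, a clone with at least one
    mitotic cell is never pruned.  Pruned clones remain in the hierarchy
    record, flagged dead.
    """
    from .model import feedback_signal

    s = feedback_signal(
        state.healthy.post_mitotic, state.leukemic_post_mitotic_total(), healthy.k
    )
    kept = [
        (cid, cp, cs)
        for cid, cp, cs in state.clones
        if not (
            cs.mitotic < prune_epsilon
            and cs.post_mitotic < prune_epsilon
            and 2.0 * cp.a_max * s < 1.0
        )
    ]
    return SystemState(
        time=state.time,
        healthy=state.healthy,
        clones=kept,
        hazard_accum=state.hazard_accum,
    )


# ---------------------------------------------------------------------------
# the hybrid loop
# ---------------------------------------------------------------------------


class _LiveSystem:
    """Mutable arrays of the live ODE system (internal)."""

    def __init__(self, healthy: HealthyParams, nu: float, c1: float, c2: float):
        self.healthy = healthy
        self.nu = nu
        self.c1 = c1
        self.c2 = c2
        self.ids: list[int] = []
        self.a = np.empty(0)
        self.p = np.empty(0)
        self.d = np.empty(0)
        self.l1 = np.empty(0)
        self.l2 = np.empty(0)
        self.hazard = 0.0

    @property
    def n(self) -> int:
        return len(self.ids)

    def pack(self) -> np.ndarray:
        return np.concatenate(([self.c1, self.c2], self.l1, self.l2, [self.hazard]))

    def unpack(self, y: np.ndarray) -> None:
        n = self.n
        self.c1, self.c2 = float(y[0]), float(y[1])
        self.l1 = np.maximum(y[2 : 2 + n], 0.0).copy()
        self.l2 = np.maximum(y[2 + n : 2 + 2 * n], 0.0).copy()
        self.hazard = float(y[-1])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        hp = self.healthy
        c1, c2 = y[0], y[1]
        l1 = y[2 : 2 + n]
        l2 = y[2 + n : 2 + 2 * n]
        s = 1.0 / (1.0 + hp.k * (c2 + l2.sum()))
        out = np.empty_like(y)
        out[0] = (2.0 * hp.a_max * s - 1.0) * hp.p * c1
        out[1] = 2.0 * (1.0 - hp.a_max * s) * hp.p * c1 - hp.d * c2
        flux = 2.0 * self.a * s * self.p * l1
        out[2 : 2 + n] = flux * (1.0 - self.nu) - self.p * l1
        out[2 + n : 2 + 2 * n] = 2.0 * (1.0 - self.a * s) * self.p * l1 - self.d * l2
        out[-1] = self.nu * flux.sum()
        return out

    def signal(self) -> float:
        return 1.0 / (1.0 + self.healthy.k * (self.c2 + self.l2.sum()))

    def per_clone_alpha_from_y(self, y: np.ndarray) -> np.ndarray:
        n = self.n
        c2 = y[1]
        l1 = np.maximum(y[2 : 2 + n], 0.0)
        l2 = np.maximum(y[2 + n : 2 + 2 * n], 0.0)
        s = 1.0 / (1.0 + self.healthy.k * (c2 + l2.sum()))
        return 2.0 * self.a * s * self.p * l1 * self.nu

    def alpha_total(self) -> float:
        s = self.signal()
        return float(self.nu * np.sum(2.0 * self.a * s * self.p * self.l1))

    def add_clone(self, cid: int, params: CloneParams) -> None:
        self.ids.append(cid)
        self.a = np.append(self.a, params.a_max)
        self.p = np.append(self.p, params.p)
        self.d = np.append(self.d, params.d)
        self.l1 = np.append(self.l1, 1.0)
        self.l2 = np.append(self.l2, 0.0)

    def drop(self, positions: list[int]) -> list[int]:
        """Remove clones by position; returns the dropped clone ids."""
        keep = [i for i in range(self.n) if i not in positions]
        dropped = [self.ids[i] for i in positions]
        self.ids = [self.ids[i] for i in keep]
        for name in ("a", "p", "d", "l1", "l2"):
            setattr(self, name, getattr(self, name)[keep])
        return dropped

    def params_at(self, pos: int) -> CloneParams:
        return CloneParams(a_max=float(self.a[pos]), p=float(self.p[pos]), d=float(self.d[pos]))

    def to_system_state(self, t: float, y: np.ndarray | None = None) -> SystemState:
        if y is None:
            c1, c2, l1, l2, haz = self.c1, self.c2, self.l1, self.l2, self.hazard
        else:
            n = self.n
            c1, c2 = float(y[0]), float(y[1])
            l1 = np.maximum(y[2 : 2 + n], 0.0)
            l2 = np.maximum(y[2 + n : 2 + 2 * n], 0.0)
            haz = float(y[-1])
        clones = [
            (cid, self.params_at(i), CompartmentState(float(l1[i]), float(l2[i])))
            for i, cid in enumerate(self.ids)
        ]
        return SystemState(
            time=t,
            healthy=CompartmentState(max(c1, 0.0), max(c2, 0.0)),
            clones=clones,
            hazard_accum=max(haz, 0.0),
        )


#: Above this total mutation intensity (events/day), or above this number of
#: live clones, the engine switches from LSODA segments with dense-output
#: event scanning to a step-driven explicit RK45 loop: a single-step method
#: pays nothing to grow the state vector when clones are inserted, whereas
#: restarting a multistep stiff solver at every insertion dominates the cost
#: in event-dense phases.  The stiffness here is mild (fastest time scale
#: 1/d_c ~ 0.4 days), so the explicit method's stability-limited step of
#: about a day is acceptable.
_ALPHA_SWITCH = 0.02
_N_SWITCH = 40
_RETIRE_CHECK_STEPS = 256


def _segment_horizon(alpha: float, remaining: float) -> float:
    """Adaptive LSODA segment length: aim for ~2 mutation events per scan.

    Long segments amortize solver start-up over quiet stretches; short
    segments bound the integration discarded when a surviving clone
    truncates the segment.
    """
    if alpha <= 1e-7:
        return min(remaining, 3650.0)
    return float(np.clip(2.0 / alpha, 10.0, 3650.0))


def simulate_patient(config: PatientConfig, seed) -> PatientResult:
    """Simulate one patient; bit-reproducible given (config, seed)."""
    rng = np.random.default_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None
    hp = config.healthy
    nu = config.mutation.nu
    bounds = config.mutation.trait_bounds
    c1_bar, c2_bar = healthy_steady_state(hp)

    tree = HierarchyTree()
    event_log: list[MutationEvent] = []
    n_events = 0
    n_established = 0

    # -- founder ----------------------------------------------------------
    s_bar = 1.0 / (1.0 + hp.k * c2_bar)
    founder_attempts = 0
    while True:
        founder_attempts += 1
        if config.founder_params is not None:
            founder = config.founder_params
            established = True
            break
        founder = init_founder(hp, config.founder_sigma, bounds, rng, config.clone_death_rate)
        if config.founder_policy == "deterministic":
            established = True
        else:
            a_birth = config.extinction.self_renewal_at_birth(founder.a_max, s_bar)
            p_e = extinction_probability(a_birth, config.extinction.death_probability)
            established = bool(rng.random() < 1.0 - p_e)
        if established or config.founder_policy != "resample":
            break

    tree.add(
        CloneNode(
            id=1, parent=None, birth_time=0.0, depth=1, params=founder,
            established=established,
        )
    )
    if not established:
        return PatientResult(
            status="founder_never_established",
            death_time=None,
            seed=seed_repr,
            hierarchy=tree,
            snapshots=[],
            event_log=[],
            n_mutation_events=0,
            n_established=0,
            founder_attempts=founder_attempts,
            trajectory=None,
            config=config,
        )

    sys_ = _LiveSystem(hp, nu, c1_bar, c2_bar)
    sys_.add_clone(1, founder)
    next_id = 2
    depth_of = {1: 1}

    hazard_target = rng.exponential() if nu > 0 else np.inf

    pending_fractions = list(config.snapshot_fractions)
    snapshots: list[Snapshot] = []
    stop_target = config.stop_fraction * c2_bar

    traj_rows: list[tuple[float, np.ndarray, list[int]]] = []

    def record_trajectory(sol, t_lo: float, t_hi: float) -> None:
        if not config.record_trajectory:
            return
        grid = np.arange(np.ceil(t_lo), t_hi, config.trajectory_dt)
        grid = np.concatenate((grid, [t_hi])) if grid.size == 0 or grid[-1] < t_hi else grid
        vals = sol.sol(grid)
        for t, col in zip(grid, vals.T):
            traj_rows.append((float(t), col.copy(), list(sys_.ids)))

    def take_snapshot(label: str, t: float, y: np.ndarray) -> None:
        state = sys_.to_system_state(t, y)
        total = state.total_cells()
        fractions = {
            cid: (cs.mitotic + cs.post_mitotic) / total if total > 0 else 0.0
            for cid, _, cs in state.clones
        }
        sig = significant_clones(state, config.significance_threshold) if total > 0 else set()
        for cid, frac in fractions.items():
            tree.nodes[cid].mass_fractions[label] = float(frac)
            tree.nodes[cid].significant[label] = cid in sig
        snapshots.append(Snapshot(label=label, time=float(t), state=state,
                                  mass_fractions=fractions, significant=sig))

    def death_event(t, y):
        return y[1] - stop_target

    death_event.terminal = True
    death_event.direction = -1

    t = 0.0
    status = "survived_horizon"
    death_time: float | None = None

    def make_atol(n_y: int) -> np.ndarray:
        atol = np.full(n_y, config.atol)
        atol[-1] = 1e-12  # the hazard state is of order one
        return atol

    def process_event(t_e: float, y_e: np.ndarray):
        """One mutation firing: parent choice, trait draw, survival filter.

        Returns ``(child, depth, parent_id)`` when the clone must be
        inserted into the ODE system, else None (extinct at birth, or
        subcritical at birth and only bookkept -- see the class note on
        truncation).  Always advances the hazard threshold.
        """
        nonlocal n_events, n_established, next_id, hazard_target
        alphas = sys_.per_clone_alpha_from_y(y_e)
        total_alpha = float(alphas.sum())
        if total_alpha <= 0.0:
            return "stalled"  # defensive: hazard cannot grow with zero rate
        pos = int(rng.choice(alphas.size, p=alphas / total_alpha))
        parent_id = sys_.ids[pos]
        depth_new = depth_of[parent_id] + 1
        sigma = config.mutation.sigma_for_depth(depth_new)
        parent_params = sys_.params_at(pos)
        a_new = sample_truncated_normal(parent_params.a_max, sigma, bounds["a_max"], rng)
        p_new = sample_truncated_normal(parent_params.p, sigma, bounds["p"], rng)
        child = CloneParams(a_max=a_new, p=p_new, d=parent_params.d)
        n_ = sys_.n
        l2_e = np.maximum(y_e[2 + n_ : 2 + 2 * n_], 0.0)
        s_e = 1.0 / (1.0 + hp.k * (max(y_e[1], 0.0) + l2_e.sum()))
        a_birth = config.extinction.self_renewal_at_birth(child.a_max, s_e)
        p_e = extinction_probability(a_birth, config.extinction.death_probability)
        survived = bool(rng.random() < 1.0 - p_e)
        n_events += 1
        child_id = next_id if survived else None
        if config.keep_event_log or survived:
            event_log.append(
                MutationEvent(
                    time=float(t_e), parent_id=parent_id, child_id=child_id,
                    a_max=child.a_max, p=child.p, depth=depth_new,
                    a_at_birth=float(a_birth), p_extinct=float(p_e),
                    survived=survived,
                )
            )
        hazard_target += rng.exponential()
        if not survived:
            return None
        # A clone that is subcritical at birth (2*a*s <= 1) can never grow,
        # because the feedback signal only falls as the disease progresses:
        # it decays from its single founding cell.  With retire_fraction > 0
        # such clones are recorded in the hierarchy but not added to the ODE
        # system; their feedback and mutation contributions (of order one
        # cell against ~1e9) are far below solver tolerance.
        supercritical = 2.0 * child.a_max * s_e * (1.0 - nu) > 1.0
        if config.retire_fraction > 0.0 and not supercritical:
            tree.add(
                CloneNode(
                    id=next_id, parent=parent_id, birth_time=float(t_e),
                    depth=depth_new, params=child, established=True, alive=False,
                )
            )
            n_established += 1
            next_id += 1
            return None
        return child, depth_new, parent_id

    def insert_clone(t_e: float, child: CloneParams, depth_new: int, parent_id: int) -> None:
        nonlocal n_established, next_id
        sys_.add_clone(next_id, child)
        tree.add(
            CloneNode(
                id=next_id, parent=parent_id, birth_time=float(t_e),
                depth=depth_new, params=child, established=True,
            )
        )
        depth_of[next_id] = depth_new
        n_established += 1
        next_id += 1

    def prune_and_retire() -> None:
        s_now = sys_.signal()
        total_now = sys_.c1 + sys_.c2 + sys_.l1.sum() + sys_.l2.sum()
        declining = 2.0 * sys_.a * s_now * (1.0 - nu) < 1.0
        prune_pos = [
            i
            for i in range(sys_.n)
            if declining[i]
            and (
                (sys_.l1[i] < config.prune_epsilon and sys_.l2[i] < config.prune_epsilon)
                or (
                    config.retire_fraction > 0.0
                    and sys_.l1[i] + sys_.l2[i] < config.retire_fraction * total_now
                )
            )
        ]
        if prune_pos:
            for cid in sys_.drop(prune_pos):
                tree.nodes[cid].alive = False

    stepper_h: float | None = None

    def fast_segment(t0: float, t_bound: float):
        """Step-driven RK45 integration for event-dense phases.

        Returns ``(t_new, outcome, payload)`` with outcome one of "insert"
        (a surviving supercritical clone must be added at t_new), "dead"
        (death threshold crossed; state recorded) or "end" (segment bound
        or retirement checkpoint reached).  Snapshot crossings and
        non-inserting mutation events are handled in-stream without
        interrupting the stepper.
        """
        nonlocal stepper_h, status, death_time
        y0 = sys_.pack()
        hz = y0.size - 1
        first = None
        if stepper_h is not None and 0.0 < stepper_h < (t_bound - t0):
            first = stepper_h
        stepper = RK45(
            sys_.rhs, t0, y0, t_bound,
            rtol=config.rtol, atol=make_atol(y0.size), first_step=first,
        )
        next_traj = np.ceil(t0)
        steps = 0
        while True:
            stepper.step()
            if stepper.status == "failed":
                raise SolverFailure("RK45 step failed", stepper.t, stepper.y)
            t_hi = float(stepper.t)
            y1 = stepper.y
            if stepper.h_abs is not None and stepper.h_abs > 0:
                stepper_h = float(stepper.h_abs)
            dense = None
            cursor = float(stepper.t_old)
            while True:
                haz_crossed = y1[hz] >= hazard_target
                death_crossed = y1[1] <= stop_target
                snaps = [f for f in pending_fractions if y1[1] <= (1.0 - f) * c2_bar]
                if not (haz_crossed or death_crossed or snaps):
                    break
                if dense is None:
                    dense = stepper.dense_output()
                found: list[tuple[float, str, float | None]] = []
                if haz_crossed:
                    te = _dense_crossing(dense, hz, hazard_target, cursor, t_hi, rising=True)
                    found.append((te, "hazard", None))
                for f in snaps:
                    te = _dense_crossing(dense, 1, (1.0 - f) * c2_bar, cursor, t_hi, rising=False)
                    found.append((te, "snapshot", f))
                if death_crossed:
                    te = _dense_crossing(dense, 1, stop_target, cursor, t_hi, rising=False)
                    found.append((te, "death", None))
                found.sort(key=lambda e: e[0])
                te, kind, payload = found[0]
                if kind == "snapshot":
                    take_snapshot(_snapshot_label(payload), te, dense(te))
                    pending_fractions.remove(payload)
                    cursor = te
                    continue
                if kind == "death":
                    status = "died_of_disease"
                    death_time = float(te)
                    yd = dense(te)
                    sys_.unpack(yd)
                    take_snapshot("terminal", death_time, yd)
                    return death_time, "dead", None
                y_e = dense(te)
                ins = process_event(te, y_e)
                cursor = te
                if ins == "stalled":
                    break
                if ins is not None:
                    sys_.unpack(y_e)
                    return float(te), "insert", ins
            if config.record_trajectory and t_hi >= next_traj:
                if dense is None:
                    dense = stepper.dense_output()
                grid = np.arange(next_traj, t_hi + 1e-9, config.trajectory_dt)
                if grid.size:
                    vals = dense(grid)
                    for tg, col in zip(grid, vals.T):
                        traj_rows.append((float(tg), col.copy(), list(sys_.ids)))
                    next_traj = grid[-1] + config.trajectory_dt
            steps += 1
            if stepper.status == "finished" or steps % _RETIRE_CHECK_STEPS == 0:
                sys_.unpack(stepper.y)
                return t_hi, "end", None

    while t < config.max_age:
        alpha_now = sys_.alpha_total()
        if alpha_now > _ALPHA_SWITCH or sys_.n > _N_SWITCH:
            t_new, outcome, payload = fast_segment(t, min(t + 365.0, config.max_age))
            t = t_new
            if outcome == "dead":
                break
            if outcome == "insert":
                insert_clone(t, *payload)
            prune_and_retire()
            continue

        remaining = config.max_age - t
        L = _segment_horizon(alpha_now, remaining)
        t_end = min(t + L, config.max_age)
        y0 = sys_.pack()
        sol = solve_ivp(
            sys_.rhs,
            (t, t_end),
            y0,
            method="LSODA",
            dense_output=True,
            events=death_event,
            rtol=config.rtol,
            atol=make_atol(y0.size),
        )
        if sol.status < 0:
            raise SolverFailure(f"ODE solver failed: {sol.message}", t, y0)
        died_in_segment = sol.status == 1 and len(sol.t_events[0]) > 0
        seg_end = float(sol.t_events[0][0]) if died_in_segment else float(sol.t[-1])

        # -- scan mutation events on the dense hazard trajectory ----------
        hazard_idx = y0.size - 1
        restart: tuple[float, tuple[CloneParams, int, int]] | None = None
        lam_end = float(sol.sol(seg_end)[hazard_idx])
        scan_lo = t
        while lam_end >= hazard_target:
            t_e = _invert_hazard(sol, hazard_idx, hazard_target, scan_lo, seg_end)
            y_e = sol.sol(t_e)
            ins = process_event(t_e, y_e)
            scan_lo = t_e
            if ins == "stalled":
                break
            if ins is not None:
                sys_.unpack(y_e)
                restart = (float(t_e), ins)
                break

        accepted_end = restart[0] if restart is not None else seg_end

        # -- snapshots and death within the accepted part -----------------
        grid = sol.t[(sol.t >= t) & (sol.t < accepted_end)]
        grid = np.concatenate((grid, [accepted_end]))
        c2_dense = lambda tt: float(sol.sol(tt)[1])
        records, stop_time = apply_stopping_and_snapshots(
            c2_dense, grid, config, c2_bar, pending_fractions
        )
        for frac, t_cross in records:
            take_snapshot(_snapshot_label(frac), t_cross, sol.sol(t_cross))
            pending_fractions.remove(frac)
        record_trajectory(sol, t, accepted_end)

        if restart is None and died_in_segment:
            status = "died_of_disease"
            death_time = seg_end if stop_time is None else stop_time
            sys_.unpack(sol.sol(death_time))
            take_snapshot("terminal", death_time, sol.sol(death_time))
            break

        if restart is not None:
            t_e, ins = restart
            insert_clone(t_e, *ins)
            t = t_e
        else:
            sys_.unpack(sol.sol(seg_end))
            t = seg_end

        prune_and_retire()

    if status == "survived_horizon":
        take_snapshot("terminal", t, sys_.pack())

    trajectory = _assemble_trajectory(traj_rows) if config.record_trajectory else None
    return PatientResult(
        status=status,
        death_time=death_time,
        seed=seed_repr,
        hierarchy=tree,
        snapshots=snapshots,
        event_log=event_log,
        n_mutation_events=n_events,
        n_established=n_established + 1,  # including the founder
        founder_attempts=founder_attempts,
        trajectory=trajectory,
        config=config,
    )


def _dense_crossing(
    dense, idx: int, target: float, t_lo: float, t_hi: float, rising: bool
) -> float:
    """Crossing time of component ``idx`` through ``target`` within one step.

    ``dense`` is a local interpolant (from a stepper's dense_output); the
    caller guarantees the crossing lies in [t_lo, t_hi].
    """
    f = lambda tt: float(dense(tt)[idx]) - target
    flo = f(t_lo)
    if (rising and flo >= 0.0) or (not rising and flo <= 0.0):
        return float(t_lo)
    fhi = f(t_hi)
    if (rising and fhi <= 0.0) or (not rising and fhi >= 0.0):
        return float(t_hi)
    return float(brentq(f, t_lo, t_hi, xtol=1e-9))


def _invert_hazard(sol, hazard_idx: int, target: float, t_lo: float, t_hi: float) -> float:
    """Time at which the (monotone) accumulated hazard reaches ``target``."""
    f = lambda tt: float(sol.sol(tt)[hazard_idx]) - target
    flo, fhi = f(t_lo), f(t_hi)
    if flo >= 0.0:
        return t_lo
    if fhi <= 0.0:
        return t_hi
    return float(brentq(f, t_lo, t_hi, xtol=1e-7))


def _assemble_trajectory(rows) -> pd.DataFrame:
    """Long-to-wide assembly of the sampled time series."""
    all_ids: list[int] = []
    for _, _, ids in rows:
        for cid in ids:
            if cid not in all_ids:
                all_ids.append(cid)
    seen_t = set()
    unique_rows = []
    for row in rows:
        if row[0] not in seen_t:
            seen_t.add(row[0])
            unique_rows.append(row)
    rows = unique_rows
    cols = ["t", "c1", "c2"] + [f"l1_{c}" for c in all_ids] + [f"l2_{c}" for c in all_ids]
    data = np.full((len(rows), len(cols)), np.nan)
    for r, (t, y, ids) in enumerate(rows):
        n = len(ids)
        data[r, 0] = t
        data[r, 1] = y[0]
        data[r, 2] = y[1]
        for i, cid in enumerate(ids):
            j = all_ids.index(cid)
            data[r, 3 + j] = y[2 + i]
            data[r, 3 + len(all_ids) + j] = y[2 + n + i]
    return pd.DataFrame(data, columns=cols)


def transplant_recovery(
    healthy: HealthyParams | None = None,
    initial_mitotic: float | None = None,
    recovery_threshold: float | None = None,
    initial_post_mitotic: float = 0.0,
    horizon: float = 365.0,
    rtol: float = 1e-8,
    atol: float = 1e-4,
) -> float:
    """Days until post-transplant neutrophil recovery (healthy system only).

    Starts from ``c1 = initial_mitotic`` (default: the 4e6 cells/kg dose
    times the 3:1 myeloid fraction), ``c2 = 0``, and integrates the healthy
    system until the mature-cell count first reaches the recovery threshold
    (default: 5e8 neutrophils/L scaled to per-kg counts).  With the default
    parametrization this takes two to three weeks.

    Raises :class:`NonRecoveryError` if the threshold is not reached within
    the horizon.
    """
    hp = healthy if healthy is not None else HealthyParams()
    dose = (
        initial_mitotic
        if initial_mitotic is not None
        else TRANSPLANT_DOSE_PER_KG * MYELOID_FRACTION
    )
    threshold = (
        recovery_threshold
        if recovery_threshold is not None
        else RECOVERY_NEUTROPHILS_PER_L * BLOOD_VOLUME_L / BODY_MASS_KG
    )
    if dose <= 0:
        raise ValueError("initial mitotic count must be positive")

    def rhs(t, y):
        c1, c2 = y
        s = 1.0 / (1.0 + hp.k * c2)
        return [
            (2.0 * hp.a_max * s - 1.0) * hp.p * c1,
            2.0 * (1.0 - hp.a_max * s) * hp.p * c1 - hp.d * c2,
        ]

    y0 = [dose, float(initial_post_mitotic)]
    if y0[1] >= threshold:
        return 0.0

    def recovered(t, y):
        return y[1] - threshold

    recovered.terminal = True
    recovered.direction = 1
    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA", events=recovered,
                    rtol=rtol, atol=atol)
    if sol.status != 1 or len(sol.t_events[0]) == 0:
        raise NonRecoveryError(
            f"mature cells did not reach {threshold:.3g} within {horizon} days"
        )
    return float(sol.t_events[0][0])
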