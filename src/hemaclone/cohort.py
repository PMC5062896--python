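"""Cohort drivers: many-patient simulations and the in-silico experiments
(mutation-rate sweeps, trait-jump sweeps, cooperativity schedules).

All randomness flows from a single master seed: per-patient streams are
spawned deterministically with :class:`numpy.random.SeedSequence`, so a
cohort is reproducible patient-by-patient and independent of execution
order.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import PatientConfig, PatientResult, simulate_patient
from .hierarchy import CohortResult, cohort_summary

__all__ = [
    "patient_seeds",
    "simulate_cohort",
    "sweep",
    "cooperativity_experiment",
    "mutation_rate_experiment",
    "trait_spread_experiment",
    "COOPERATIVE_SCHEDULE",
]

#: Trait-jump schedule of the cooperativity experiment: the founder draw
#: uses sigma_1 = 0.0014 and the jumps of the first, second, and third or
#: higher mutations use 5x, 20x and 100x sigma_1.
COOPERATIVE_SCHEDULE = (0.007, 0.028, 0.14)
COOPERATIVE_FOUNDER_SIGMA = 0.0014


def patient_seeds(master_seed: int, n_patients: int) -> list[int]:
    """Deterministic independent per-patient seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1, dtype=np.uint32)[0]) for child in ss.spawn(n_patients)]


def simulate_cohort(
    config: PatientConfig,
    n_patients: int,
    master_seed: int,
    progress: bool = False,
    on_patient: Callable[[int, PatientResult], None] | None = None,
) -> CohortResult:
    """Simulate ``n_patients`` independent disease courses.

    ``on_patient(index, result)`` is called after each patient (used by the
    file writers); a patient whose simulation fails is recorded with status
    ``"failed"`` and the cohort continues.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    seeds = patient_seeds(master_seed, n_patients)
    patients: list[PatientResult] = []
    for i, seed in enumerate(seeds):
        try:
            res = simulate_patient(config, seed)
        except Exception as exc:  # pragma: no cover - defensive
            res = _failed_result(config, seed, exc)
        patients.append(res)
        if on_patient is not None:
            on_patient(i, res)
        if progress:
            print(f"patient {i + 1}/{n_patients}: {res.status}", flush=True)
    return CohortResult(patients=patients, config=config, master_seed=master_seed)


def _failed_result(config: PatientConfig, seed: int, exc: Exception) -> PatientResult:
    from .hierarchy import HierarchyTree

    res = PatientResult(
        status="failed",
        death_time=None,
        seed=seed,
        hierarchy=HierarchyTree(),
        snapshots=[],
        event_log=[],
        n_mutation_events=0,
        n_established=0,
        founder_attempts=0,
        trajectory=None,
        config=config,
    )
    res.error = repr(exc)
    return res


def _cohort_row(label, value, cohort: CohortResult, mode: str = "any") -> dict:
    df = cohort_summary(cohort, mode=mode)
    ok = df[df.status != "failed"]
    return {
        "parameter": label,
        "value": value,
        "n_patients": len(ok),
        "mean_total_clones": float(ok.n_clones.mean()),
        "mean_significant_clones": float(ok.n_significant.mean()),
        "mean_depth": float(ok.depth.mean()),
        "max_significant_clones": int(ok.n_significant.max()),
        "fraction_died": float((ok.status == "died_of_disease").mean()),
        "fraction_below_10_significant": float((ok.n_significant < 10).mean()),
    }


def sweep(
    config: PatientConfig,
    parameter: str,
    values: Sequence[float],
    n_patients: int,
    master_seed: int,
    mode: str = "any",
    progress: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """One cohort per grid value of ``parameter`` ("nu" or "sigma").

    Sweeping "sigma" varies the trait-jump kernel of *mutations*; the
    founder draw keeps ``config.founder_sigma`` (a separate knob), so the
    cohort's founder composition stays fixed across grid values and the
    comparison isolates the mutation-kernel effect.  All grid points share
    the same per-patient seed scheme, so paired comparisons across grid
    values are common-random-number comparisons.  Returns (summary table,
    dict of CohortResult by grid value).
    """
    if parameter not in ("nu", "sigma"):
        raise ValueError("parameter must be 'nu' or 'sigma'")
    if len(values) == 0:
        raise ValueError("sweep grid must be non-empty")
    if any(v <= 0 for v in values):
        raise ValueError("sweep grid values must be positive")
    rows = []
    cohorts: dict[float, CohortResult] = {}
    for v in values:
        if parameter == "nu":
            mut = replace(config.mutation, nu=float(v))
            cfg = replace(config, mutation=mut)
        else:
            mut = replace(config.mutation, sigma_schedule=float(v))
            cfg = replace(config, mutation=mut)
        cohort = simulate_cohort(cfg, n_patients, master_seed, progress=progress)
        cohorts[float(v)] = cohort
        rows.append(_cohort_row(parameter, float(v), cohort, mode=mode))
    return pd.DataFrame(rows), cohorts


def _diseased(df: pd.DataFrame) -> pd.DataFrame:
    """Patients that developed at least one significant clone.

    Per-patient hierarchy statistics (clone counts, depth) are averaged over
    these patients: a virtual patient whose founder never grows out has no
    clonal hierarchy to measure.
    """
    return df[(df.status != "failed") & (df.n_significant > 0)]


def mutation_rate_experiment(
    config: PatientConfig,
    n_patients: int | Sequence[int],
    master_seed: int,
    nus: Sequence[float] = (5e-10, 5e-9, 5e-8),
    mode: str = "any",
    progress: bool = False,
) -> dict:
    """Cohorts across the studied mutation-rate range and the headline
    statistics of the resulting clonal hierarchies.

    Statistics returned (all restricted to diseased patients where they
    concern hierarchies; see :func:`_diseased`):

    - ``second_higher_fraction``: share of patients (>= 2 significant
      clones, reference cohort nu = nus[1]) whose second-emerging
      significant clone has higher self-renewal than the first.
    - ``max_significant`` / ``fraction_below_10``: extreme and typical
      significant-clone counts pooled over all cohorts and patients.
    - ``delta_mean_significant``: mean significant clones at nus[1] minus
      at nus[0] (a ten-fold mutation-rate step).
    - ``depth_increment_per_decade``: average increase of mean hierarchy
      depth (maximal depth over *all* established clones, matching the
      depth definition of the model) per ten-fold increase of nu.
    - ``total_clone_ratio``: ratio of mean total established clones between
      nus[1] and nus[0].

    ``n_patients`` may be one size for all cohorts or a sequence aligned
    with ``nus`` (the high-rate cohorts are far more expensive per patient,
    so desk-scale runs use larger cohorts at the cheap low rates).
    """
    from .hierarchy import fraction_second_exceeds_first

    if isinstance(n_patients, (int, np.integer)):
        sizes = [int(n_patients)] * len(nus)
    else:
        sizes = [int(n) for n in n_patients]
        if len(sizes) != len(nus):
            raise ValueError("n_patients sequence must align with nus")

    summaries: dict[float, pd.DataFrame] = {}
    cohorts: dict[float, CohortResult] = {}
    for nu, size in zip(nus, sizes):
        cfg = replace(config, mutation=replace(config.mutation, nu=float(nu)))
        cohort = simulate_cohort(cfg, size, master_seed, progress=progress)
        cohorts[float(nu)] = cohort
        summaries[float(nu)] = cohort_summary(cohort, mode=mode)

    ref_nu = float(nus[1]) if len(nus) > 1 else float(nus[0])
    frac2, n_eligible = fraction_second_exceeds_first(cohorts[ref_nu], mode=mode)

    pooled = pd.concat(summaries.values(), ignore_index=True)
    pooled = pooled[pooled.status != "failed"]
    mean_sig = {nu: float(_diseased(df).n_significant.mean()) for nu, df in summaries.items()}
    mean_depth_all = {nu: float(_diseased(df).depth_all.mean()) for nu, df in summaries.items()}
    mean_total = {nu: float(_diseased(df).n_clones.mean()) for nu, df in summaries.items()}
    nus_sorted = sorted(summaries)
    increments = [
        (mean_depth_all[b] - mean_depth_all[a]) / np.log10(b / a)
        for a, b in zip(nus_sorted, nus_sorted[1:])
    ]
    return {
        "cohorts": cohorts,
        "summaries": summaries,
        "second_higher_fraction": frac2,
        "n_eligible_second_vs_first": n_eligible,
        "max_significant": int(pooled.n_significant.max()),
        "fraction_below_10": float((pooled.n_significant < 10).mean()),
        "n_pooled": int(len(pooled)),
        "mean_significant": mean_sig,
        "mean_depth_all_clones": mean_depth_all,
        "mean_total_clones": mean_total,
        "delta_mean_significant": mean_sig[float(nus[1])] - mean_sig[float(nus[0])]
        if len(nus) > 1 else np.nan,
        "depth_increment_per_decade": float(np.mean(increments)) if increments else np.nan,
        "total_clone_ratio": mean_total[float(nus[1])] / mean_total[float(nus[0])]
        if len(nus) > 1 else np.nan,
    }


def trait_spread_experiment(
    config: PatientConfig,
    n_patients: int,
    master_seed: int,
    sigmas: Sequence[float] = (0.01, 0.05),
    mode: str = "any",
    progress: bool = False,
) -> dict:
    """Effect of the trait-jump standard deviation on clone counts.

    Widening the jump distribution produces more aggressive outlier clones,
    faster disease progression and hence fewer significant clones; the
    returned ``delta_mean_significant`` is the mean significant-clone count
    (diseased patients) at sigmas[0] minus that at sigmas[1].  Both cohorts
    share the per-patient seed scheme (common random numbers) and the
    founder draw keeps its baseline spread, so the comparison isolates the
    mutation kernel.
    """
    table, cohorts = sweep(config, "sigma", sigmas, n_patients, master_seed, mode=mode,
                           progress=progress)
    mean_sig = {}
    for sig, cohort in cohorts.items():
        df = cohort_summary(cohort, mode=mode)
        mean_sig[sig] = float(_diseased(df).n_significant.mean())
    return {
        "cohorts": cohorts,
        "table": table,
        "mean_significant": mean_sig,
        "delta_mean_significant": mean_sig[float(sigmas[0])] - mean_sig[float(sigmas[1])],
    }


def cooperativity_experiment(
    config: PatientConfig,
    n_patients: int,
    master_seed: int,
    schedule: Sequence[float] = COOPERATIVE_SCHEDULE,
    founder_sigma: float = COOPERATIVE_FOUNDER_SIGMA,
    min_depth: int = 4,
    mode: str = "any",
    progress: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Compare the increasing trait-jump schedule against constant-sigma
    controls.

    Runs one cohort with the increasing schedule (cooperative mutations) and
    one control cohort per constant sigma taken from the schedule; reports
    for each the number of patients whose clonal hierarchy reaches
    ``min_depth`` or more.  The founder draw keeps ``founder_sigma``
    (sigma_1) in every variant; only the mutation-jump schedule differs.
    Cooperativity predicts the increasing schedule maximizes the
    deep-hierarchy count.
    """
    variants: dict[str, tuple[float, ...]] = {
        "increasing": tuple(float(s) for s in schedule),
        "constant_sigma1": (float(founder_sigma),),
    }
    for i, s in enumerate(schedule, start=2):
        variants[f"constant_sigma{i}"] = (float(s),)

    rows = []
    cohorts: dict[str, CohortResult] = {}
    for name, sched in variants.items():
        mut = replace(config.mutation, sigma_schedule=sched)
        cfg = replace(config, mutation=mut, founder_sigma=founder_sigma)
        cohort = simulate_cohort(cfg, n_patients, master_seed, progress=progress)
        cohorts[name] = cohort
        df = cohort_summary(cohort, mode=mode)
        ok = df[df.status != "failed"]
        rows.append(
            {
                "variant": name,
                "founder_sigma": founder_sigma,
                "sigma_schedule": sched,
                "n_patients": len(ok),
                "n_deep_hierarchies": int((ok.depth >= min_depth).sum()),
                "mean_depth": float(ok.depth.mean()),
                "mean_significant_clones": float(ok.n_significant.mean()),
            }
        )
    return pd.DataFrame(rows), cohorts
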