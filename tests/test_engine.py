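"""Hybrid per-patient simulation: founder, disease course, stopping,
pruning, transplant calibration."""

import dataclasses
import numpy as np
import pytest

from hemaclone import (
    CloneParams,
    CompartmentState,
    HealthyParams,
    MutationConfig,
    NonRecoveryError,
    PatientConfig,
    SystemState,
    apply_stopping_and_snapshots,
    healthy_steady_state,
    init_founder,
    prune_extinct_clones,
    simulate_patient,
    transplant_recovery,
)


def _cfg(**kw):
    base = dict(record_trajectory=False, keep_event_log=True)
    base.update(kw)
    return PatientConfig(**base)


def _no_mutation(**kw):
    return _cfg(mutation=MutationConfig(nu=0.0), **kw)


class TestInitFounder:
    def test_zero_sigma_copies_healthy_traits(self, healthy, rng):
        f = init_founder(healthy, 0.0, None, rng)
        assert f.a_max == healthy.a_max
        assert f.p == healthy.p

    def test_tight_founder_distribution(self, healthy, rng):
        """With the cooperativity founder spread (0.0014) essentially all
        draws are within 0.01 of the healthy self-renewal (7-sigma bound)."""
        draws = [init_founder(healthy, 0.0014, None, rng) for _ in range(2000)]
        assert all(abs(f.a_max - 0.87) < 0.01 for f in draws)

    def test_draws_respect_trait_bounds(self, healthy, rng):
        draws = [init_founder(healthy, 0.3, None, rng) for _ in range(500)]
        assert all(0.0 <= f.a_max <= 1.0 for f in draws)
        assert all(1.0 / 365.0 <= f.p <= 1.0 for f in draws)


class TestDiseaseCourse:
    def test_weak_founder_never_establishes_disease(self):
        """A founder with a_max below the healthy value decays; the patient
        survives the horizon with only the founder in the hierarchy."""
        cfg = _no_mutation(founder_params=CloneParams(a_max=0.85, p=0.45))
        res = simulate_patient(cfg, seed=7)
        assert res.status == "survived_horizon"
        assert len(res.hierarchy) == 1
        assert res.hierarchy.significant_ids("any") == set()
        # healthy compartments remain at steady state throughout
        term = res.snapshots[-1]
        _, c2_bar = healthy_steady_state(cfg.healthy)
        assert term.state.healthy.post_mitotic == pytest.approx(c2_bar, rel=1e-3)

    def test_aggressive_founder_causes_death(self):
        cfg = _no_mutation(founder_params=CloneParams(a_max=0.95, p=0.45))
        res = simulate_patient(cfg, seed=7)
        assert res.status == "died_of_disease"
        assert res.death_time is not None and 0 < res.death_time < 3650
        assert max(n.depth for n in res.hierarchy.nodes.values()) == 1
        labels = [s.label for s in res.snapshots]
        assert labels == ["depletion_05", "depletion_50", "depletion_95", "terminal"]
        times = [s.time for s in res.snapshots]
        assert times == sorted(times)
        # the 95% depletion snapshot coincides with the death criterion
        assert times[-1] == pytest.approx(res.death_time)

    def test_death_time_stable_under_tolerance_halving(self):
        cfg = _no_mutation(founder_params=CloneParams(a_max=0.95, p=0.45))
        t1 = simulate_patient(cfg, seed=1).death_time
        t2 = simulate_patient(dataclasses.replace(cfg, rtol=cfg.rtol / 2, atol=cfg.atol / 2),
                              seed=1).death_time
        assert t2 == pytest.approx(t1, rel=1e-4)  # 4 significant digits

    def test_reproducibility_bitwise(self, fast_config):
        cfg = dataclasses.replace(fast_config, keep_event_log=True,
                                  mutation=MutationConfig(nu=5e-8))
        r1 = simulate_patient(cfg, seed=3)
        r2 = simulate_patient(cfg, seed=3)
        assert r1.status == r2.status
        assert r1.death_time == r2.death_time
        assert r1.n_mutation_events == r2.n_mutation_events
        assert [(e.time, e.parent_id, e.a_max) for e in r1.event_log] == [
            (e.time, e.parent_id, e.a_max) for e in r2.event_log
        ]
        assert r1.hierarchy.to_dict() == r2.hierarchy.to_dict()

    def test_surviving_spawned_clones_exceed_critical_self_renewal(self):
        """Survivors of the extinction filter must have a_max > 0.5 at
        birth: p_e = 1 for a <= 1/2."""
        cfg = _cfg(mutation=MutationConfig(nu=5e-8, sigma_schedule=0.05),
                   founder_params=CloneParams(a_max=0.872, p=0.45))
        res = simulate_patient(cfg, seed=11)
        spawned = [e for e in res.event_log if e.survived]
        assert spawned, "expected at least one established clone"
        assert all(e.a_max > 0.5 for e in spawned)

    def test_event_genealogy_is_consistent(self):
        cfg = _cfg(mutation=MutationConfig(nu=5e-8),
                   founder_params=CloneParams(a_max=0.875, p=0.45))
        res = simulate_patient(cfg, seed=5)
        tree = res.hierarchy
        assert tree.root.parent is None and tree.root.depth == 1
        for node in tree.nodes.values():
            if node.parent is not None:
                parent = tree.nodes[node.parent]
                assert node.depth == parent.depth + 1
                assert node.birth_time >= parent.birth_time

    def test_founder_policies(self, fast_config):
        from hemaclone import ExtinctionModel
        cfg = dataclasses.replace(
            fast_config, founder_policy="filter", founder_sigma=0.005,
            extinction=ExtinctionModel(trait="realized"),
            mutation=MutationConfig(nu=0.0),
        )
        # with the realized-trait filter most founders are rejected
        statuses = {simulate_patient(cfg, seed=s).status for s in range(8)}
        assert "founder_never_established" in statuses
        cfg2 = dataclasses.replace(cfg, founder_policy="resample")
        res = simulate_patient(cfg2, seed=0)
        assert res.status != "founder_never_established"
        assert res.founder_attempts >= 1


class TestStoppingAndSnapshots:
    def test_monotone_decline_crosses_all_levels(self):
        cfg = PatientConfig()
        c2 = lambda t: 4.0e8 * np.exp(-t / 100.0)
        grid = np.linspace(0, 1000, 2001)
        records, stop = apply_stopping_and_snapshots(c2, grid, cfg, 4.0e8)
        assert [f for f, _ in records] == [0.05, 0.50, 0.95]
        times = [t for _, t in records]
        assert times == sorted(times)
        assert stop == pytest.approx(100.0 * np.log(20), rel=1e-6)

    def test_no_decline_no_snapshots(self):
        cfg = PatientConfig()
        c2 = lambda t: 4.0e8 + 0 * t
        records, stop = apply_stopping_and_snapshots(c2, np.linspace(0, 100, 11), cfg, 4.0e8)
        assert records == [] and stop is None

    def test_non_monotone_crossing_reported_once_at_first_passage(self):
        """c2 dips below the 5% level, recovers, and dips again; only the
        first downward crossing is recorded (dense-output oracle on a
        constructed trajectory)."""
        cfg = PatientConfig(snapshot_fractions=(0.05,))
        baseline = 4.0e8
        # dips below 0.95*baseline near t=30 and again after t=70
        c2 = lambda t: baseline * (1 - 0.07 * np.exp(-((t - 30) / 8.0) ** 2)
                                   - 0.07 * np.exp(-((t - 80) / 8.0) ** 2))
        grid = np.linspace(0, 120, 481)
        records, stop = apply_stopping_and_snapshots(c2, grid, cfg, baseline)
        assert len(records) == 1
        frac, t_cross = records[0]
        assert frac == 0.05
        assert 20 < t_cross < 30  # on the first dip's falling flank
        assert stop is None


class TestPruning:
    def test_decayed_subcritical_clone_is_pruned(self, healthy):
        c1_bar, c2_bar = healthy_steady_state(healthy)
        state = SystemState(
            time=0.0, healthy=CompartmentState(c1_bar, c2_bar),
            clones=[(1, CloneParams(a_max=0.8, p=0.3), CompartmentState(1e-6, 1e-6))],
        )
        out = prune_extinct_clones(state, 0.1, healthy)
        assert out.n_clones == 0

    def test_clone_with_whole_cells_never_pruned(self, healthy):
        c1_bar, c2_bar = healthy_steady_state(healthy)
        state = SystemState(
            time=0.0, healthy=CompartmentState(c1_bar, c2_bar),
            clones=[(1, CloneParams(a_max=0.8, p=0.3), CompartmentState(2.0, 0.0))],
        )
        assert prune_extinct_clones(state, 1.0, healthy).n_clones == 1

    def test_growing_clone_never_pruned(self, healthy):
        c1_bar, c2_bar = healthy_steady_state(healthy)
        state = SystemState(
            time=0.0, healthy=CompartmentState(c1_bar, c2_bar),
            clones=[(1, CloneParams(a_max=0.95, p=0.3), CompartmentState(1e-6, 1e-6))],
        )
        assert prune_extinct_clones(state, 0.1, healthy).n_clones == 1

    def test_truncation_matches_exact_mode(self):
        """retire_fraction=0 integrates every established clone (exact
        mode); at moderate event counts the default truncation of doomed
        negligible clones leaves the disease course and the significant
        hierarchy unchanged."""
        kw = dict(mutation=MutationConfig(nu=2e-8),
                  founder_params=CloneParams(a_max=0.885, p=0.45),
                  record_trajectory=False, keep_event_log=False)
        exact = simulate_patient(PatientConfig(retire_fraction=0.0, **kw), seed=3)
        truncated = simulate_patient(PatientConfig(**kw), seed=3)
        assert exact.status == truncated.status == "died_of_disease"
        assert truncated.death_time == pytest.approx(exact.death_time, rel=1e-3)
        assert truncated.hierarchy.significant_ids("any") == \
            exact.hierarchy.significant_ids("any")
        assert truncated.n_mutation_events == exact.n_mutation_events

    def test_results_insensitive_to_epsilon(self):
        """Clone counts and depth are unchanged when the pruning floor
        varies ten-fold around the default."""
        outcomes = []
        for eps in (0.03, 0.1, 0.3):
            cfg = _cfg(prune_epsilon=eps, mutation=MutationConfig(nu=5e-9),
                       founder_params=CloneParams(a_max=0.874, p=0.45))
            res = simulate_patient(cfg, seed=2)
            sig = res.hierarchy.significant_ids("any")
            outcomes.append((res.status, len(sig), res.n_mutation_events))
        assert outcomes[0] == outcomes[1] == outcomes[2]


class TestTransplantRecovery:
    def test_already_recovered_dose(self):
        assert transplant_recovery(initial_post_mitotic=1e8) == 0.0

    def test_recovery_time_monotone_in_dose(self):
        t_small = transplant_recovery(initial_mitotic=1e6)
        t_large = transplant_recovery(initial_mitotic=1e7)
        assert t_large < t_small

    def test_default_dose_recovers_in_two_to_three_weeks(self):
        days = transplant_recovery()
        assert 14.0 <= days <= 21.0

    def test_non_recovery_signalled(self):
        with pytest.raises(NonRecoveryError):
            transplant_recovery(initial_mitotic=1.0, horizon=5.0)
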