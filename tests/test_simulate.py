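"""Synthetic-cohort generator: path simulation, wave observation, cohorts."""

import numpy as np
import pandas as pd
import pytest

from morbistate import (
    IntensityModel,
    SimulationConfig,
    StateSpace,
    Trajectory,
    default_state_config,
    observe_at_waves,
    simulate_cohort,
    simulate_individual_path,
    transition_probability,
)


def two_state_model(rate=0.1):
    sp = StateSpace(living=("S1",), death="S2", allowed=frozenset({("S1", "S2")}))
    return IntensityModel.from_rates(sp, {("S1", "S2"): rate})


def three_state_chain(a, b):
    sp = StateSpace(
        living=("S1", "S2", "S3"),
        death="S4",
        allowed=frozenset({("S1", "S2"), ("S2", "S3")}),
    )
    # no death transitions: a pure progression chain
    return IntensityModel.from_rates(sp, {("S1", "S2"): a, ("S2", "S3"): b})


class TestIndividualPath:
    def test_zero_rates_yield_no_jumps(self, rng):
        sp = StateSpace(living=("S1", "S2"), death="S3")
        im = IntensityModel(
            state_space=sp,
            transitions=sp.transitions,
            log_baseline=np.full(len(sp.transitions), -50.0),  # effectively zero
            beta=np.zeros((len(sp.transitions), 0)),
        )
        traj = simulate_individual_path(im, {}, 80.0, rng)
        assert traj.jump_times == ()
        assert traj.death_time is None

    def test_exponential_death_time_mean(self, rng):
        im = two_state_model(rate=0.1)
        times = []
        for _ in range(10_000):
            t = simulate_individual_path(im, {}, 500.0, rng).death_time
            assert t is not None
            times.append(t)
        times = np.asarray(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 10.0) < 3 * se

    def test_two_stage_occupancy_matches_closed_form(self, rng):
        # S1 -a-> S2 -b-> S3: occupancy probabilities have the classic
        # two-stage closed forms; compare empirical frequencies at t
        a, b, t = 0.5, 0.2, 2.0
        im = three_state_chain(a, b)
        n = 20_000
        counts = {"S1": 0, "S2": 0, "S3": 0}
        for _ in range(n):
            traj = simulate_individual_path(im, {}, t + 1e-9, rng)
            counts[traj.state_at(t)] += 1
        p1 = np.exp(-a * t)
        p2 = a * (np.exp(-b * t) - np.exp(-a * t)) / (a - b)
        p3 = 1.0 - p1 - p2
        for state, p in zip(("S1", "S2", "S3"), (p1, p2, p3)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[state] / n - p) < 4 * se, state

    def test_progressive_property(self, rng):
        cfg = default_state_config(n_participants=1, seed=0)
        sp = cfg.true_intensities.state_space
        order = {s: i for i, s in enumerate(sp.states)}
        for _ in range(200):
            traj = simulate_individual_path(
                cfg.true_intensities, {"two_way": 1}, 7.0, rng
            )
            path = [traj.baseline_state, *traj.states_after_jump]
            ranks = [order[s] for s in path]
            assert ranks == sorted(ranks)

    def test_rejects_bad_inputs(self, rng):
        im = two_state_model()
        with pytest.raises(ValueError, match="horizon"):
            simulate_individual_path(im, {}, 0.0, rng)
        with pytest.raises(KeyError, match="unknown covariate"):
            simulate_individual_path(im, {"nope": 1.0}, 5.0, rng)


class TestObserveAtWaves:
    def make_traj(self, jumps=(), states=(), death=None):
        return Trajectory(
            participant_id=1,
            baseline_state="S1",
            jump_times=jumps,
            states_after_jump=states,
            death_time=death,
        )

    def test_no_jumps_all_waves_baseline(self):
        recs = observe_at_waves(self.make_traj(), [0, 2, 4, 7])
        assert len(recs) == 4
        assert all(r.state == "S1" and r.vital_status == "alive" for r in recs)

    def test_death_between_waves_yields_one_exact_record(self):
        recs = observe_at_waves(self.make_traj(death=3.0), [0, 2, 4, 7])
        assert [r.years_since_baseline for r in recs] == [0.0, 2.0, 3.0]
        assert [r.vital_status for r in recs] == ["alive", "alive", "dead"]

    def test_jump_is_interval_censored(self):
        recs = observe_at_waves(
            self.make_traj(jumps=(2.5,), states=("S2",)), [0, 2, 4, 7]
        )
        assert [r.state for r in recs] == ["S1", "S1", "S2", "S2"]
        assert all(r.years_since_baseline in (0, 2, 4, 7) for r in recs)

    def test_observed_states_nondecreasing(self, rng):
        cfg = default_state_config(n_participants=1, seed=0)
        sp = cfg.true_intensities.state_space
        order = {s: i for i, s in enumerate(sp.states)}
        for _ in range(200):
            traj = simulate_individual_path(
                cfg.true_intensities, {"two_way": 0}, 7.0, rng
            )
            recs = observe_at_waves(traj, (0, 2, 4, 7), sp.death)
            ranks = [order[r.state] for r in recs]
            assert ranks == sorted(ranks)


class TestSimulateCohort:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_participants=60, seed=11, mode="disease")
        p1, _ = simulate_cohort(cfg)
        p2, _ = simulate_cohort(SimulationConfig(n_participants=60, seed=11, mode="disease"))
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.to_csv(f1, index=False)
        p2.to_csv(f2, index=False)
        assert f1.read_bytes() == f2.read_bytes()

    def test_per_participant_draws_stable_under_cohort_size(self):
        small, _ = simulate_cohort(SimulationConfig(n_participants=20, seed=5))
        large, _ = simulate_cohort(SimulationConfig(n_participants=40, seed=5))
        pd.testing.assert_frame_equal(
            small, large[large["id"] < 20].reset_index(drop=True)
        )

    def test_group_fraction_near_configured_probability(self):
        cfg = SimulationConfig(n_participants=6800, seed=2, mode="disease")
        panel, _ = simulate_cohort(cfg)
        base = panel[panel.wave_index == 0]
        frac = base["two_way"].mean()
        assert abs(frac - 0.60) < 0.02

    def test_zero_hazard_disease_never_reported(self):
        cfg = SimulationConfig(n_participants=300, seed=3, mode="disease")
        cfg.disease_table["asthma"]["hazard"] = 0.0
        cfg.disease_table["asthma"]["prevalence"] = 0.0
        panel, _ = simulate_cohort(cfg)
        assert panel["disease_asthma"].sum() == 0

    def test_disease_indicators_cumulative(self):
        cfg = SimulationConfig(n_participants=150, seed=4, mode="disease")
        panel, _ = simulate_cohort(cfg)
        dcols = [c for c in panel.columns if c.startswith("disease_")]
        for _, grp in panel.groupby("id"):
            counts = grp[dcols].sum(axis=1).to_numpy()
            assert (np.diff(counts) >= 0).all()

    def test_wave_structure_and_exact_deaths(self):
        cfg = SimulationConfig(n_participants=400, seed=6, mode="disease")
        panel, _ = simulate_cohort(cfg)
        alive = panel[panel.vital_status == "alive"]
        assert set(alive.years_since_baseline.unique()) <= {0.0, 2.0, 4.0, 7.0}
        dead = panel[panel.vital_status == "dead"]
        assert len(dead) > 0
        # exact death dates do not sit on the wave grid (a.s.)
        assert (~dead.years_since_baseline.isin([0.0, 2.0, 4.0])).all()
        # nothing recorded after death
        for pid in dead.id:
            grp = panel[panel.id == pid]
            assert grp.vital_status.iloc[-1] == "dead"
            assert (grp.vital_status.iloc[:-1] == "alive").all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="group_probability"):
            SimulationConfig(n_participants=10, group_probability=1.5)
        with pytest.raises(ValueError, match="wave offsets"):
            SimulationConfig(n_participants=10, wave_offsets_years=(0, 3, 3))
        with pytest.raises(ValueError, match="true_intensities"):
            SimulationConfig(n_participants=10, mode="state")

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = default_state_config(n_participants=25, seed=9)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        p1, _ = simulate_cohort(cfg)
        p2, _ = simulate_cohort(back)
        pd.testing.assert_frame_equal(p1, p2)


class TestCrossModuleTransitionFrequencies:
    def test_empirical_wave_transitions_match_expm_probabilities(self, rng):
        """State-mode cohorts reproduce the expm transition matrix over one
        wave interval (generator vs matrix-exponential cross-check)."""
        cfg = default_state_config(n_participants=4000, seed=13, group_hr=1.0)
        panel, _ = simulate_cohort(cfg)
        im = cfg.true_intensities
        sp = im.state_space
        P = transition_probability(im.intensity_matrix({"two_way": 0}), 2.0)
        # pairs observed between waves 0 and 1 (dt = 2), starting from S1
        first = panel[panel.wave_index == 0].set_index("id")
        second = panel[(panel.wave_index == 1)].set_index("id")
        both = first.join(second, lsuffix="_0", rsuffix="_1", how="inner")
        start = both[both.state_0 == "S1"]
        # death records between waves 0 and 1 carry wave_index 1
        n = len(start)
        for s in sp.states:
            observed = (start.state_1 == s).mean()
            expected = P[sp.index("S1"), sp.index(s)]
            se = np.sqrt(max(expected * (1 - expected), 1e-6) / n)
            assert abs(observed - expected) < 4 * se, s
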