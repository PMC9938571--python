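"""Progressive multistate Markov model: generators, expm, panel likelihood, fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from morbistate import (
    IntensityModel,
    MultistateModel,
    StateSpace,
    build_intensity_matrix,
    default_state_config,
    fit_multistate,
    panel_log_likelihood,
    simulate_cohort,
    transition_probability,
)


def make_panel(rows):
    return pd.DataFrame(
        rows, columns=["id", "years_since_baseline", "state", "vital_status"]
    )


class TestStateSpace:
    def test_default_full_forward_set(self):
        sp = StateSpace()
        assert sp.n_states == 6
        assert len(sp.allowed) == 10 + 5  # C(5,2) forward moves + 5 deaths
        assert ("S2", "S1") not in sp.allowed
        assert ("S6", "S1") not in sp.allowed

    def test_reversal_rejected(self):
        with pytest.raises(ValueError, match="progressive"):
            StateSpace(
                living=("S1", "S2"), death="S3", allowed=frozenset({("S2", "S1")})
            )


class TestIntensityMatrix:
    def test_null_effects_reduce_to_baseline(self, illness_death_space):
        im = IntensityModel.from_rates(
            illness_death_space,
            {("S1", "S2"): 0.3, ("S1", "S3"): 0.05, ("S2", "S3"): 0.1},
            covariate_names=("x",),
        )
        Q0 = im.intensity_matrix({"x": 0.0})
        Q5 = im.intensity_matrix({"x": 5.0})
        np.testing.assert_allclose(Q0, Q5)

    def test_log_linear_unit_effect_doubles_one_entry(self, illness_death_space):
        im = IntensityModel.from_rates(
            illness_death_space,
            {("S1", "S2"): 0.3, ("S1", "S3"): 0.05, ("S2", "S3"): 0.1},
            beta={("S1", "S2"): {"x": np.log(2.0)}},
            covariate_names=("x",),
        )
        Q0 = build_intensity_matrix(im, {"x": 0.0})
        Q1 = build_intensity_matrix(im, {"x": 1.0})
        assert Q1[0, 1] == pytest.approx(2 * Q0[0, 1])
        assert Q1[0, 2] == pytest.approx(Q0[0, 2])
        assert Q1[1, 2] == pytest.approx(Q0[1, 2])

    def test_rows_sum_to_zero_for_random_parameters(self, rng):
        sp = StateSpace()
        for _ in range(20):
            nt = len(sp.transitions)
            im = IntensityModel(
                state_space=sp,
                transitions=sp.transitions,
                log_baseline=rng.normal(-2, 1, nt),
                beta=rng.normal(0, 0.5, (nt, 2)),
                covariate_names=("a", "b"),
            )
            Q = im.intensity_matrix({"a": rng.normal(), "b": rng.normal()})
            np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_missing_covariate_raises(self, illness_death_space):
        im = IntensityModel.from_rates(
            illness_death_space, {("S1", "S2"): 0.3}, covariate_names=("x",)
        )
        with pytest.raises(KeyError, match="missing covariate"):
            im.intensity_matrix({})


class TestTransitionProbability:
    def test_identity_at_zero(self, illness_death_space):
        im = IntensityModel.from_rates(
            illness_death_space,
            {("S1", "S2"): 0.3, ("S1", "S3"): 0.05, ("S2", "S3"): 0.1},
        )
        np.testing.assert_allclose(
            transition_probability(im.intensity_matrix(), 0.0), np.eye(3), atol=1e-14
        )

    def test_two_state_closed_form(self):
        lam = 0.3
        Q = np.array([[-lam, lam], [0.0, 0.0]])
        for t in (0.5, 1.0, 5.0):
            P = transition_probability(Q, t)
            assert P[0, 1] == pytest.approx(1 - np.exp(-lam * t), abs=1e-12)

    def test_three_state_chain_matches_ode_integration(self):
        a, b = 0.4, 0.15
        Q = np.array([[-a, a, 0.0], [0.0, -b, b], [0.0, 0.0, 0.0]])
        t = 3.0
        P = transition_probability(Q, t)
        closed = 1 - (a * np.exp(-b * t) - b * np.exp(-a * t)) / (a - b)
        assert P[0, 2] == pytest.approx(closed, abs=1e-10)
        # independent oracle: integrate the Kolmogorov forward equations
        sol = solve_ivp(
            lambda _, p: (p.reshape(3, 3) @ Q).ravel(),
            (0.0, t),
            np.eye(3).ravel(),
            rtol=1e-11,
            atol=1e-12,
        )
        np.testing.assert_allclose(P, sol.y[:, -1].reshape(3, 3), atol=1e-8)

    def test_rows_stochastic_and_structural_zeros(self, rng):
        sp = StateSpace()
        nt = len(sp.transitions)
        im = IntensityModel(
            state_space=sp,
            transitions=sp.transitions,
            log_baseline=rng.normal(-2, 1, nt),
            beta=np.zeros((nt, 0)),
        )
        P = transition_probability(im.intensity_matrix(), 2.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0) and np.all(P <= 1 + 1e-12)
        for i in range(6):
            for j in range(i):
                assert abs(P[i, j]) <= 1e-12  # no probability of state decrease

    def test_chapman_kolmogorov(self, rng):
        sp = StateSpace()
        nt = len(sp.transitions)
        im = IntensityModel(
            state_space=sp,
            transitions=sp.transitions,
            log_baseline=rng.normal(-2, 0.8, nt),
            beta=np.zeros((nt, 0)),
        )
        Q = im.intensity_matrix()
        for t1, t2 in ((0.5, 1.5), (2.0, 3.0), (1.0, 6.0)):
            P = transition_probability(Q, t1) @ transition_probability(Q, t2)
            np.testing.assert_allclose(
                P, transition_probability(Q, t1 + t2), atol=1e-9
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            transition_probability(np.zeros((2, 2)), -1.0)


class TestPanelLogLikelihood:
    def illness_death_model(self):
        sp = StateSpace(
            living=("S1", "S2"),
            death="S3",
            allowed=frozenset({("S1", "S2"), ("S1", "S3"), ("S2", "S3")}),
        )
        return IntensityModel.from_rates(
            sp, {("S1", "S2"): 0.25, ("S1", "S3"): 0.04, ("S2", "S3"): 0.12}
        )

    def test_single_transition_two_state_model(self):
        sp = StateSpace(living=("S1",), death="S2", allowed=frozenset({("S1", "S2")}))
        im = IntensityModel.from_rates(sp, {("S1", "S2"): 0.2})
        panel = make_panel(
            [[1, 0.0, "S1", "alive"], [1, 3.0, "S2", "dead"]]
        )
        # interval-censored death: likelihood is exactly P_12(3)
        ll = panel_log_likelihood(im, panel, exact_death_times=False)
        assert ll == pytest.approx(np.log(1 - np.exp(-0.2 * 3.0)), abs=1e-12)

    def test_skipped_wave_equals_latent_state_enumeration(self):
        im = self.illness_death_model()
        sp = im.state_space
        panel = make_panel(
            [[1, 0.0, "S1", "alive"], [1, 4.0, "S2", "alive"]]
        )
        ll = panel_log_likelihood(im, panel)
        # oracle: sum over every admissible latent state at the unobserved
        # middle wave (t = 2) of the product of transition probabilities
        Q = im.intensity_matrix()
        P2 = transition_probability(Q, 2.0)
        i, j = sp.index("S1"), sp.index("S2")
        brute = sum(P2[i, m] * P2[m, j] for m in range(sp.n_states))
        assert ll == pytest.approx(np.log(brute), abs=1e-10)

    def test_exact_death_density(self):
        im = self.illness_death_model()
        sp = im.state_space
        T = 2.7
        panel = make_panel(
            [[1, 0.0, "S1", "alive"], [1, T, "S3", "dead"]]
        )
        ll = panel_log_likelihood(im, panel)
        Q = im.intensity_matrix()
        P = transition_probability(Q, T)
        brute = sum(
            P[sp.index("S1"), sp.index(s)] * Q[sp.index(s), sp.index("S3")]
            for s in sp.living
        )
        assert ll == pytest.approx(np.log(brute), abs=1e-10)

    def test_zero_elapsed_identical_states_contribute_nothing(self):
        im = self.illness_death_model()
        panel = make_panel(
            [[1, 0.0, "S1", "alive"], [1, 0.0, "S1", "alive"]]
        )
        assert panel_log_likelihood(im, panel) == pytest.approx(0.0, abs=1e-14)

    def test_decreasing_state_sequence_rejected_with_participant(self):
        im = self.illness_death_model()
        panel = make_panel(
            [[7, 0.0, "S2", "alive"], [7, 2.0, "S1", "alive"]]
        )
        with pytest.raises(ValueError, match="participant 7"):
            panel_log_likelihood(im, panel)

    def test_likelihood_invariant_to_participant_order(self):
        im = self.illness_death_model()
        rows = [
            [1, 0.0, "S1", "alive"], [1, 2.0, "S2", "alive"], [1, 4.5, "S3", "dead"],
            [2, 0.0, "S1", "alive"], [2, 2.0, "S1", "alive"], [2, 4.0, "S2", "alive"],
            [3, 0.0, "S2", "alive"], [3, 2.0, "S2", "alive"],
        ]
        ll_fwd = panel_log_likelihood(im, make_panel(rows))
        ll_rev = panel_log_likelihood(im, make_panel(rows[::-1]))
        assert ll_fwd == pytest.approx(ll_rev, abs=1e-10)


class TestFitMultistate:
    def test_baseline_rate_recovery_two_state_panel(self):
        """Interval-censored panel data from a single known rate: the point
        estimate should sit within three standard errors of the truth."""
        sp = StateSpace(living=("S1",), death="S2", allowed=frozenset({("S1", "S2")}))
        rows = []
        rng = np.random.default_rng(42)
        for pid in range(2000):
            t_death = rng.exponential(1 / 0.2)
            last = 0.0
            rows.append([pid, 0.0, "S1", "alive"])
            for w in (2.0, 4.0, 7.0):
                if t_death <= w:
                    rows.append([pid, t_death, "S2", "dead"])
                    break
                rows.append([pid, w, "S1", "alive"])
        res = fit_multistate(make_panel(rows), sp)
        q_hat = np.exp(res.params[0])
        se_q = q_hat * res.bse[0]  # delta method on the log scale
        assert res.converged
        assert abs(q_hat - 0.2) < 3 * se_q

    def test_group_effect_recovery_and_wald_duality(self):
        cfg = default_state_config(n_participants=3000, seed=21)
        panel, _ = simulate_cohort(cfg)
        res = fit_multistate(
            panel, cfg.true_intensities.state_space, covariate_names=("two_way",)
        )
        table = res.hazard_ratio_table(covariate="two_way")
        assert len(table) == len(res.model.transitions)
        row = table[table.transition == "S1->S2"].iloc[0]
        true_beta = np.log(0.83)
        k = list(res.model.transitions).index(("S1", "S2"))
        idx = res.model.n_transitions + k
        assert abs(res.params[idx] - true_beta) < 3 * res.bse[idx]
        # CI excludes 1 exactly when the Wald p-value is below 0.05
        for _, r in table.iterrows():
            excludes_one = r.hr_lower > 1 or r.hr_upper < 1
            assert excludes_one == (r.p < 0.05)

    def test_truth_initialization_cannot_beat_default_fit(self):
        cfg = default_state_config(n_participants=800, seed=5)
        panel, _ = simulate_cohort(cfg)
        model = MultistateModel(
            panel, cfg.true_intensities.state_space, ("two_way",)
        )
        res_default = model.fit(compute_cov=False)
        res_truth = model.fit(
            start_params=model.pack(cfg.true_intensities), compute_cov=False
        )
        assert res_truth.loglike - res_default.loglike < 1e-4

    def test_unsupported_transitions_dropped_with_warning(self):
        sp = StateSpace(living=("S1", "S2", "S3"), death="S4")
        rows = [
            [1, 0.0, "S1", "alive"], [1, 2.0, "S2", "alive"],
            [2, 0.0, "S1", "alive"], [2, 2.0, "S1", "alive"],
        ]
        with pytest.warns(UserWarning, match="dropping"):
            model = MultistateModel(make_panel(rows), sp)
        assert model.transitions == (("S1", "S2"),)

    def test_summary_mentions_fit_and_transitions(self):
        cfg = default_state_config(n_participants=300, seed=8)
        panel, _ = simulate_cohort(cfg)
        res = fit_multistate(panel, cfg.true_intensities.state_space, ("two_way",))
        text = res.summary()
        assert "log-likelihood" in text
        assert "S1->S2" in text
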