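"""Multievent model: matrix structure, emissions, forward likelihood."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetipm.multievent import (
    CaptureHistory, build_matrices, dataset_loglik, detection_probability,
    female_event_matrix, female_transition_matrix, history_loglik,
    initial_state_distribution, male_event_matrix, male_transition_matrix,
)
from cetipm.params import DetectionParams, RateSeries, VitalRateSet

prob = st.floats(0.0, 1.0, allow_nan=False)


def enumeration_loglik(history, transitions, emissions):
    """Independent oracle: sum path probabilities over all latent state paths."""
    S = emissions.shape[1]
    t0 = history.first_year
    init = initial_state_distribution(history.events[0], emissions[t0])
    L = history.n_years
    if L == 1:
        return 0.0
    total = 0.0
    for path in itertools.product(range(S), repeat=L - 1):
        for s0 in range(S):
            prob_path = init[s0]
            s_prev = s0
            for k, s in enumerate(path):
                year = t0 + k + 1
                prob_path *= transitions[year - 1][s_prev, s]
                prob_path *= emissions[year][s, history.events[k + 1] - 1]
                s_prev = s
            total += prob_path
    return np.log(total) if total > 0 else -np.inf


class TestTransitionMatrices:
    @given(phiF=prob, phiBy=prob, F=prob, gamma=prob, p1=prob, p2=prob)
    @settings(max_examples=100, deadline=None)
    def test_female_rows_stochastic(self, phiF, phiBy, F, gamma, p1, p2):
        T = female_transition_matrix(phiF, phiBy, F, gamma, p1, p2)
        assert np.all(T >= -1e-12) and np.all(T <= 1 + 1e-12)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert T[7, 7] == 1.0  # dead is absorbing

    @given(phiJS=prob, phiAd=prob, psiM=prob)
    @settings(max_examples=100, deadline=None)
    def test_male_rows_stochastic(self, phiJS, phiAd, psiM):
        T = male_transition_matrix(phiJS, phiAd, psiM)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert T[4, 4] == 1.0

    def test_zero_survival_sends_everything_to_dead(self):
        T = female_transition_matrix(0, 0.8, 0.5, 0.4, 0.2, 0.3)
        np.testing.assert_allclose(T[:7, 7], 1.0)

    def test_deterministic_calf_retention(self):
        T = female_transition_matrix(1, 1, 1, 0.4, 0.2, 0.3)
        assert T[2, 3] == 1.0   # By -> Bc1
        assert T[4, 5] == 1.0   # Bc2 -> Bc3

    def test_male_no_advance_and_deterministic_chain(self):
        T = male_transition_matrix(0.9, 0.8, 0.0)
        assert T[0, 0] == pytest.approx(0.9) and T[0, 1] == 0.0
        T = male_transition_matrix(1.0, 1.0, 1.0)
        assert T[0, 1] == T[1, 2] == T[2, 3] == T[3, 3] == 1.0

    def test_out_of_range_names_parameter(self):
        with pytest.raises(ValueError, match="phiBy"):
            female_transition_matrix(0.5, 1.2, 0.5, 0.4, 0.2, 0.3)
        with pytest.raises(ValueError, match="psiM"):
            male_transition_matrix(0.5, 0.5, -0.1)


class TestEventMatrices:
    @given(p=prob, dPb=prob, dNb=prob)
    @settings(max_examples=100, deadline=None)
    def test_female_rows_sum_to_one(self, p, dPb, dNb):
        E = female_event_matrix(p, dPb, dNb)
        np.testing.assert_allclose(E.sum(axis=1), 1.0, atol=1e-12)
        assert E[7, 0] == 1.0  # dead emits "not seen"

    @given(p=st.lists(prob, min_size=4, max_size=4), d1=prob, d2=prob)
    @settings(max_examples=100, deadline=None)
    def test_male_rows_sum_to_one(self, p, d1, d2):
        E = male_event_matrix(np.array(p), d1, d2)
        np.testing.assert_allclose(E.sum(axis=1), 1.0, atol=1e-12)
        assert E[4, 0] == 1.0

    def test_perfect_detection_is_deterministic_map(self):
        E = female_event_matrix(1.0, 1.0, 1.0)
        expected_events = {0: 2, 1: 3, 2: 4, 3: 5, 4: 5, 5: 5, 6: 6}
        for state, event in expected_events.items():
            assert E[state, event - 1] == 1.0
        Em = male_event_matrix(np.ones(4), 1.0, 1.0)
        for state, event in {0: 2, 1: 3, 2: 4, 3: 5}.items():
            assert Em[state, event - 1] == 1.0

    def test_no_detection_emits_not_seen(self):
        E = female_event_matrix(0.0, 0.3, 0.7)
        np.testing.assert_allclose(E[:, 0], 1.0)
        Em = male_event_matrix(np.zeros(4), 0.3, 0.7)
        np.testing.assert_allclose(Em[:, 0], 1.0)

    def test_ambiguous_codes_split_detection(self):
        E = female_event_matrix(0.6, 0.25, 0.75)
        assert E[1, 2] == pytest.approx(0.15)       # Pb classified
        assert E[1, 6] == pytest.approx(0.45)       # Pb "seen alone"
        Em = male_event_matrix(np.full(4, 0.6), 0.25, 0.75)
        assert Em[2, 3] == pytest.approx(0.15)      # AdNt classified
        assert Em[2, 5] == pytest.approx(0.45)      # AdNt "seen as adult"


class TestDetectionProbability:
    def test_center(self):
        assert detection_probability(0, 0, 0.0) == pytest.approx(0.5)

    def test_monotone_in_effort(self):
        z = np.linspace(-2, 2, 9)
        p = detection_probability(-0.5, 0.7, z)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_linear_predictor_identity(self):
        assert detection_probability(-1.0, 0.5, 2.0, 0.0) == pytest.approx(0.5)


class TestInitialStateDistribution:
    def test_unambiguous_event(self):
        E = female_event_matrix(0.4, 0.6, 0.7)
        d = initial_state_distribution(4, E)
        assert d[2] == pytest.approx(1.0)

    def test_seen_alone_symmetric(self):
        E = female_event_matrix(0.4, 0.5, 0.5)
        d = initial_state_distribution(7, E)
        np.testing.assert_allclose(d[[1, 6]], 0.5)

    def test_calf_event_uniform_over_calf_ages(self):
        E = female_event_matrix(0.4, 0.6, 0.7)
        d = initial_state_distribution(5, E)
        np.testing.assert_allclose(d[[3, 4, 5]], 1 / 3)
        assert d.sum() == pytest.approx(1.0)

    def test_not_seen_rejected(self):
        E = female_event_matrix(0.4, 0.6, 0.7)
        with pytest.raises(ValueError):
            initial_state_distribution(1, E)


def _matrices(n_years, rates=None, detection=None, effort=None):
    rates = rates or VitalRateSet(0.9, 0.8, 0.5, 0.4, 0.2, 0.3, 0.95, 0.9, 0.3, 0.0)
    series = RateSeries.constant(rates, n_years - 1)
    detection = detection or DetectionParams()
    effort = effort if effort is not None else np.arange(n_years) + 3
    return build_matrices(series, detection, effort)


class TestHistoryLoglik:
    def test_single_final_detection_is_zero(self):
        Tf, _, Ef, _ = _matrices(5)
        h = CaptureHistory(0, "F", 4, [4])
        assert history_loglik(h, Tf, Ef) == 0.0

    def test_two_year_hand_enumeration(self):
        # juvenile seen then missed: survive-and-miss or die
        rates = VitalRateSet(0.9, 0.8, 0.5, 0.4, 0.2, 0.3, 0.95, 0.9, 0.3, 0.0)
        det = DetectionParams(alpha_F=np.log(0.4 / 0.6), beta_effort=0.0,
                              sd_year_F=0.0, deltaPb=1.0, deltaNb=1.0)
        Tf, _, Ef, _ = _matrices(2, rates, det, np.array([5, 5]))
        h = CaptureHistory(0, "F", 0, [2, 1])
        assert history_loglik(h, Tf, Ef) == pytest.approx(np.log(0.64), abs=1e-12)

    def test_impossible_sequence_gives_minus_inf(self):
        # a breeder with young cannot be a juvenile the next year
        Tf, _, Ef, _ = _matrices(3)
        h = CaptureHistory(0, "F", 0, [4, 2])
        assert history_loglik(h, Tf, Ef) == -np.inf

    def test_forward_matches_enumeration_on_random_cases(self, rng):
        """Forward algorithm vs exhaustive path enumeration, histories <= 5 yrs."""
        n_cases = 120
        checked = 0
        while checked < n_cases:
            n_years = int(rng.integers(2, 6))
            rates = VitalRateSet(*rng.uniform(0.05, 0.95, size=9), 0.0)
            det = DetectionParams(
                alpha_F=rng.normal(), alpha_M_by_stage=rng.normal(size=4),
                beta_effort=rng.normal(scale=0.5),
                deltaPb=rng.uniform(), deltaNb=rng.uniform(),
                deltaAdNt=rng.uniform(), deltaAd=rng.uniform(),
            )
            effort = rng.integers(2, 23, size=n_years)
            Tf, Tm, Ef, Em = _matrices(n_years, rates, det, effort)
            sex = "F" if rng.random() < 0.5 else "M"
            n_events = 7 if sex == "F" else 6
            first = int(rng.integers(0, n_years))
            events = rng.integers(1, n_events + 1, size=n_years - first)
            events[0] = rng.integers(2, n_events + 1)
            h = CaptureHistory(0, sex, first, events)
            trans, emit = (Tf, Ef) if sex == "F" else (Tm, Em)
            got = history_loglik(h, trans, emit)
            want = enumeration_loglik(h, trans, emit)
            if want == -np.inf:
                assert got == -np.inf
            else:
                assert got == pytest.approx(want, abs=1e-10)
            checked += 1

    def test_single_detection_loglik_increases_as_p_decreases(self):
        # seen once then never again: lower detection makes that more likely
        rates = VitalRateSet(0.9, 0.8, 0.5, 0.4, 0.2, 0.3, 0.95, 0.9, 0.3, 0.0)
        logliks = []
        for alpha in (1.0, 0.0, -1.0, -2.0):
            det = DetectionParams(alpha_F=alpha, beta_effort=0.0, sd_year_F=0.0)
            Tf, _, Ef, _ = _matrices(6, rates, det, np.full(6, 5))
            h = CaptureHistory(0, "F", 0, [2, 1, 1, 1, 1, 1])
            logliks.append(history_loglik(h, Tf, Ef))
        assert np.all(np.diff(logliks) > 0)


class TestDatasetLoglik:
    def test_empty_set_is_zero(self):
        rates = RateSeries.constant(
            VitalRateSet(0.9, 0.8, 0.5, 0.4, 0.2, 0.3, 0.95, 0.9, 0.3, 0.0), 4)
        assert dataset_loglik([], rates, DetectionParams(), np.full(5, 5)) == 0.0

    def test_additivity_and_permutation_invariance(self, sim):
        hs = sim.histories[:40]
        rates = sim.rates
        det = sim.truth.detection
        base = dataset_loglik(hs, rates, det, sim.effort, sim.eps_F, sim.eps_M)
        double = dataset_loglik(hs + hs, rates, det, sim.effort, sim.eps_F, sim.eps_M)
        assert double == pytest.approx(2 * base, rel=1e-12)
        shuffled = list(reversed(hs))
        assert dataset_loglik(shuffled, rates, det, sim.effort, sim.eps_F,
                              sim.eps_M) == pytest.approx(base, rel=1e-12)

    def test_simulated_histories_finite_and_nonpositive(self, sim):
        ll = dataset_loglik(sim.histories[:50], sim.rates, sim.truth.detection,
                            sim.effort, sim.eps_F, sim.eps_M)
        assert np.isfinite(ll) and ll <= 0.0
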