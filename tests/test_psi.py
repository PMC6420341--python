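"""Psi adaptive procedure: selection, update, estimation, determinism."""

import math

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import entropy as shannon_entropy

from facebody.psi import (
    PsiConfigError,
    bernoulli_responder,
    default_psi_state,
    expected_entropies,
    posterior_entropy,
    psi_estimate,
    psi_init,
    psi_select,
    psi_update,
    run_psi_session,
)
from facebody.psychometric import PsychometricParams, pf_eval


def brute_force_select(alpha_grid, sigma_grid, candidates, posterior, gamma, lam):
    """Exhaustive expected-entropy enumeration over all (x, response) branches."""
    posterior = np.asarray(posterior, dtype=float).reshape(len(alpha_grid), len(sigma_grid))
    posterior = posterior / posterior.sum()
    best_x, best_eh = None, np.inf
    for x in candidates:
        eh = 0.0
        for r in (0, 1):
            w = np.zeros_like(posterior)
            for i, a in enumerate(alpha_grid):
                for j, s in enumerate(sigma_grid):
                    p1 = gamma + (1 - gamma - lam) * ndtr((x - a) / s)
                    w[i, j] = posterior[i, j] * (p1 if r == 1 else 1 - p1)
            p_r = w.sum()
            if p_r > 0:
                eh += p_r * shannon_entropy((w / p_r).ravel())
        if eh < best_eh - 1e-12:
            best_eh, best_x = eh, x
    return best_x


class TestInit:
    def test_uniform_prior_normalisation(self):
        st = psi_init(np.linspace(0, 1, 21), np.geomspace(0.05, 0.5, 11),
                      np.linspace(0, 1, 5))
        assert st.posterior.shape == (231,)
        assert np.allclose(st.posterior, 1 / 231)
        assert st.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_explicit_prior_normalised(self):
        st = psi_init([0.4, 0.6], [0.1], [0.5], prior=[2.0, 2.0])
        assert np.allclose(st.posterior, [0.5, 0.5])

    def test_zero_prior_rejected(self):
        with pytest.raises(PsiConfigError, match="prior"):
            psi_init([0.4, 0.6], [0.1], [0.5], prior=[0.0, 0.0])

    def test_empty_grid_rejected(self):
        with pytest.raises(PsiConfigError):
            psi_init([], [0.1], [0.5])
        with pytest.raises(PsiConfigError):
            psi_init([0.5], [0.1], [])


class TestSelect:
    def test_point_mass_posterior_breaks_tie_to_lowest_candidate(self):
        prior = np.zeros(9)
        prior[4] = 1.0
        st = psi_init(np.linspace(0.3, 0.7, 3), [0.05, 0.1, 0.2],
                      [0.2, 0.5, 0.8], prior=prior)
        assert np.allclose(expected_entropies(st), 0.0, atol=1e-9)
        assert psi_select(st) == 0.2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_posteriors(self, seed):
        rng = np.random.default_rng(seed)
        na, ns, nc = rng.integers(2, 4), rng.integers(1, 4), rng.integers(2, 6)
        alpha_grid = np.sort(rng.uniform(0, 1, na))
        sigma_grid = np.sort(rng.uniform(0.05, 0.4, ns))
        candidates = np.sort(rng.uniform(0, 1, nc))
        prior = rng.uniform(0.1, 1.0, na * ns)
        st = psi_init(alpha_grid, sigma_grid, candidates, prior=prior)
        expected = brute_force_select(alpha_grid, sigma_grid, candidates,
                                      prior, st.gamma, st.lam)
        assert psi_select(st) == pytest.approx(expected, abs=1e-12)

    def test_expected_entropy_symmetric_around_half(self):
        st = psi_init(np.linspace(0.2, 0.8, 7), [0.1],
                      np.linspace(0.1, 0.9, 9), gamma=0.0, lam=0.0)
        eh = expected_entropies(st)
        assert np.allclose(eh, eh[::-1], atol=1e-12)


class TestUpdate:
    def test_two_hypothesis_bayes_by_hand(self):
        # alpha in {0.4, 0.6}, sigma=0.1: P(anger | x=0.5) is 0.97*Phi(+-1);
        # the 0.97 factors cancel, so posterior(0.4) = Phi(1)/(Phi(1)+Phi(-1))
        st = psi_init([0.4, 0.6], [0.1], np.linspace(0, 1, 41),
                      gamma=0.0, lam=0.03)
        st = psi_update(st, 0.5, 1)
        phi1 = 0.5 * (1 + math.erf(1 / math.sqrt(2)))
        assert st.posterior[0] == pytest.approx(phi1, abs=1e-9)
        assert st.posterior[0] == pytest.approx(0.8413, abs=5e-5)

    def test_posterior_sums_to_one_after_every_update(self):
        st = default_psi_state()
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = float(rng.choice(st.candidates))
            st = psi_update(st, x, int(rng.integers(2)))
            assert st.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(st.history) == 20

    def test_point_mass_is_absorbing(self):
        prior = np.zeros(3)
        prior[1] = 1.0
        st = psi_init([0.3, 0.5, 0.7], [0.1], [0.2, 0.5, 0.8], prior=prior)
        for r in (0, 1, 1, 0):
            st = psi_update(st, 0.5, r)
        assert np.allclose(st.posterior, [0, 1, 0], atol=1e-12)

    def test_invalid_response_rejected(self):
        st = default_psi_state()
        with pytest.raises(ValueError, match="response"):
            psi_update(st, 0.5, 2)

    def test_off_candidate_stimulus_warns_but_updates(self):
        st = psi_init([0.4, 0.6], [0.1], [0.0, 1.0])
        with pytest.warns(UserWarning, match="candidate"):
            st = psi_update(st, 0.5, 1)
        assert st.posterior.sum() == pytest.approx(1.0, abs=1e-12)


class TestEstimate:
    def test_uniform_symmetric_grid_centres_at_half(self):
        st = psi_init(np.linspace(0.2, 0.8, 13), [0.05, 0.1], [0.5])
        st.history.append((0.5, 1))  # silence the no-update warning
        a, _ = psi_estimate(st)
        assert a == pytest.approx(0.5, abs=1e-12)

    def test_point_mass_returns_cell(self):
        alpha_grid = np.array([0.3, 0.45, 0.6])
        sigma_grid = np.array([0.08, 0.12])
        prior = np.zeros(6)
        prior[1 * 2 + 1] = 1.0  # (alpha=0.45, sigma=0.12)
        st = psi_init(alpha_grid, sigma_grid, [0.5], prior=prior)
        st.history.append((0.5, 0))
        assert psi_estimate(st) == pytest.approx((0.45, 0.12), abs=1e-12)

    def test_warns_before_any_update(self):
        st = default_psi_state()
        with pytest.warns(UserWarning, match="update"):
            psi_estimate(st)


class TestSessionDynamics:
    def test_deterministic_given_seeded_observer(self):
        truth = PsychometricParams(0.45, 0.1, 0.0, 0.03)
        traces = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            _, trace = run_psi_session(bernoulli_responder(truth, rng), 40)
            traces.append(trace)
        assert traces[0].equals(traces[1])

    def test_entropy_nonincreasing_in_expectation_each_trial(self):
        # at the selected stimulus, the response-averaged posterior entropy
        # never exceeds the current entropy (information never hurts)
        st = default_psi_state()
        rng = np.random.default_rng(9)
        truth = PsychometricParams(0.55, 0.15, 0.0, 0.03)
        for _ in range(30):
            h_now = posterior_entropy(st)
            eh = expected_entropies(st).min()
            assert eh <= h_now + 1e-10
            x = psi_select(st)
            st = psi_update(st, x, int(rng.random() < pf_eval(truth, x)))

    def test_posterior_concentrates_on_true_cell(self):
        # observer drawn from the grid: mass on the truth should grow
        alpha_grid = np.linspace(0, 1, 11)
        sigma_grid = np.geomspace(0.05, 0.3, 5)
        truth = PsychometricParams(alpha_grid[5], sigma_grid[2], 0.0, 0.03)
        gains = []
        for seed in range(20):
            st = psi_init(alpha_grid, sigma_grid, np.linspace(0, 1, 21),
                          gamma=0.0, lam=0.03)
            rng = np.random.default_rng(seed)
            start = st.posterior[5 * 5 + 2]
            for _ in range(60):
                x = psi_select(st)
                st = psi_update(st, x, int(rng.random() < pf_eval(truth, x)))
            gains.append(st.posterior[5 * 5 + 2] - start)
        assert np.median(gains) > 0

    def test_recovery_within_tolerance(self):
        # population rate of |error| < 0.03 sits near 0.9 under these
        # conditions; assert with Monte-Carlo slack plus a tight median
        truth = PsychometricParams(0.5, 0.12, 0.0, 0.03)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            st, _ = run_psi_session(bernoulli_responder(truth, rng), 144)
            a_hat, _ = psi_estimate(st)
            errs.append(abs(a_hat - 0.5))
        errs = np.array(errs)
        assert np.median(errs) < 0.02
        assert np.mean(errs < 0.03) >= 0.85
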