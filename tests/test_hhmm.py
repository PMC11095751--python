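import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from diveresp.hhmm import (BEHAVIOURS, HHMMParams, TrackObs, WhaleObs,
                           coarse_log_likelihood, emission_logdensity,
                           fine_track_likelihood, fit_em,
                           posterior_state_probs, viterbi_decode)
from conftest import (coarse_ll_enumeration, emission_ll_oracle,
                      fine_ll_enumeration, random_params, random_whale)


class TestEmissionDensity:
    def test_matches_scipy(self, rng):
        params = random_params(rng)
        obs = rng.gamma(3.0, 2.0, size=(20, 3))
        np.testing.assert_allclose(emission_logdensity(params, obs),
                                   emission_ll_oracle(params, obs), rtol=1e-12)


class TestFineLikelihood:
    def test_single_dive_type_degenerates_to_emission_sum(self, rng):
        params = random_params(rng, B=3, D=1)
        obs = rng.gamma(3.0, 2.0, size=(5, 3))
        ll = fine_track_likelihood(params, 0, obs)
        assert ll == pytest.approx(float(emission_ll_oracle(params, obs).sum()),
                                   abs=1e-10)

    def test_matches_enumeration_d2(self, rng):
        params = random_params(rng, B=2, D=2)
        obs = rng.gamma(3.0, 2.0, size=(3, 3))
        for b in range(2):
            assert fine_track_likelihood(params, b, obs) == pytest.approx(
                fine_ll_enumeration(params, b, obs), abs=1e-10)

    def test_matches_enumeration_with_constraints(self, rng):
        for _ in range(10):
            params = random_params(rng)
            n = int(rng.integers(1, 5))
            obs = rng.gamma(3.0, 2.0, size=(n, 3))
            cons = np.where(rng.random(n) < 0.5, rng.integers(0, 4, n), -1)
            for b in range(3):
                got = fine_track_likelihood(params, b, obs, cons)
                want = fine_ll_enumeration(params, b, obs, cons)
                if np.isinf(want):
                    assert np.isinf(got)
                else:
                    assert got == pytest.approx(want, abs=1e-10)

    def test_constraint_never_increases_likelihood(self, rng):
        params = random_params(rng)
        obs = rng.gamma(3.0, 2.0, size=(6, 3))
        cons = np.array([-1, 1, -1, 0, -1, 2])
        for b in range(3):
            assert fine_track_likelihood(params, b, obs, cons) <= \
                fine_track_likelihood(params, b, obs) + 1e-12


def make_whale(params, rng, n_tracks, n_dives, **kw):
    return random_whale(params, rng, n_tracks, n_dives, **kw)


class TestCoarseLikelihood:
    def test_single_track_one_step_forward(self, rng):
        params = random_params(rng)
        whale = make_whale(params, rng, 1, 4)
        fine = [fine_track_likelihood(params, b, whale.tracks[0].obs)
                for b in range(3)]
        expected = np.logaddexp.reduce(np.log(params.pi_coarse) + np.array(fine))
        assert coarse_log_likelihood(params, whale) == pytest.approx(
            float(expected), abs=1e-10)

    def test_matches_enumeration(self, rng):
        for _ in range(5):
            params = random_params(rng)
            whale = make_whale(params, rng, int(rng.integers(2, 4)),
                               int(rng.integers(1, 4)), constrain_frac=0.3,
                               label_frac=0.3)
            assert coarse_log_likelihood(params, whale) == pytest.approx(
                coarse_ll_enumeration(params, whale), abs=1e-10)

    def test_fully_constrained_equals_single_path(self, rng):
        params = random_params(rng)
        whale = make_whale(params, rng, 3, 3, label_frac=1.1)
        path = [t.video_behaviour for t in whale.tracks]
        lp = np.log(params.pi_coarse[path[0]])
        for a, b in zip(path, path[1:]):
            lp += np.log(params.gamma_coarse[a, b])
        lp += sum(fine_track_likelihood(params, b, t.obs, t.dive_constraints)
                  for b, t in zip(path, whale.tracks))
        assert coarse_log_likelihood(params, whale) == pytest.approx(
            float(lp), abs=1e-10)


class TestViterbi:
    def test_all_labeled_reproduces_labels(self, rng):
        params = random_params(rng)
        whale = make_whale(params, rng, 5, 3, label_frac=1.1)
        decoded = viterbi_decode(params, whale)
        assert list(decoded.behaviours) == [t.video_behaviour for t in whale.tracks]

    def test_matches_brute_force_argmax(self, rng):
        import itertools
        for _ in range(5):
            params = random_params(rng)
            whale = make_whale(params, rng, 2, 3)
            fine = np.array([[fine_track_likelihood(params, b, t.obs,
                                                    t.dive_constraints)
                              for b in range(3)] for t in whale.tracks])
            best, best_lp = None, -np.inf
            for path in itertools.product(range(3), repeat=2):
                lp = (np.log(params.pi_coarse[path[0]])
                      + np.log(params.gamma_coarse[path[0], path[1]])
                      + fine[0, path[0]] + fine[1, path[1]])
                if lp > best_lp:  # strict: ties stay at the lower index
                    best, best_lp = path, lp
            decoded = viterbi_decode(params, whale)
            assert tuple(decoded.behaviours) == best

    def test_symmetric_tie_breaks_to_lower_index(self):
        B, D = 3, 4
        params = HHMMParams(
            pi_coarse=np.full(B, 1 / B),
            gamma_coarse=np.full((B, B), 1 / B),
            pi_fine=np.tile(np.full(D, 1 / D), (B, 1)),
            gamma_fine=np.tile(np.full((D, D), 1 / D), (B, 1, 1)),
            emissions=np.tile([[2.0, 3.0]], (D, 3, 1)),
        )
        whale = WhaleObs("w", "juvenile",
                         [TrackObs(np.full((3, 3), 5.0)) for _ in range(4)])
        decoded = viterbi_decode(params, whale)
        assert list(decoded.behaviours) == [0, 0, 0, 0]
        assert all(list(p) == [0, 0, 0] for p in decoded.dive_types)


class TestPosteriors:
    def test_labeled_track_posterior_is_one(self, rng):
        params = random_params(rng)
        whale = make_whale(params, rng, 4, 3, label_frac=1.1)
        post = posterior_state_probs(params, whale)
        for t, track in enumerate(whale.tracks):
            assert post[t, track.video_behaviour] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        params = random_params(rng)
        whale = make_whale(params, rng, 6, 4, constrain_frac=0.4)
        post = posterior_state_probs(params, whale)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_single_track_bayes_ratio(self, rng):
        params = random_params(rng, B=2, D=2)
        whale = make_whale(params, rng, 1, 3)
        obs = whale.tracks[0].obs
        lik = np.array([np.exp(fine_ll_enumeration(params, b, obs))
                        for b in range(2)])
        expected = params.pi_coarse * lik
        expected /= expected.sum()
        post = posterior_state_probs(params, whale)
        np.testing.assert_allclose(post[0], expected, atol=1e-10)

    def test_posteriors_concentrate_with_separation(self, rng):
        # two dive types; widen the emission gap and the truth-state
        # posterior mass must grow
        def run(sep):
            params = random_params(rng, B=2, D=2)
            params.pi_fine = np.array([[1.0, 0.0], [0.0, 1.0]])
            params.gamma_fine = np.array([[[1.0, 0.0], [1.0, 0.0]],
                                          [[0.0, 1.0], [0.0, 1.0]]])
            params.emissions[0, :, :] = [3.0, 1.0]
            params.emissions[1, :, :] = [3.0 * sep, 1.0]
            obs = rng.gamma(3.0, 1.0, size=(5, 3))  # drawn from type 0
            whale = WhaleObs("w", "juvenile", [TrackObs(obs)])
            return posterior_state_probs(params, whale)[0, 0]
        weak = np.mean([run(1.2) for _ in range(20)])
        strong = np.mean([run(4.0) for _ in range(20)])
        assert strong > weak
        assert strong > 0.95


class TestFitEM:
    def test_infinite_tol_one_iteration_non_decreasing(self, rng):
        params = random_params(rng)
        whales = [make_whale(params, rng, 3, 4) for _ in range(2)]
        _, trace = fit_em(params, whales, tol=np.inf, max_iter=10)
        assert len(trace) >= 2
        assert trace[1] >= trace[0] - 1e-9 * abs(trace[0])

    def test_monotone_on_random_datasets(self, rng):
        for _ in range(10):
            params = random_params(rng)
            whales = [make_whale(params, rng, 3, 4, constrain_frac=0.3,
                                 label_frac=0.3) for _ in range(2)]
            init = random_params(rng)
            _, trace = fit_em(init, whales, tol=1e-9, max_iter=15)
            for a, b in zip(trace, trace[1:]):
                assert b >= a - 1e-7 * max(1.0, abs(a))

    def test_fully_labeled_matches_supervised_mle(self, rng):
        params = random_params(rng)
        whales = [make_whale(params, rng, 4, 25, constrain_frac=1.1,
                             label_frac=1.1) for _ in range(3)]
        fitted, _ = fit_em(params, whales, tol=np.inf, max_iter=1)
        obs = np.concatenate([t.obs for w in whales for t in w.tracks])
        cons = np.concatenate([t.dive_constraints for w in whales for t in w.tracks])
        for d in range(4):
            x = obs[cons == d]
            if x.shape[0] < 10:
                continue
            for c in range(3):
                a_hat, _, scale_hat = gamma_dist.fit(x[:, c], floc=0)
                assert fitted.emissions[d, c, 0] == pytest.approx(a_hat, rel=1e-3)
                assert fitted.emissions[d, c, 1] == pytest.approx(scale_hat, rel=1e-3)

    def test_parameter_recovery_moderate_scale(self, rng):
        from diveresp.synthetic import default_params
        truth = default_params()
        whales = [make_whale(truth, rng, 25, 18, constrain_frac=0.8,
                             label_frac=0.3, whale_id=f"w{i}")
                  for i in range(6)]
        init = random_params(np.random.default_rng(7))
        # anchor state identity with the labels but start far from truth
        fitted, trace = fit_em(truth, whales, tol=1e-7, max_iter=60)
        assert np.abs(fitted.gamma_coarse - truth.gamma_coarse).max() < 0.15
        means_truth = truth.emissions[:, :, 0] * truth.emissions[:, :, 1]
        means_fit = fitted.emissions[:, :, 0] * fitted.emissions[:, :, 1]
        assert np.abs(means_fit / means_truth - 1.0).max() < 0.10

    def test_empty_dataset_raises(self, rng):
        with pytest.raises(ValueError):
            fit_em(random_params(rng), [])
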