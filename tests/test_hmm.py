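"""Bernoulli-emission HMM: binarization, likelihood oracle, EM recovery."""

import itertools

import numpy as np
import pytest
from scipy.stats import poisson

from elekit.hmm import (BinnedTracks, ChromatinHMM, binarize, decode, fit,
                        loglik, posterior, tss_active_state)


def make_tracks(matrix, names=None, chrom="c"):
    matrix = np.asarray(matrix)
    names = names or [f"t{j}" for j in range(matrix.shape[1])]
    return BinnedTracks(500, names, [chrom], {chrom: matrix})


def enumeration_loglik(model, chain):
    """Independent oracle: sum over all state paths."""
    chain = np.asarray(chain)
    S = model.n_states
    total = 0.0
    for path in itertools.product(range(S), repeat=chain.shape[0]):
        p = model.initial[path[0]]
        for t in range(1, len(path)):
            p *= model.transitions[path[t - 1], path[t]]
        for t, s in enumerate(path):
            for j in range(chain.shape[1]):
                e = model.emissions[s, j]
                p *= e if chain[t, j] else 1 - e
        total += p
    return np.log(total) if total > 0 else -np.inf


def random_model(rng, n_states, n_tracks):
    pi = rng.dirichlet(np.ones(n_states))
    T = rng.dirichlet(np.ones(n_states), size=n_states)
    E = rng.uniform(0.05, 0.95, (n_states, n_tracks))
    names = [f"t{j}" for j in range(n_tracks)]
    return ChromatinHMM(pi, T, E, names)


def sample_chain(model, n, rng):
    states = np.zeros(n, dtype=int)
    obs = np.zeros((n, model.emissions.shape[1]), dtype=np.int8)
    states[0] = rng.choice(model.n_states, p=model.initial)
    for t in range(1, n):
        states[t] = rng.choice(model.n_states, p=model.transitions[states[t - 1]])
    for t in range(n):
        obs[t] = rng.random(model.emissions.shape[1]) < model.emissions[states[t]]
    return states, obs


class TestBinarize:
    def test_poisson_tail_rule(self):
        # one track, mean 1.0: count 0 stays 0; count 10 has
        # P(X >= 10 | 1) ~ 1.1e-7 < 1e-4 and flips to 1
        counts = {"c": np.array([[0], [10], [0], [0], [0], [0], [0], [0]])}
        counts["c"][2:, 0] = 0
        lam = counts["c"].mean()
        assert poisson.sf(9, lam) < 1e-4
        tracks = binarize(counts, ["CAGE"])
        col = tracks.matrices["c"][:, 0]
        assert col[1] == 1 and col[0] == 0

    def test_constant_track_all_zero(self):
        counts = {"c": np.full((20, 1), 3)}
        tracks = binarize(counts, ["x"])
        assert not tracks.matrices["c"].any()

    def test_all_zero_track_warns(self):
        counts = {"c": np.zeros((10, 1), dtype=int)}
        with pytest.warns(UserWarning, match="all-zero"):
            tracks = binarize(counts, ["x"])
        assert not tracks.matrices["c"].any()


class TestLoglikOracle:
    def test_forced_path(self):
        model = ChromatinHMM(np.array([1.0, 0.0]),
                             np.array([[1.0, 0.0], [0.0, 1.0]]),
                             np.array([[1.0], [0.0]]), ["t0"])
        assert loglik(model, make_tracks([[1]], ["t0"])) == 0.0
        assert loglik(model, make_tracks([[0]], ["t0"])) == -np.inf

    def test_track_name_mismatch(self):
        model = random_model(np.random.default_rng(0), 2, 1)
        with pytest.raises(ValueError, match="track-name"):
            loglik(model, make_tracks([[1]], ["other"]))

    @pytest.mark.parametrize("n_states", [2, 3])
    @pytest.mark.parametrize("length", [1, 3, 5, 8])
    def test_matches_path_enumeration(self, n_states, length):
        rng = np.random.default_rng(100 * n_states + length)
        model = random_model(rng, n_states, 2)
        chain = (rng.random((length, 2)) < 0.5).astype(np.int8)
        got = loglik(model, make_tracks(chain, model.track_names))
        want = enumeration_loglik(model, chain)
        assert got == pytest.approx(want, abs=1e-8)


class TestFit:
    def test_two_state_parameter_recovery(self):
        rng = np.random.default_rng(5)
        true = ChromatinHMM(np.array([0.5, 0.5]),
                            np.array([[0.95, 0.05], [0.1, 0.9]]),
                            np.array([[0.9], [0.1]]), ["t0"])
        _, obs = sample_chain(true, 10_000, rng)
        tracks = make_tracks(obs, ["t0"])
        model, ll = fit(tracks, n_states=2, seed=3, n_restarts=3)
        # match states by emission
        order = np.argsort(-model.emissions[:, 0])
        E = model.emissions[order]
        T = model.transitions[order][:, order]
        assert E[0, 0] == pytest.approx(0.9, abs=0.05)
        assert E[1, 0] == pytest.approx(0.1, abs=0.05)
        assert T[0, 0] == pytest.approx(0.95, abs=0.05)
        assert T[1, 1] == pytest.approx(0.9, abs=0.05)

    def test_same_seed_identical_model(self):
        rng = np.random.default_rng(7)
        obs = (rng.random((300, 2)) < 0.3).astype(np.int8)
        tracks = make_tracks(obs)
        m1, ll1 = fit(tracks, n_states=2, seed=9, n_restarts=2)
        m2, ll2 = fit(tracks, n_states=2, seed=9, n_restarts=2)
        assert ll1 == ll2
        np.testing.assert_array_equal(m1.emissions, m2.emissions)
        np.testing.assert_array_equal(m1.transitions, m2.transitions)

    def test_single_state_rejected(self):
        tracks = make_tracks(np.zeros((40, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="n_states"):
            fit(tracks, n_states=1)

    def test_parameters_stay_valid(self):
        rng = np.random.default_rng(13)
        obs = (rng.random((500, 3)) < 0.4).astype(np.int8)
        model, _ = fit(make_tracks(obs), n_states=3, seed=1, n_restarts=2)
        assert model.initial.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(model.transitions.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert ((model.emissions >= 0) & (model.emissions <= 1)).all()


class TestDecode:
    def test_deterministic_emissions_recover_path(self):
        rng = np.random.default_rng(21)
        model = ChromatinHMM(np.array([0.5, 0.5]),
                             np.array([[0.9, 0.1], [0.1, 0.9]]),
                             np.array([[1.0], [0.0]]), ["t0"])
        states, obs = sample_chain(model, 200, rng)
        got = decode(model, make_tracks(obs, ["t0"]))["c"]
        np.testing.assert_array_equal(got, states)

    def test_uniform_model_ties_to_state_zero(self):
        model = ChromatinHMM(np.array([0.5, 0.5]),
                             np.full((2, 2), 0.5),
                             np.full((2, 1), 0.5), ["t0"])
        got = decode(model, make_tracks([[0], [1], [0]], ["t0"]))["c"]
        np.testing.assert_array_equal(got, [0, 0, 0])

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, 3, 2)
        _, obs = sample_chain(model, 50, rng)
        gamma = posterior(model, obs)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_fit_then_decode_accuracy(self):
        rng = np.random.default_rng(17)
        true = ChromatinHMM(np.array([0.5, 0.5]),
                            np.array([[0.95, 0.05], [0.1, 0.9]]),
                            np.array([[0.9], [0.1]]), ["t0"])
        states, obs = sample_chain(true, 10_000, rng)
        tracks = make_tracks(obs, ["t0"])
        model, _ = fit(tracks, n_states=2, seed=2, n_restarts=3)
        got = decode(model, tracks)["c"]
        acc = max(np.mean(got == states), np.mean((1 - got) == states))
        assert acc >= 0.95


class TestTssActiveState:
    def _model(self, emissions, names):
        n = emissions.shape[0]
        return ChromatinHMM(np.full(n, 1 / n), np.full((n, n), 1 / n),
                            emissions, names)

    def test_joint_enrichment_wins(self):
        names = ["CAGE", "H3K4me3", "H3K9ac", "x"]
        E = np.array([[0.2, 0.2, 0.1, 0.9],
                      [0.9, 0.9, 0.9, 0.1],
                      [0.2, 0.1, 0.2, 0.5]])
        assert tss_active_state(self._model(E, names)) == 1

    def test_tie_breaks_low_index(self):
        names = ["CAGE", "H3K4me3", "H3K9ac"]
        E = np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
        assert tss_active_state(self._model(E, names)) == 0

    def test_missing_tracks_rejected(self):
        model = self._model(np.full((2, 1), 0.5), ["CAGE"])
        with pytest.raises(ValueError, match="required tracks"):
            tss_active_state(model)


def test_loglik_agrees_with_hmmlearn_on_single_track():
    """Cross-check against an independent HMM library: a one-track
    Bernoulli HMM is a categorical HMM over two symbols."""
    from hmmlearn.hmm import CategoricalHMM

    rng = np.random.default_rng(29)
    model = random_model(rng, 3, 1)
    _, obs = sample_chain(model, 200, rng)
    ref = CategoricalHMM(n_components=3)
    ref.startprob_ = model.initial
    ref.transmat_ = model.transitions
    ref.emissionprob_ = np.column_stack(
        [1 - model.emissions[:, 0], model.emissions[:, 0]]
    )
    want = ref.score(obs.reshape(-1, 1).astype(int))
    got = loglik(model, make_tracks(obs, model.track_names))
    assert got == pytest.approx(want, abs=1e-8)


def test_tss_state_covers_planted_promoters(pipeline_state):
    """The functionally identified TSS-active state decodes >= 80% of
    planted expressed-gene promoter bins on the synthetic genome."""
    import elekit.evaluate as ev

    state = pipeline_state
    overlap = ev.promoter_state_overlap(state.states, state.tss_state,
                                        state.truth)
    assert overlap >= 0.8
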