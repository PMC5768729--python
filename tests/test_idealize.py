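"""State discovery, Viterbi/segmental-K-means idealization, outlier removal."""

import itertools
import math

import numpy as np
import pytest
from hmmlearn.hmm import GaussianHMM

import fretgate as fg
from fretgate.idealize import _log_emissions


def brute_force_path(obs, means, sigmas, pi, a):
    """Oracle: exhaustively score every K^T path; ties resolve to the
    lexicographically smallest path (paths enumerated in lex order)."""
    k, t = len(means), len(obs)
    paths = np.array(list(itertools.product(range(k), repeat=t)))
    with np.errstate(divide="ignore"):
        log_pi, log_a = np.log(pi), np.log(a)
    log_b = _log_emissions(np.asarray(obs, float), np.asarray(means, float), np.asarray(sigmas, float))
    scores = log_pi[paths[:, 0]] + log_b[0, paths[:, 0]]
    for i in range(1, t):
        scores = scores + log_a[paths[:, i - 1], paths[:, i]] + log_b[i, paths[:, i]]
    return paths[np.argmax(scores)] + 1


def random_instance(rng, k=None, t=None):
    k = k if k is not None else int(rng.integers(2, 4))
    t = t if t is not None else int(rng.integers(2, 11))
    means = np.sort(rng.uniform(0.1, 0.9, k))
    means += np.arange(k) * 1e-3  # keep strictly ascending
    sigmas = rng.uniform(0.03, 0.15, k)
    a = rng.uniform(0.05, 1.0, (k, k))
    a /= a.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.05, 1.0, k)
    pi /= pi.sum()
    obs = rng.uniform(0.0, 1.0, t)
    return obs, means, sigmas, pi, a


def fret_from_values(values, mol="m", dt=0.1):
    values = np.asarray(values, float)
    return fg.FretTrace(mol, dt, values, np.zeros(values.size, bool), fg.NO_BLEACH)


class TestViterbi:
    def test_matches_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            obs, means, sigmas, pi, a = random_instance(rng)
            got = fg.viterbi_path(obs, means, sigmas, pi, a)
            want = brute_force_path(obs, means, sigmas, pi, a)
            assert np.array_equal(got, want)

    def test_matches_hmmlearn_decoder(self):
        # independent cross-check against an established HMM implementation
        rng = np.random.default_rng(1)
        for _ in range(20):
            obs, means, sigmas, pi, a = random_instance(rng, t=50)
            k = means.size
            hmm = GaussianHMM(n_components=k, covariance_type="diag", init_params="")
            hmm.startprob_, hmm.transmat_ = pi, a
            hmm.means_ = means.reshape(-1, 1)
            hmm.covars_ = (sigmas**2).reshape(-1, 1)
            ref = hmm.predict(obs.reshape(-1, 1)) + 1
            assert np.array_equal(fg.viterbi_path(obs, means, sigmas, pi, a), ref)

    def test_equidistant_frame_assigned_to_lower_state(self):
        means = np.array([0.4, 0.8])
        sigmas = np.array([0.05, 0.05])
        uniform = np.full((2, 2), 0.5)
        path = fg.viterbi_path(np.array([0.6]), means, sigmas, np.array([0.5, 0.5]), uniform)
        assert path[0] == 1

    def test_permuting_states_permutes_labels_identically(self):
        rng = np.random.default_rng(3)
        obs, means, sigmas, pi, a = random_instance(rng, k=3, t=40)
        base = fg.viterbi_path(obs, means, sigmas, pi, a)
        perm = np.array([2, 0, 1])  # permuted state j carries original state perm[j]
        permuted = fg.viterbi_path(
            obs, means[perm], sigmas[perm], pi[perm], a[np.ix_(perm, perm)]
        )
        assert np.array_equal(perm[permuted - 1] + 1, base)


class TestSkm:
    def model_two_state(self):
        return fg.HmmModel(
            means=[0.47, 0.79],
            sigmas=[0.05, 0.05],
            initial_probs=[0.5, 0.5],
            transition_probs=[[0.9, 0.1], [0.1, 0.9]],
        )

    def test_noiseless_alternation_recovered_exactly(self):
        vals = np.array([0.47, 0.79] * 20)
        ideal = fg.skm_idealize(fret_from_values(vals), self.model_two_state())
        assert np.array_equal(ideal.labels, np.array([1, 2] * 20))

    def test_dark_frames_stay_unassigned(self):
        vals = np.array([0.47, 0.47, 0.0, 0.0, 0.79, 0.79])
        dark = np.array([False, False, True, True, False, False])
        trace = fg.FretTrace("m", 0.1, vals, dark, fg.NO_BLEACH)
        ideal = fg.skm_idealize(trace, self.model_two_state())
        assert np.array_equal(ideal.labels, np.array([1, 1, 0, 0, 2, 2]))

    def test_all_dark_trace_gives_empty_idealization(self):
        trace = fg.FretTrace("m", 0.1, np.zeros(10), np.ones(10, bool), fg.NO_BLEACH)
        ideal = fg.skm_idealize(trace, self.model_two_state())
        assert not ideal.assigned.any()

    def test_zero_cycles_equals_plain_viterbi(self):
        rng = np.random.default_rng(5)
        vals = np.clip(rng.normal(0.6, 0.2, 80), 0.01, 0.99)
        m = self.model_two_state()
        ideal = fg.skm_idealize(fret_from_values(vals), m, max_cycles=0)
        ref = fg.viterbi_path(vals, m.means, m.sigmas, m.initial_probs, m.transition_probs)
        assert np.array_equal(ideal.labels, ref)

    def test_label_accuracy_high_for_separated_states(self):
        # states 2+ effective s.d. apart: per-frame accuracy must exceed 95%
        cfg = fg.SimulationConfig(
            state_means=(0.47, 0.63, 0.79),
            state_sigmas=(0.04, 0.04, 0.04),
            transition_rates=fg.intracellular_site().transition_rates,
            background_sigma=5.0,
            blink_rate=0.0,
            bleach_lifetime=1e9,
            n_traces=20,
            n_frames=400,
            seed=8,
        )
        traces, truths = fg.simulate_dataset(cfg)
        model = fg.HmmModel(
            means=cfg.state_means,
            sigmas=cfg.state_sigmas,
            initial_probs=fg.stationary_distribution(cfg.rate_matrix()),
            transition_probs=fg.discretize_rates(cfg.rate_matrix(), cfg.frame_interval),
        )
        accs = []
        for trace, truth in zip(traces, truths):
            fret = fg.compute_fret(
                fg.correct_bleedthrough(trace, cfg.bleedthrough_fraction)
            )
            ideal = fg.skm_idealize(fret, model)
            m = ideal.assigned
            accs.append(np.mean(ideal.labels[m] == truth.state_path[m]))
        assert np.mean(accs) >= 0.95


class TestDiscoverModel:
    def test_single_state_data_selects_k_equal_one(self):
        rng = np.random.default_rng(0)
        traces = [
            fret_from_values(np.clip(rng.normal(0.7, 0.05, 200), 0.01, 0.99), mol=f"m{i}")
            for i in range(10)
        ]
        best, _ = fg.discover_model(traces, k_candidates=range(1, 4), seed=1, n_restarts=2)
        assert best.n_states == 1
        assert best.means[0] == pytest.approx(0.7, abs=0.01)

    def test_three_state_recovery_on_clean_synthetic_data(self):
        cfg = fg.SimulationConfig(
            state_means=(0.47, 0.63, 0.79),
            state_sigmas=(0.04, 0.04, 0.04),
            transition_rates=fg.intracellular_site().transition_rates,
            background_sigma=5.0,
            blink_rate=0.0,
            bleach_lifetime=1e9,
            n_traces=40,
            n_frames=300,
            seed=2,
        )
        traces, _ = fg.simulate_dataset(cfg)
        frets = [
            fg.compute_fret(fg.correct_bleedthrough(t, cfg.bleedthrough_fraction))
            for t in traces
        ]
        best, per_k = fg.discover_model(frets, k_candidates=range(1, 5), seed=3, n_restarts=3)
        assert best.n_states == 3
        assert best.means == pytest.approx([0.47, 0.63, 0.79], abs=0.02)
        assert per_k[3].evidence > per_k[2].evidence

    def test_em_objective_is_monotone_across_iterations(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0.4, 0.05, 500), rng.normal(0.8, 0.05, 500)])
        traces = [fret_from_values(np.clip(vals, 0.01, 0.99))]
        best, _ = fg.discover_model(traces, k_candidates=[2], seed=5, n_restarts=1)
        hist = np.asarray(best.loglik_history)
        # non-decreasing up to floating-point roundoff near the fixed point
        assert np.all(np.diff(hist) >= -1e-8 * np.abs(hist[:-1]))

    def test_convergence_rule_stops_at_tolerance(self):
        rng = np.random.default_rng(6)
        vals = np.clip(rng.normal(0.6, 0.08, 800), 0.01, 0.99)
        best, _ = fg.discover_model(
            [fret_from_values(vals)], k_candidates=[1], tol=1e-6, seed=7, n_restarts=1
        )
        hist = np.asarray(best.loglik_history)
        assert best.converged
        assert abs(hist[-1] - hist[-2]) < 1e-6
        # and every earlier step improved by at least the tolerance
        assert np.all(np.diff(hist[:-1]) >= 1e-6) or hist.size <= 2

    def test_no_bright_frames_is_an_error(self):
        trace = fg.FretTrace("m", 0.1, np.zeros(50), np.ones(50, bool), fg.NO_BLEACH)
        with pytest.raises(ValueError):
            fg.discover_model([trace], k_candidates=[1], seed=0)


class TestOutlierRemoval:
    def model(self):
        return fg.HmmModel(
            means=[0.4, 0.8],
            sigmas=[0.05, 0.05],
            initial_probs=[0.5, 0.5],
            transition_probs=[[0.9, 0.1], [0.1, 0.9]],
        )

    def test_on_model_trace_retained_and_offset_trace_removed(self):
        m = self.model()
        on = fret_from_values(np.array([0.4] * 20 + [0.8] * 20), mol="on")
        off = fret_from_values(np.array([0.5] * 20 + [0.9] * 20), mol="off")  # +2 sigma
        ideals = [fg.skm_idealize(t, m, max_cycles=0) for t in (on, off)]
        kept_t, kept_i = fg.remove_outlier_traces([on, off], ideals, m, threshold=1.0)
        assert [t.molecule_id for t in kept_t] == ["on"]
        assert len(kept_i) == 1

    def test_empty_input_gives_empty_output(self):
        kept_t, kept_i = fg.remove_outlier_traces([], [], self.model())
        assert kept_t == [] and kept_i == []
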