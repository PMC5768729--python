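"""Dwells, occupancy, transition density, histogram mixtures, Hill fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fretgate as fg
from fretgate.kinetics import extract_dwells


def ideal_from_labels(labels, mol="m"):
    model = fg.HmmModel(
        means=[0.4, 0.6, 0.8][: max(max(labels), 2)],
        sigmas=[0.05] * max(max(labels), 2),
        initial_probs=np.full(max(max(labels), 2), 1.0 / max(max(labels), 2)),
        transition_probs=np.full(
            (max(max(labels), 2), max(max(labels), 2)), 1.0 / max(max(labels), 2)
        ),
    )
    return fg.Idealization(mol, np.asarray(labels, int), model)


class TestExtractDwells:
    def test_short_trace_example(self):
        d = extract_dwells(ideal_from_labels([1, 1, 2]), 0.1)
        assert len(d) == 2
        assert (d[0].state, d[0].n_frames, d[0].censored) == (1, 2, True)
        assert d[0].duration == pytest.approx(0.2)
        assert (d[1].state, d[1].duration, d[1].censored) == (2, pytest.approx(0.1), True)

    def test_durations_conserve_assigned_time(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 4, 500)
        labels[rng.random(500) < 0.1] = 0
        d = extract_dwells(ideal_from_labels(labels), 0.1)
        assert sum(x.duration for x in d) == pytest.approx(np.sum(labels > 0) * 0.1)

    def test_single_run_is_fully_censored(self):
        d = extract_dwells(ideal_from_labels([2, 2, 2]), 0.1)
        assert len(d) == 1 and d[0].censored

    def test_dark_gap_splits_and_censors_dwells(self):
        d = extract_dwells(ideal_from_labels([1, 1, 0, 1, 1, 2, 2]), 0.1)
        assert [x.n_frames for x in d] == [2, 2, 2]
        assert [x.censored for x in d] == [True, True, True]
        # middle dwell of an uninterrupted run is not censored
        d2 = extract_dwells(ideal_from_labels([1, 2, 2, 1]), 0.1)
        assert [x.censored for x in d2] == [True, False, True]


class TestOccupancy:
    def test_fractions_from_labels(self):
        occ = fg.occupancy([ideal_from_labels([1, 1, 2, 3])], 0.1, n_states=3)
        assert occ.fractions == pytest.approx([0.5, 0.25, 0.25])

    def test_mean_dwell_averages_uncensored_only(self):
        # state 2 has uncensored dwells of 0.2 s and 0.4 s bracketed by state 1
        labels = [1, 2, 2, 1, 2, 2, 2, 2, 1]
        occ = fg.occupancy([ideal_from_labels(labels)], 0.1, n_states=2)
        assert occ.mean_dwell_times[1] == pytest.approx(0.3)
        # state 1's dwells all touch an edge -> undefined sentinel unless interior
        labels2 = [1, 1, 1]
        occ2 = fg.occupancy([ideal_from_labels(labels2)], 0.1, n_states=2)
        assert math.isnan(occ2.mean_dwell_times[0])
        assert math.isnan(occ2.mean_dwell_times[1])

    def test_dwell_estimator_matches_discretized_chain(self):
        # two-state chain observed at frames: dwell lengths are geometric with
        # the discretized stay probability (1 + exp(-2 k dt)) / 2, which
        # accounts for within-frame leave-and-return; closed form is the oracle
        k_exit, dt = 1.0, 0.1
        q = np.array([[0.0, k_exit], [k_exit, 0.0]])
        p = fg.discretize_rates(q, dt)
        stay = (1.0 + math.exp(-2.0 * k_exit * dt)) / 2.0
        assert p[0, 0] == pytest.approx(stay)
        true_mean = dt / (1.0 - stay)
        path = fg.simulate_state_path(p, 60_000, 9)
        occ = fg.occupancy([ideal_from_labels(path)], dt, n_states=2)
        dwells = [
            d for d in extract_dwells(ideal_from_labels(path), dt) if not d.censored
        ]
        n = len(dwells)
        assert n > 1000
        se = np.std([d.duration for d in dwells], ddof=1) / math.sqrt(n)
        assert abs(np.nanmean(occ.mean_dwell_times) - true_mean) < 2 * se

    def test_transition_rate_counts_per_assigned_second(self):
        labels = [1, 1, 2, 2, 1, 1, 1, 1, 2, 2]  # 3 transitions, 1 s assigned
        occ = fg.occupancy([ideal_from_labels(labels)], 0.1, n_states=2)
        assert occ.n_transitions == 3
        assert occ.mean_transition_rate == pytest.approx(3.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=5, max_size=200))
    def test_fractions_always_sum_to_one(self, labels):
        if not any(x > 0 for x in labels):
            return
        occ = fg.occupancy([ideal_from_labels(labels)], 0.1, n_states=3)
        assert occ.fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestTransitionDensity:
    def fret_trace(self, vals, mol="m"):
        vals = np.asarray(vals, float)
        return fg.FretTrace(mol, 0.1, vals, np.zeros(vals.size, bool), fg.NO_BLEACH)

    def test_single_transition_lands_in_correct_bin(self):
        vals = [0.5] * 5 + [0.8] * 5
        ideal = ideal_from_labels([1] * 5 + [2] * 5)
        tdp = fg.transition_density([ideal], [self.fret_trace(vals)], n_bins=50)
        assert tdp.n_transitions == 1
        ix, iy = np.nonzero(tdp.density)
        assert (ix[0], iy[0]) == (25, 40)  # bin containing (0.5, 0.8)

    def test_integrated_density_equals_transition_count(self):
        rng = np.random.default_rng(2)
        ideals, traces = [], []
        for i in range(5):
            labels = rng.integers(1, 4, 200)
            vals = np.array([0.4, 0.6, 0.8])[labels - 1] + rng.normal(0, 0.03, 200)
            ideals.append(ideal_from_labels(labels, mol=f"m{i}"))
            traces.append(self.fret_trace(np.clip(vals, 0.01, 0.99), mol=f"m{i}"))
        tdp = fg.transition_density(ideals, traces)
        total_from_occ = sum(
            fg.occupancy([i], 0.1, n_states=3).n_transitions for i in ideals
        )
        assert tdp.n_transitions == total_from_occ
        assert tdp.density.sum() * tdp.total_assigned_time == pytest.approx(
            tdp.n_transitions
        )

    def test_single_molecule_rate_normalization(self):
        vals = [0.5, 0.8, 0.5, 0.8, 0.5]  # 4 transitions over 0.5 s assigned
        ideal = ideal_from_labels([1, 2, 1, 2, 1])
        tdp = fg.transition_density([ideal], [self.fret_trace(vals)])
        assert tdp.density.sum() == pytest.approx(4 / 0.5)


class TestFitHistogram:
    def gaussian_traces(self, means, weights, n=4000, sigma=0.05, seed=0):
        rng = np.random.default_rng(seed)
        comps = rng.choice(len(means), size=n, p=weights)
        vals = np.clip(np.asarray(means)[comps] + rng.normal(0, sigma, n), 0.01, 0.99)
        return [fg.FretTrace("m", 0.1, vals, np.zeros(n, bool), fg.NO_BLEACH)]

    def test_single_state_recovered(self):
        fit = fg.fit_histogram(self.gaussian_traces([0.7], [1.0]), 1)
        assert fit.means[0] == pytest.approx(0.70, abs=0.01)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_three_state_means_recovered(self):
        fit = fg.fit_histogram(
            self.gaussian_traces([0.55, 0.67, 0.79], [0.5, 0.25, 0.25], n=12000), 3
        )
        assert fit.means == pytest.approx([0.55, 0.67, 0.79], abs=0.02)
        assert fit.weights.sum() == pytest.approx(1.0)
        # the summed model curve integrates to ~1 over the support
        x = np.linspace(0, 1, 2001)
        assert np.trapezoid(fit.model_curve(x), x) == pytest.approx(1.0, abs=0.01)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fg.fit_histogram(self.gaussian_traces([0.7], [1.0], n=50), 1)


class TestFitHill:
    def test_noiseless_recovery_within_one_percent(self):
        conc = np.array([0.0, 5.0, 15.0, 35.0, 55.0, 90.0, 150.0, 300.0])
        truth = 0.65 - 0.45 * conc**2 / (conc**2 + 55.0**2)
        fit = fg.fit_hill(conc, truth, hill_n=2.0)
        assert fit.ec50 == pytest.approx(55.0, rel=0.01)
        assert fit.r0 == pytest.approx(0.65, abs=1e-6)
        assert fit.r_inf == pytest.approx(0.20, abs=1e-6)
        assert fit.floor <= fit.ceiling

    def test_response_scaling_leaves_ec50_unchanged(self):
        conc = np.array([0.0, 10.0, 30.0, 55.0, 100.0, 300.0])
        resp = 0.1 + 0.5 * conc / (conc + 55.0)
        e1 = fg.fit_hill(conc, resp, hill_n=1.0).ec50
        e2 = fg.fit_hill(conc, 3.7 * resp, hill_n=1.0).ec50
        assert e2 == pytest.approx(e1, rel=1e-6)

    def test_flat_response_rejected(self):
        conc = np.array([0.0, 10.0, 100.0, 1000.0])
        with pytest.raises(ValueError):
            fg.fit_hill(conc, np.full(4, 0.3), hill_n=2.0)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fg.fit_hill([0.0, 1.0, 10.0], [0.1, 0.2, 0.3], hill_n=1.0)
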