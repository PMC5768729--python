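"""FRET state discovery and trace idealization.

Model discovery fits Gaussian-emission hidden Markov models to the pooled
(dark-state-truncated) FRET traces by expectation-maximization, stopping
when the objective improves by less than a convergence tolerance (default
1e-6 nats), and selects the number of states K by the Bayesian information
criterion — a penalized-likelihood surrogate for evidence-based selection.
Individual traces are then idealized with the segmental K-means algorithm:
Viterbi assignment under the shared model, optionally alternating with
bounded per-trace parameter re-estimation until the state path is stable.

Dark frames (donor blinking, post-bleach) are never assigned a state; a dark
gap restarts the Markov chain, so dwells are conservatively split at gaps.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM

from .preprocess import FretTrace

UNASSIGNED = 0  # label for dark frames; states are 1..K


@dataclass
class HmmModel:
    """Gaussian-emission HMM over FRET efficiency, states sorted by mean."""

    means: np.ndarray
    sigmas: np.ndarray
    initial_probs: np.ndarray
    transition_probs: np.ndarray
    log_likelihood: float = math.nan
    bic: float = math.nan
    converged: bool = True
    n_iter: int = 0
    loglik_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        k = self.means.size
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("state means must be strictly ascending")
        if np.any(self.sigmas <= 0):
            raise ValueError("state sigmas must be positive")
        if self.transition_probs.shape != (k, k) or not np.allclose(
            self.transition_probs.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("transition_probs must be K x K row-stochastic")
        if self.initial_probs.shape != (k,) or not math.isclose(
            self.initial_probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("initial_probs must sum to 1")

    @property
    def n_states(self) -> int:
        return self.means.size

    @property
    def evidence(self) -> float:
        """BIC-based log-evidence surrogate (nats), higher is better."""
        return -0.5 * self.bic

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "means": self.means.tolist(),
                "sigmas": self.sigmas.tolist(),
                "initial_probs": self.initial_probs.tolist(),
                "transition_probs": self.transition_probs.tolist(),
                "log_likelihood": self.log_likelihood,
                "bic": self.bic,
                "converged": self.converged,
                "n_iter": self.n_iter,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "HmmModel":
        d = json.loads(text)
        return cls(
            means=d["means"],
            sigmas=d["sigmas"],
            initial_probs=d["initial_probs"],
            transition_probs=d["transition_probs"],
            log_likelihood=d.get("log_likelihood", math.nan),
            bic=d.get("bic", math.nan),
            converged=d.get("converged", True),
            n_iter=d.get("n_iter", 0),
        )


@dataclass
class Idealization:
    """Per-frame state labels for one trace (0 = dark/unassigned)."""

    molecule_id: str
    labels: np.ndarray
    model: HmmModel = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def assigned(self) -> np.ndarray:
        return self.labels > 0


def bright_segments(trace: FretTrace) -> list[tuple[int, int]]:
    """Half-open index ranges of the maximal non-dark runs of a trace."""
    segs: list[tuple[int, int]] = []
    ok = ~trace.dark
    i = 0
    n = ok.size
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


# ---------------------------------------------------------------------------
# model discovery (EM over K candidates, BIC selection)
# ---------------------------------------------------------------------------


class _RecordingMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full per-iteration objective."""

    def __init__(self, tol: float, n_iter: int) -> None:
        super().__init__(tol, n_iter, verbose=False)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(log_prob)
        super().report(log_prob)


def _sorted_model(hmm: GaussianHMM, monitor: _RecordingMonitor, n_obs: int) -> HmmModel:
    means = hmm.means_.ravel()
    order = np.argsort(means)
    k = means.size
    sigmas = np.sqrt(hmm.covars_.reshape(k, -1)[:, 0])
    ll = monitor.full_history[-1]
    n_par = (k - 1) + k * (k - 1) + 2 * k
    bic = -2.0 * ll + n_par * math.log(n_obs)
    return HmmModel(
        means=means[order],
        sigmas=np.maximum(sigmas[order], 1e-4),
        initial_probs=hmm.startprob_[order],
        transition_probs=hmm.transmat_[np.ix_(order, order)],
        log_likelihood=float(ll),
        bic=float(bic),
        converged=bool(monitor.converged),
        n_iter=len(monitor.full_history),
        loglik_history=list(monitor.full_history),
    )


def _fit_k(
    x: np.ndarray,
    lengths: list[int],
    k: int,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    n_restarts: int,
) -> HmmModel:
    pooled_sd = max(float(x.std()), 1e-3)
    quantiles = np.quantile(x, (np.arange(k) + 0.5) / k)
    best: HmmModel | None = None
    for r in range(n_restarts):
        means0 = quantiles.copy()
        if r > 0:
            means0 = means0 + rng.normal(0.0, pooled_sd / 2.0, k)
        means0 = np.sort(means0)
        # keep initial means distinct
        for i in range(1, k):
            means0[i] = max(means0[i], means0[i - 1] + 1e-4)
        hmm = GaussianHMM(
            n_components=k,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            init_params="",
            params="stmc",
            min_covar=1e-6,
        )
        hmm.startprob_ = np.full(k, 1.0 / k)
        hmm.transmat_ = np.full((k, k), 1.0 / k)
        hmm.means_ = means0.reshape(-1, 1)
        hmm.covars_ = np.full((k, 1), (pooled_sd / max(k, 1)) ** 2)
        monitor = _RecordingMonitor(tol, max_iter)
        hmm.monitor_ = monitor
        hmm_log = logging.getLogger("hmmlearn.base")
        level = hmm_log.level
        hmm_log.setLevel(logging.ERROR)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hmm.fit(x.reshape(-1, 1), lengths)
        except ValueError:
            continue
        finally:
            hmm_log.setLevel(level)
        if np.any(np.diff(np.sort(hmm.means_.ravel())) <= 0):
            continue
        model = _sorted_model(hmm, monitor, x.size)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise RuntimeError(f"all EM restarts failed for K={k}")
    return best


def discover_model(
    traces: Sequence[FretTrace],
    k_candidates: Iterable[int] = range(1, 6),
    tol: float = 1e-6,
    seed: int = 0,
    max_traces: int = 1500,
    n_restarts: int = 5,
    max_iter: int = 100,
) -> tuple[HmmModel, dict[int, HmmModel]]:
    """Discover the number and parameters of FRET states across traces.

    Traces are truncated to their non-dark stretches and pooled (a deterministic
    seed-driven subsample of at most ``max_traces`` molecules keeps runtime
    bounded).  For each candidate K a Gaussian HMM is fit by EM with
    ``n_restarts`` seeded initializations, iterating until the log-likelihood
    improves by less than ``tol``; the best K by BIC wins.

    Returns the selected model and the per-K model dictionary.
    """
    if len(traces) == 0:
        raise ValueError("at least one trace is required")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(traces))
    if len(traces) > max_traces:
        idx = np.sort(rng.choice(idx, size=max_traces, replace=False))

    chunks: list[np.ndarray] = []
    lengths: list[int] = []
    for i in idx:
        for a, b in bright_segments(traces[i]):
            chunks.append(traces[i].efret[a:b])
            lengths.append(b - a)
    if not chunks:
        raise ValueError("no non-dark frames available for model discovery")
    x = np.concatenate(chunks)

    per_k: dict[int, HmmModel] = {}
    for k in k_candidates:
        if x.size <= 2 * k:
            continue
        per_k[k] = _fit_k(x, lengths, k, tol, max_iter, rng, n_restarts)
    if not per_k:
        raise ValueError("no candidate K could be fit")
    best_k = min(per_k, key=lambda k: per_k[k].bic)
    if not per_k[best_k].converged:
        warnings.warn(
            f"EM for K={best_k} did not converge within {max_iter} iterations; "
            "returning best-so-far parameters",
            RuntimeWarning,
        )
    return per_k[best_k], per_k


# ---------------------------------------------------------------------------
# Viterbi / segmental K-means idealization
# ---------------------------------------------------------------------------


def _log_emissions(obs: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    z = (obs[:, None] - means[None, :]) / sigmas[None, :]
    return -0.5 * z * z - np.log(sigmas[None, :]) - 0.5 * math.log(2.0 * math.pi)


def viterbi_path(
    obs: np.ndarray,
    means: np.ndarray,
    sigmas: np.ndarray,
    initial_probs: np.ndarray,
    transition_probs: np.ndarray,
) -> np.ndarray:
    """Most likely state path (1-based labels) under a Gaussian-emission HMM.

    Computed in log space; ties are broken toward the lower state index.
    """
    obs = np.asarray(obs, dtype=float)
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(initial_probs, dtype=float))
        log_a = np.log(np.asarray(transition_probs, dtype=float))
    log_b = _log_emissions(obs, means, sigmas)
    n, k = log_b.shape
    delta = log_pi + log_b[0]
    psi = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + log_a
        psi[t] = np.argmax(scores, axis=0)  # argmax -> lowest index on ties
        delta = scores[psi[t], np.arange(k)] + log_b[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path + 1


def _viterbi_model(obs: np.ndarray, model: HmmModel) -> np.ndarray:
    return viterbi_path(
        obs, model.means, model.sigmas, model.initial_probs, model.transition_probs
    )


def skm_idealize(
    trace: FretTrace, model: HmmModel, max_cycles: int = 20
) -> Idealization:
    """Idealize one trace with the segmental K-means algorithm.

    Each non-dark segment is assigned its Viterbi path under the model; the
    per-trace emission means/widths and transition frequencies are then
    re-estimated from the assignment and the two steps alternate until the
    path no longer changes (at most ``max_cycles`` cycles; ``max_cycles=0``
    gives the plain Viterbi assignment under the shared model).  States the
    trace never visits keep the shared-model parameters.  Dark frames stay
    unassigned.
    """
    labels = np.full(trace.n_frames, UNASSIGNED, dtype=np.int64)
    segs = bright_segments(trace)
    if not segs:
        return Idealization(trace.molecule_id, labels, model)

    means = model.means.copy()
    sigmas = model.sigmas.copy()
    trans = model.transition_probs.copy()
    k = model.n_states

    def assign() -> np.ndarray:
        out = np.full(trace.n_frames, UNASSIGNED, dtype=np.int64)
        for a, b in segs:
            out[a:b] = viterbi_path(
                trace.efret[a:b], means, sigmas, model.initial_probs, trans
            )
        return out

    labels = assign()
    for _ in range(max_cycles):
        # per-trace re-estimation from the current assignment
        new_means, new_sigmas = means.copy(), sigmas.copy()
        for s in range(1, k + 1):
            vals = trace.efret[labels == s]
            if vals.size >= 2:
                new_means[s - 1] = vals.mean()
                new_sigmas[s - 1] = max(vals.std(ddof=1), 1e-3)
        if np.any(np.diff(new_means) <= 0):
            new_means, new_sigmas = means, sigmas  # keep ordering identifiable
        counts = np.zeros((k, k))
        for a, b in segs:
            seg = labels[a:b]
            for u, v in zip(seg[:-1], seg[1:]):
                counts[u - 1, v - 1] += 1
        new_trans = trans.copy()
        rows = counts.sum(axis=1)
        nz = rows > 0
        new_trans[nz] = counts[nz] / rows[nz, None]
        new_trans = np.clip(new_trans, 1e-12, None)
        new_trans /= new_trans.sum(axis=1, keepdims=True)

        means, sigmas, trans = new_means, new_sigmas, new_trans
        new_labels = assign()
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return Idealization(trace.molecule_id, labels, model)


def idealize_dataset(
    traces: Sequence[FretTrace], model: HmmModel, max_cycles: int = 20
) -> list[Idealization]:
    return [skm_idealize(t, model, max_cycles=max_cycles) for t in traces]


def remove_outlier_traces(
    traces: Sequence[FretTrace],
    idealizations: Sequence[Idealization],
    model: HmmModel,
    threshold: float = 1.0,
) -> tuple[list[FretTrace], list[Idealization]]:
    """Drop traces whose FRET values sit far from the model state values.

    A trace is removed when the mean absolute deviation of its assigned
    frames from the corresponding state means, in units of the state widths,
    exceeds ``threshold`` (default one standard deviation).  Traces with no
    assigned frames are retained.
    """
    kept_t: list[FretTrace] = []
    kept_i: list[Idealization] = []
    for trace, ideal in zip(traces, idealizations):
        mask = ideal.assigned
        if not mask.any():
            kept_t.append(trace)
            kept_i.append(ideal)
            continue
        s = ideal.labels[mask] - 1
        dev = np.abs(trace.efret[mask] - model.means[s]) / model.sigmas[s]
        if float(dev.mean()) <= threshold:
            kept_t.append(trace)
            kept_i.append(ideal)
    return kept_t, kept_i
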