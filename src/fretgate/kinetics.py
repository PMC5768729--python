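"""Descriptive and kinetic statistics of idealized FRET traces.

Dwell extraction, state occupancies and mean dwell times, transition density
plots (2-D histograms of FRET before vs. after each transition, on a
transitions-per-molecule-per-second scale), Gaussian-mixture fits of pooled
FRET histograms, and Hill dose-response fits with a fixed Hill coefficient.

Censoring convention: a dwell that touches the start or end of a trace, or
abuts a dark gap (blink or photobleach), has an unknown true duration and is
flagged censored.  Mean dwell times average uncensored dwells only, while
occupancy fractions pool all assigned frames — censoring biases dwell means
but not time fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .idealize import Idealization
from .preprocess import FretTrace


@dataclass
class Dwell:
    molecule_id: str
    state: int
    start_frame: int
    n_frames: int
    duration: float  # seconds
    censored: bool


@dataclass
class OccupancySummary:
    """Time-fraction and dwell-time summary over a dataset."""

    states: np.ndarray
    fractions: np.ndarray           # fraction of assigned time per state
    mean_dwell_times: np.ndarray    # seconds, NaN where no uncensored dwell
    n_molecules: int
    n_transitions: int
    total_assigned_time: float      # seconds
    mean_transition_rate: float     # transitions per second of assigned time


@dataclass
class TransitionDensity:
    """Rate-normalized 2-D histogram of (FRET before, FRET after)."""

    bin_edges: np.ndarray           # shared edges for both axes
    density: np.ndarray             # transitions per molecule per second
    n_transitions: int
    n_molecules: int
    total_assigned_time: float


@dataclass
class HistogramFit:
    """Pooled FRET histogram with a per-state Gaussian mixture fit."""

    bin_edges: np.ndarray
    counts: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray

    def model_curve(self, x: np.ndarray) -> np.ndarray:
        """Summed mixture density evaluated at ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sigmas):
            out += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        return out


@dataclass
class DoseResponseFit:
    """Hill-law fit ``r(c) = r0 + (r_inf - r0) * c^n / (c^n + EC50^n)``."""

    concentrations: np.ndarray
    responses: np.ndarray
    hill_n: float
    ec50: float
    r0: float       # zero-dose asymptote
    r_inf: float    # saturating asymptote
    residual_norm: float

    @property
    def floor(self) -> float:
        return min(self.r0, self.r_inf)

    @property
    def ceiling(self) -> float:
        return max(self.r0, self.r_inf)

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        h = c**self.hill_n / (c**self.hill_n + self.ec50**self.hill_n)
        return self.r0 + (self.r_inf - self.r0) * h


# ---------------------------------------------------------------------------
# dwells and occupancy
# ---------------------------------------------------------------------------

def extract_dwells(ideal: Idealization, frame_interval: float) -> list[Dwell]:
    """Maximal runs of identical state labels, with censoring flags.

    Runs bordering the trace start/end or an unassigned (dark) frame are
    censored; duration is run length times the frame interval.
    """
    labels = ideal.labels
    n = labels.size
    dwells: list[Dwell] = []
    i = 0
    while i < n:
        if labels[i] == 0:
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        censored = (i == 0) or (j == n) or labels[i - 1] == 0 or labels[j] == 0
        dwells.append(
            Dwell(
                molecule_id=ideal.molecule_id,
                state=int(labels[i]),
                start_frame=i,
                n_frames=j - i,
                duration=(j - i) * frame_interval,
                censored=bool(censored),
            )
        )
        i = j
    return dwells


def _count_transitions(ideal: Idealization) -> int:
    """State changes within contiguous assigned stretches (gaps do not count)."""
    lab = ideal.labels
    prev = lab[:-1]
    nxt = lab[1:]
    return int(np.sum((prev > 0) & (nxt > 0) & (prev != nxt)))


def occupancy(
    idealizations: Sequence[Idealization],
    frame_interval: float,
    n_states: int | None = None,
) -> OccupancySummary:
    """State occupancies, mean dwell times and overall transition rate.

    Occupancy pools all assigned frames across molecules; mean dwell times
    use uncensored dwells only (NaN sentinel for states with none).
    """
    if n_states is None:
        n_states = max((int(i.labels.max()) for i in idealizations), default=0)
    counts = np.zeros(n_states, dtype=float)
    dwell_sums = np.zeros(n_states, dtype=float)
    dwell_ns = np.zeros(n_states, dtype=int)
    n_trans = 0
    for ideal in idealizations:
        for s in range(1, n_states + 1):
            counts[s - 1] += np.sum(ideal.labels == s)
        for d in extract_dwells(ideal, frame_interval):
            if not d.censored:
                dwell_sums[d.state - 1] += d.duration
                dwell_ns[d.state - 1] += 1
        n_trans += _count_transitions(ideal)
    total = counts.sum()
    if total == 0:
        raise ValueError("no assigned frames")
    mean_dwells = np.full(n_states, math.nan)
    nz = dwell_ns > 0
    mean_dwells[nz] = dwell_sums[nz] / dwell_ns[nz]
    total_time = total * frame_interval
    return OccupancySummary(
        states=np.arange(1, n_states + 1),
        fractions=counts / total,
        mean_dwell_times=mean_dwells,
        n_molecules=len(idealizations),
        n_transitions=n_trans,
        total_assigned_time=total_time,
        mean_transition_rate=n_trans / total_time,
    )


# ---------------------------------------------------------------------------
# transition density plots
# ---------------------------------------------------------------------------

def transition_density(
    idealizations: Sequence[Idealization],
    traces: Sequence[FretTrace],
    n_bins: int = 50,
) -> TransitionDensity:
    """2-D histogram of observed mean FRET in the dwell before vs. after
    each transition, normalized to transitions per molecule per second of
    assigned time."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist = np.zeros((n_bins, n_bins), dtype=float)
    n_trans = 0
    total_frames = 0
    dt = None
    for ideal, trace in zip(idealizations, traces):
        dt = trace.frame_interval
        total_frames += int(np.sum(ideal.assigned))
        dwells = extract_dwells(ideal, trace.frame_interval)
        for d1, d2 in zip(dwells[:-1], dwells[1:]):
            # consecutive dwells separated by a dark gap are not a transition
            if d1.start_frame + d1.n_frames != d2.start_frame:
                continue
            e_before = float(trace.efret[d1.start_frame : d1.start_frame + d1.n_frames].mean())
            e_after = float(trace.efret[d2.start_frame : d2.start_frame + d2.n_frames].mean())
            ix = min(max(np.searchsorted(edges, e_before, side="right") - 1, 0), n_bins - 1)
            iy = min(max(np.searchsorted(edges, e_after, side="right") - 1, 0), n_bins - 1)
            hist[ix, iy] += 1.0
            n_trans += 1
    total_time = total_frames * (dt if dt is not None else math.nan)
    density = hist / total_time if total_time and total_time > 0 else hist
    return TransitionDensity(
        bin_edges=edges,
        density=density,
        n_transitions=n_trans,
        n_molecules=len(idealizations),
        total_assigned_time=float(total_time),
    )


# ---------------------------------------------------------------------------
# histogram + mixture fit
# ---------------------------------------------------------------------------

def fit_histogram(
    traces: Sequence[FretTrace],
    n_states: int,
    bin_width: float = 0.02,
    seed: int = 0,
) -> HistogramFit:
    """Pooled FRET histogram fitted with one Gaussian per state.

    Pools all non-dark efficiency values, bins them at ``bin_width`` over
    [0, 1], and fits an ``n_states``-component Gaussian mixture by EM,
    components sorted by mean.
    """
    pooled = np.concatenate([t.efret[~t.dark] for t in traces]) if traces else np.array([])
    if pooled.size < 100:
        raise ValueError("need at least 100 pooled FRET values")
    if pooled.size <= 3 * n_states:
        raise ValueError("fewer values than mixture parameters")
    gmm = GaussianMixture(
        n_components=n_states, covariance_type="diag", n_init=3, random_state=seed
    )
    gmm.fit(pooled.reshape(-1, 1))
    order = np.argsort(gmm.means_.ravel())
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(pooled, bins=edges)
    return HistogramFit(
        bin_edges=edges,
        counts=counts,
        means=gmm.means_.ravel()[order],
        sigmas=np.sqrt(gmm.covariances_.reshape(n_states, -1)[:, 0])[order],
        weights=gmm.weights_[order],
    )


# ---------------------------------------------------------------------------
# dose-response fitting
# ---------------------------------------------------------------------------

def fit_hill(
    concentrations: Sequence[float],
    responses: Sequence[float],
    hill_n: float,
) -> DoseResponseFit:
    """Least-squares Hill fit with the Hill coefficient fixed.

    Fits ``r(c) = r0 + (r_inf - r0) * c^n / (c^n + EC50^n)`` with EC50 and
    the two asymptotes free.  Requires at least 4 distinct concentrations
    and a non-flat response.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    span = float(r.max() - r.min())
    if span < 1e-12 * max(1.0, float(np.abs(r).max())):
        raise ValueError("flat response: EC50 is unidentifiable")

    def model(cc, ec50, r0, r_inf):
        h = cc**hill_n / (cc**hill_n + ec50**hill_n)
        return r0 + (r_inf - r0) * h

    pos = c[c > 0]
    ec50_0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    p0 = (ec50_0, float(r[np.argmin(c)]), float(r[np.argmax(c)]))
    popt, _ = curve_fit(
        model,
        c,
        r,
        p0=p0,
        bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = r - model(c, *popt)
    return DoseResponseFit(
        concentrations=c,
        responses=r,
        hill_n=float(hill_n),
        ec50=float(popt[0]),
        r0=float(popt[1]),
        r_inf=float(popt[2]),
        residual_norm=float(np.linalg.norm(resid)),
    )
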