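"""Synthetic smFRET trace generation with known ground truth.

Emulates the statistical structure of camera-based single-molecule FRET
recordings of a membrane transporter labeled on one face: a small number of
Gaussian FRET states interconverting as a continuous-time Markov chain,
observed at a fixed frame interval through two noisy photon-counting
channels, with single-step donor photobleaching, transient donor blinking,
and donor-to-acceptor spectral bleed-through.

Every random draw is controlled by a seed so that a (config, seed) pair
produces a byte-identical dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm


@dataclass(frozen=True)
class SimulationConfig:
    """Generating model for one simulated dataset.

    Parameters
    ----------
    state_means : sequence of float
        FRET efficiency of each conformational state, strictly increasing,
        all within (0, 1).
    state_sigmas : sequence of float
        Width (s.d., FRET units) of the per-state efficiency distribution.
    transition_rates : array (K, K)
        Continuous-time rate matrix in 1/s; off-diagonal entries are the
        state-to-state rates (non-negative), the diagonal is ignored and
        recomputed as minus the row sum.
    frame_interval : float
        Camera integration time in seconds (0.1 s = 100 ms resolution).
    total_intensity : float
        Mean summed donor+acceptor photon count per live frame.
    background_sigma : float
        Additive Gaussian background noise s.d. per channel (photons/frame).
    shot_noise_scale : float
        Extra per-channel noise with s.d. ``scale * sqrt(expected counts)``,
        emulating photon statistics and camera gain; 0 disables it.
    bleedthrough_fraction : float
        Fraction of donor photons leaking into the acceptor channel.
    bleach_lifetime : float
        Mean of the exponential donor photobleaching time, seconds.
    blink_rate : float
        Rate of donor blinking events (1/s) before photobleaching.
    blink_duration_mean : float
        Mean of the exponential blink duration, seconds.
    n_traces, n_frames : int
        Dataset dimensions.
    seed : int
        Master seed; per-trace streams are spawned from it.
    """

    state_means: tuple[float, ...] = (0.47, 0.63, 0.79)
    state_sigmas: tuple[float, ...] = (0.06, 0.06, 0.06)
    transition_rates: tuple[tuple[float, ...], ...] = (
        (0.0, 0.0635, 0.0317),
        (0.3077, 0.0, 0.1538),
        (0.0833, 0.0833, 0.0),
    )
    frame_interval: float = 0.1
    total_intensity: float = 500.0
    background_sigma: float = 12.0
    shot_noise_scale: float = 0.0
    bleedthrough_fraction: float = 0.165
    bleach_lifetime: float = 100.0
    blink_rate: float = 0.01
    blink_duration_mean: float = 0.4
    n_traces: int = 100
    n_frames: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means, dtype=float)
        sigmas = np.asarray(self.state_sigmas, dtype=float)
        if means.ndim != 1 or means.size == 0:
            raise ValueError("state_means must be a non-empty 1-D sequence")
        if np.any(np.diff(means) <= 0):
            raise ValueError("state_means must be strictly increasing")
        if np.any(means <= 0) or np.any(means >= 1):
            raise ValueError("state_means must lie in (0, 1)")
        if sigmas.shape != means.shape or np.any(sigmas <= 0):
            raise ValueError("state_sigmas must be positive, one per state")
        q = np.asarray(self.transition_rates, dtype=float)
        if q.shape != (means.size, means.size):
            raise ValueError("transition_rates must be K x K")
        off = q[~np.eye(means.size, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for name in ("total_intensity", "bleach_lifetime"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("background_sigma", "shot_noise_scale", "blink_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.bleedthrough_fraction < 1:
            raise ValueError("bleedthrough_fraction must be in [0, 1)")
        if self.n_traces <= 0 or self.n_frames <= 0:
            raise ValueError("n_traces and n_frames must be positive")

    @property
    def n_states(self) -> int:
        return len(self.state_means)

    def rate_matrix(self) -> np.ndarray:
        """Rate matrix with the diagonal set to minus the row sums."""
        q = np.asarray(self.transition_rates, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class LigandModulation:
    """Hill-law modulation of selected kinetic rates by a ligand.

    Each entry of ``affected_rates`` is ``(from_state, to_state, multiplier)``
    with 0-based state indices.  At concentration ``c`` the affected rate is
    scaled by ``1 + (multiplier - 1) * c**n / (c**n + ec50**n)``, so it moves
    from its base value at zero dose to ``base * multiplier`` at saturation.
    """

    ligand_name: str
    ec50: float
    hill_n: float
    affected_rates: tuple[tuple[int, int, float], ...]
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        for i, j, mult in self.affected_rates:
            if i == j:
                raise ValueError("affected_rates must be off-diagonal entries")
            if mult <= 0:
                raise ValueError("rate multipliers must be positive")


@dataclass
class IntensityTrace:
    """Paired donor/acceptor photon-count series for one molecule."""

    molecule_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be equal-length 1-D series")
        if self.donor.size < 1:
            raise ValueError("trace must contain at least one frame")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Generating truth for one simulated trace (1-based state labels)."""

    molecule_id: str
    state_path: np.ndarray
    bleach_frame: int
    blink_intervals: list[tuple[int, int]]
    config: SimulationConfig = field(repr=False)


def hill_fraction(conc, ec50: float, hill_n: float):
    """Fractional occupancy ``c**n / (c**n + ec50**n)`` of the Hill law."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(over="ignore"):
        cn = np.power(c, hill_n)
        return cn / (cn + ec50**hill_n)


def modulate_rates(
    base_rates: np.ndarray, mod: LigandModulation, conc: float | None = None
) -> np.ndarray:
    """Scale the rates a ligand affects by its Hill-saturating multiplier."""
    if conc is None:
        conc = mod.concentration
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    frac = float(hill_fraction(conc, mod.ec50, mod.hill_n))
    q = np.asarray(base_rates, dtype=float).copy()
    for i, j, mult in mod.affected_rates:
        q[i, j] *= 1.0 + (mult - 1.0) * frac
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a continuous-time rate matrix (null space of Qᵀ)."""
    q = np.asarray(rate_matrix, dtype=float).copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    w, v = np.linalg.eig(q.T)
    idx = np.argmin(np.abs(w))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def discretize_rates(rate_matrix: np.ndarray, frame_interval: float) -> np.ndarray:
    """Per-frame transition probabilities, exact via the matrix exponential."""
    q = np.asarray(rate_matrix, dtype=float).copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    p = expm(q * frame_interval)
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


def simulate_state_path(
    transition_probs: np.ndarray,
    n_frames: int,
    seed_or_rng,
    initial_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a discrete-time Markov state path (1-based labels).

    ``transition_probs`` is the per-frame row-stochastic matrix; the initial
    state is drawn from ``initial_probs`` (default: the chain's stationary
    distribution).
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    p = np.asarray(transition_probs, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("transition_probs must be square")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition_probs must be row-stochastic")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    if initial_probs is None:
        w, v = np.linalg.eig(p.T)
        idx = np.argmin(np.abs(w - 1.0))
        pi0 = np.abs(np.real(v[:, idx]))
        pi0 = pi0 / pi0.sum()
    else:
        pi0 = np.asarray(initial_probs, dtype=float)
        pi0 = pi0 / pi0.sum()
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_frames)
    path = np.empty(n_frames, dtype=np.int64)
    s = int(np.searchsorted(np.cumsum(pi0), u[0], side="right"))
    s = min(s, p.shape[0] - 1)
    path[0] = s
    for t in range(1, n_frames):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, p.shape[0] - 1)
        path[t] = s
    return path + 1


def _channel_noise_sd(cfg: SimulationConfig, expected_counts: np.ndarray) -> np.ndarray:
    return np.sqrt(
        cfg.background_sigma**2 + cfg.shot_noise_scale**2 * np.clip(expected_counts, 0.0, None)
    )


def render_trace(
    path: np.ndarray,
    cfg: SimulationConfig,
    seed_or_rng,
    molecule_id: str = "mol0",
    bleach_frame: int | None = None,
) -> tuple[IntensityTrace, GroundTruth]:
    """Render a state path into a noisy two-channel intensity trace.

    Pipeline per frame: the apparent FRET efficiency is the state mean plus
    Gaussian conformational jitter (state sigma); donor/acceptor signal counts
    split ``total_intensity`` accordingly; the raw acceptor channel receives a
    fixed fraction of the donor signal (spectral bleed-through); both channels
    get additive background noise (and optional shot noise).  After the
    exponentially drawn donor bleach frame, and during blink intervals, both
    channels carry background only.
    """
    path = np.asarray(path, dtype=np.int64)
    if path.size == 0:
        raise ValueError("state path must be non-empty")
    if path.min() < 1 or path.max() > cfg.n_states:
        raise ValueError("state labels must be in 1..K")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    n = path.size
    dt = cfg.frame_interval

    if bleach_frame is None:
        bleach_time = rng.exponential(cfg.bleach_lifetime)
        bleach_frame = min(n, int(np.ceil(bleach_time / dt)))
    else:
        bleach_frame = min(n, int(bleach_frame))
    bleach_time = bleach_frame * dt

    # Blinks: Poisson process before the bleach, exponential durations.
    blink_intervals: list[tuple[int, int]] = []
    live = np.ones(n, dtype=bool)
    live[bleach_frame:] = False
    t = 0.0
    if cfg.blink_rate > 0:
        while True:
            t += rng.exponential(1.0 / cfg.blink_rate)
            if t >= bleach_time:
                break
            dur = rng.exponential(cfg.blink_duration_mean)
            f0 = int(t / dt)
            f1 = min(bleach_frame, int(np.ceil((t + dur) / dt)))
            f1 = max(f1, f0 + 1)
            live[f0:f1] = False
            blink_intervals.append((f0, f1))
            t += dur

    means = np.asarray(cfg.state_means)[path - 1]
    sigmas = np.asarray(cfg.state_sigmas)[path - 1]
    e_app = np.clip(means + rng.normal(0.0, 1.0, n) * sigmas, 1e-3, 1.0 - 1e-3)

    donor_signal = np.where(live, cfg.total_intensity * (1.0 - e_app), 0.0)
    acceptor_signal = np.where(live, cfg.total_intensity * e_app, 0.0)
    acceptor_raw = acceptor_signal + cfg.bleedthrough_fraction * donor_signal

    donor = donor_signal + rng.normal(0.0, 1.0, n) * _channel_noise_sd(cfg, donor_signal)
    acceptor = acceptor_raw + rng.normal(0.0, 1.0, n) * _channel_noise_sd(cfg, acceptor_raw)

    trace = IntensityTrace(molecule_id, dt, donor, acceptor)
    truth = GroundTruth(molecule_id, path.copy(), bleach_frame, blink_intervals, cfg)
    return trace, truth


def simulate_dataset(
    cfg: SimulationConfig,
    mods: Sequence[LigandModulation] = (),
) -> tuple[list[IntensityTrace], list[GroundTruth]]:
    """Simulate a full dataset of traces plus its ground-truth manifest.

    Ligand modulations (each carrying its own concentration) are applied to
    the base rate matrix before discretization.  Per-trace random streams are
    spawned deterministically from ``cfg.seed``.
    """
    q = cfg.rate_matrix()
    for mod in mods:
        q = modulate_rates(q, mod)
    p = discretize_rates(q, cfg.frame_interval)
    pi = stationary_distribution(q)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_traces)
    traces: list[IntensityTrace] = []
    truths: list[GroundTruth] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        path = simulate_state_path(p, cfg.n_frames, rng, initial_probs=pi)
        trace, truth = render_trace(path, cfg, rng, molecule_id=f"mol{i:05d}")
        traces.append(trace)
        truths.append(truth)
    return traces, truths


def intracellular_site(**overrides) -> SimulationConfig:
    """Default config emulating the intracellular labeling site.

    Three states at FRET 0.47/0.63/0.79 with sigma 0.06 and a reversible
    apo chain whose stationary occupancy is (0.63, 0.13, 0.24): the fully
    inward-open low-FRET state dominates and the partially open intermediate
    holds ~13% of time-averaged population.  Intensity and noise levels are
    set so the selection-stage signal-to-noise ratios land near 30:1
    (vs. background) and 12:1 (within-trace).
    """
    base = dict(
        state_means=(0.47, 0.63, 0.79),
        state_sigmas=(0.06, 0.06, 0.06),
        transition_rates=(
            (0.0, 0.04 / 0.63, 0.02 / 0.63),
            (0.04 / 0.13, 0.0, 0.02 / 0.13),
            (0.02 / 0.24, 0.02 / 0.24, 0.0),
        ),
        total_intensity=500.0,
        background_sigma=12.0,
        shot_noise_scale=1.6,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def extracellular_site(**overrides) -> SimulationConfig:
    """Default config emulating the extracellular labeling site.

    States at FRET 0.55/0.67/0.79; the apo chain spends ~65% of its time in
    the fully outward-open low-FRET state.
    """
    pi = (0.65, 0.175, 0.175)
    base = dict(
        state_means=(0.55, 0.67, 0.79),
        state_sigmas=(0.06, 0.06, 0.06),
        transition_rates=(
            (0.0, 0.04 / pi[0], 0.02 / pi[0]),
            (0.04 / pi[1], 0.0, 0.02 / pi[1]),
            (0.02 / pi[2], 0.02 / pi[2], 0.0),
        ),
        total_intensity=500.0,
        background_sigma=12.0,
        shot_noise_scale=1.6,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def sodium_titration(ec50: float = 55.0, hill_n: float = 2.0, fold: float = 4.0) -> LigandModulation:
    """Na+-like modulation: saturating ion destabilizes the low-FRET state.

    Scales both exit rates from the open low-FRET state (state 0) up by
    ``fold`` and the entries back into it down by ``1/fold``, so the
    low-FRET occupancy falls with concentration along a sigmoid centred
    near ``ec50`` (mM).
    """
    return LigandModulation(
        ligand_name="Na+",
        ec50=ec50,
        hill_n=hill_n,
        affected_rates=(
            (0, 1, fold),
            (0, 2, fold),
            (1, 0, 1.0 / fold),
            (2, 0, 1.0 / fold),
        ),
    )


def with_concentration(mod: LigandModulation, conc: float) -> LigandModulation:
    """Copy of a modulation at a given concentration."""
    return replace(mod, concentration=conc)
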