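"""Trace correction, FRET calculation, QC metrics and selection.

Converts raw donor/acceptor photon-count traces into corrected FRET
efficiency traces and applies the five single-molecule selection criteria:

1. no multi-step donor photobleaching (zero or one bleaching step),
2. SNR vs. background >= 15,
3. SNR vs. within-trace noise >= 4,
4. fewer than 4 donor blinking events,
5. FRET efficiency above 0.15 for at least 300 frames.

FRET efficiency is ``E = I_A / (I_A + I_D)`` computed after subtracting a
fixed fraction (default 0.165) of the donor intensity from the acceptor
channel (donor-to-acceptor spectral bleed-through), and is set to zero on
frames where the donor is dark (blinking or photobleached).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulate import IntensityTrace

NO_BLEACH = -1  # sentinel bleach_frame for traces with no detected bleach


@dataclass
class FretTrace:
    """Corrected FRET efficiency trace with dark-frame bookkeeping."""

    molecule_id: str
    frame_interval: float
    efret: np.ndarray
    dark: np.ndarray
    bleach_frame: int  # frame index of bleach, or NO_BLEACH

    def __post_init__(self) -> None:
        self.efret = np.asarray(self.efret, dtype=float)
        self.dark = np.asarray(self.dark, dtype=bool)
        if self.efret.shape != self.dark.shape:
            raise ValueError("efret and dark must have equal length")
        if np.any(self.efret[self.dark] != 0.0):
            raise ValueError("efret must be exactly 0 on dark frames")
        if not np.all(np.isfinite(self.efret)):
            raise ValueError("efret must be finite")

    @property
    def n_frames(self) -> int:
        return self.efret.size


@dataclass
class TraceQC:
    """Per-trace quality metrics and the selection verdict."""

    molecule_id: str
    snr_background: float
    snr_signal: float
    n_bleach_steps: int
    n_blinks: int
    n_frames_above_floor: int
    passed: bool = False
    failed_criteria: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the five-trace selection rules."""

    bleedthrough_fraction: float = 0.165
    min_snr_background: float = 15.0
    min_snr_signal: float = 4.0
    max_blinks: int = 3  # "< 4 blinking events"
    min_frames_above_floor: int = 300
    fret_floor: float = 0.15


# ---------------------------------------------------------------------------
# channel corrections and FRET calculation
# ---------------------------------------------------------------------------

def correct_bleedthrough(trace: IntensityTrace, fraction: float = 0.165) -> IntensityTrace:
    """Subtract ``fraction`` of the donor intensity from the acceptor channel."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("bleed-through fraction must be in [0, 1)")
    return IntensityTrace(
        trace.molecule_id,
        trace.frame_interval,
        trace.donor.copy(),
        trace.acceptor - fraction * trace.donor,
    )


def compute_fret(
    trace: IntensityTrace,
    dark_mask: np.ndarray | None = None,
    bleach_frame: int = NO_BLEACH,
) -> FretTrace:
    """Per-frame FRET efficiency ``E = I_A / (I_A + I_D)``.

    ``dark_mask`` marks donor-dark (blinking) frames; frames at or after
    ``bleach_frame`` and frames with non-positive total intensity are also
    treated as dark.  E is forced to exactly 0 on all dark frames.
    """
    n = trace.n_frames
    dark = np.zeros(n, dtype=bool) if dark_mask is None else np.asarray(dark_mask, bool).copy()
    if dark.size != n:
        raise ValueError("dark_mask length mismatch")
    if bleach_frame != NO_BLEACH:
        dark[bleach_frame:] = True
    total = trace.total
    dark |= total <= 0
    e = np.zeros(n, dtype=float)
    ok = ~dark
    e[ok] = trace.acceptor[ok] / total[ok]
    return FretTrace(trace.molecule_id, trace.frame_interval, e, dark, bleach_frame)


# ---------------------------------------------------------------------------
# change-point segmentation of total intensity (bleach-step detection)
# ---------------------------------------------------------------------------

def _noise_sd(x: np.ndarray) -> float:
    """Robust per-frame noise s.d. from first differences (MAD estimator)."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / math.sqrt(2.0))


def _binary_segmentation(x: np.ndarray, penalty: float, min_size: int = 3) -> list[int]:
    """Change-point indices via greedy binary segmentation, piecewise-mean cost.

    Splits whenever the reduction in within-segment sum of squares exceeds
    ``penalty``.  Returns sorted interior breakpoints.
    """
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(a: int, b: int) -> float:  # [a, b)
        m = b - a
        s = cs[b] - cs[a]
        return float(cs2[b] - cs2[a] - s * s / m)

    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        base = sse(a, b)
        best_gain, best_k = 0.0, -1
        for k in range(a + min_size, b - min_size + 1):
            gain = base - sse(a, k) - sse(k, b)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k >= 0 and best_gain > penalty:
            breaks.append(best_k)
            stack.append((a, best_k))
            stack.append((best_k, b))
    return sorted(breaks)


def _segment_means(x: np.ndarray, breaks: list[int]) -> tuple[np.ndarray, np.ndarray]:
    edges = np.array([0, *breaks, x.size])
    means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return edges, means


def _remove_transient_dips(
    edges: np.ndarray, means: np.ndarray, margin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge blink-like dips: a segment far below both neighbours, with the
    neighbours at a common level, is a transient dark excursion, not a step."""
    edges, means = edges.copy(), list(means)
    changed = True
    while changed and len(means) >= 3:
        changed = False
        for i in range(1, len(means) - 1):
            if (
                means[i] < means[i - 1] - margin
                and means[i] < means[i + 1] - margin
                and abs(means[i + 1] - means[i - 1]) <= margin
            ):
                # merge segments i-1, i, i+1 into one at the flanking level
                a, b = edges[i - 1], edges[i + 2]
                lvl = (means[i - 1] + means[i + 1]) / 2.0
                edges = np.delete(edges, [i, i + 1])
                means[i - 1 : i + 2] = [lvl]
                changed = True
                break
    return edges, np.asarray(means)


@dataclass
class BleachDetection:
    bleach_frame: int  # NO_BLEACH if none detected
    n_steps: int
    background_mean: float
    background_sd: float


def detect_bleach(trace: IntensityTrace, penalty_scale: float = 10.0) -> BleachDetection:
    """Locate the donor photobleaching point on the total-intensity trace.

    Penalized mean-shift segmentation of donor+acceptor, followed by removal
    of transient (blink-like) dips; the bleach frame is the start of the
    trailing run of segments sitting at the background level, and the step
    count is the number of significant downward level changes that remain.
    A trace with no downward step returns the ``NO_BLEACH`` sentinel, with
    background statistics taken from the trailing 10% of frames.
    """
    total = trace.total
    n = total.size
    if n < 10:
        raise ValueError("bleach detection requires at least 10 frames")
    sd = _noise_sd(total)
    sd = max(sd, 1e-9)
    penalty = penalty_scale * sd * sd * math.log(n)
    breaks = _binary_segmentation(total, penalty)
    edges, means = _segment_means(total, breaks)
    edges, means = _remove_transient_dips(edges, means, 3.0 * sd)

    if len(means) == 1:
        tail = total[int(0.9 * n):]
        return BleachDetection(NO_BLEACH, 0, float(tail.mean()), float(tail.std(ddof=1)))

    bg_mean = float(means[-1])
    bg_seg = total[edges[-2]: edges[-1]]
    bg_sd = float(bg_seg.std(ddof=1)) if bg_seg.size > 1 else sd

    # extend the background run backwards over consecutive background-level segments
    i = len(means) - 1
    while i > 0 and abs(means[i - 1] - bg_mean) <= 3.0 * max(bg_sd, sd):
        i -= 1
    n_steps = int(np.sum(np.diff(means[: i + 1]) < -3.0 * sd))
    if n_steps == 0:
        tail = total[int(0.9 * n):]
        return BleachDetection(NO_BLEACH, 0, float(tail.mean()), float(tail.std(ddof=1)))
    return BleachDetection(int(edges[i]), n_steps, bg_mean, bg_sd)


# ---------------------------------------------------------------------------
# blinking, SNR, selection
# ---------------------------------------------------------------------------

def detect_blinks(
    trace: IntensityTrace, bleach: BleachDetection
) -> tuple[list[tuple[int, int]], int]:
    """Donor dark intervals before the bleach.

    A dark interval is a maximal pre-bleach run of frames where the donor
    channel sits below ``background_mean + 3 * background_sd`` (the 3-sigma
    dark threshold), with the background statistics measured on the
    post-bleach donor channel.  Because a dark donor excites no acceptor,
    the total intensity must simultaneously sit at background level — this
    distinguishes true blinks from high-FRET frames whose donor count is
    low but whose acceptor is bright.  For traces without an observed
    bleach no background is measurable, so only the total-intensity test
    (within 3 noise s.d. of zero) is applied.  Returns the intervals as
    half-open frame ranges and their count.
    """
    end = trace.n_frames if bleach.bleach_frame == NO_BLEACH else bleach.bleach_frame
    if bleach.bleach_frame == NO_BLEACH:
        thr = 3.0 * max(_noise_sd(trace.total), 1e-9)
        dark = trace.total[:end] < thr
    else:
        post_donor = trace.donor[bleach.bleach_frame:]
        post_total = trace.total[bleach.bleach_frame:]
        thr_d = float(post_donor.mean()) + 3.0 * float(post_donor.std(ddof=1))
        thr_t = float(post_total.mean()) + 3.0 * float(post_total.std(ddof=1))
        dark = (trace.donor[:end] < thr_d) & (trace.total[:end] < thr_t)
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < dark.size:
        if dark[i]:
            j = i
            while j < dark.size and dark[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    return intervals, len(intervals)


def blink_mask(n_frames: int, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for a, b in intervals:
        mask[a:b] = True
    return mask


def compute_snr(
    trace: IntensityTrace,
    bleach: BleachDetection,
    dark_intervals: Sequence[tuple[int, int]] = (),
    min_segment: int = 5,
) -> tuple[float, float]:
    """Signal-to-noise ratios of the total-intensity step at the bleach.

    ``snr_background`` is the bleach step magnitude (mean pre-bleach total
    minus mean post-bleach total) over the post-bleach (background) noise
    s.d.; ``snr_signal`` is the same magnitude over the pre-bleach noise
    s.d., which additionally contains photon-statistics and photophysical
    noise.  Pre-bleach statistics exclude donor-dark frames.  Traces without
    at least ``min_segment`` frames on both sides of a bleach return
    infinite sentinels.
    """
    if bleach.bleach_frame == NO_BLEACH:
        return math.inf, math.inf
    b = bleach.bleach_frame
    total = trace.total
    pre_ok = ~blink_mask(trace.n_frames, dark_intervals)[:b]
    pre = total[:b][pre_ok]
    post = total[b:]
    if pre.size < min_segment or post.size < min_segment:
        return math.inf, math.inf
    step = float(pre.mean() - post.mean())
    post_sd = float(post.std(ddof=1))
    pre_sd = float(pre.std(ddof=1))
    snr_bg = step / post_sd if post_sd > 0 else math.inf
    snr_sig = step / pre_sd if pre_sd > 0 else math.inf
    return snr_bg, snr_sig


def qc_trace(
    trace: IntensityTrace, criteria: SelectionCriteria = SelectionCriteria()
) -> tuple[TraceQC, FretTrace]:
    """Full single-trace QC: corrections, bleach/blink detection, SNRs,
    FRET calculation, and the five-way selection verdict."""
    bleach = detect_bleach(trace)
    intervals, n_blinks = detect_blinks(trace, bleach)
    snr_bg, snr_sig = compute_snr(trace, bleach, intervals)
    corrected = correct_bleedthrough(trace, criteria.bleedthrough_fraction)
    fret = compute_fret(corrected, blink_mask(trace.n_frames, intervals), bleach.bleach_frame)
    n_above = int(np.sum(fret.efret[~fret.dark] > criteria.fret_floor))

    qc = TraceQC(
        molecule_id=trace.molecule_id,
        snr_background=snr_bg,
        snr_signal=snr_sig,
        n_bleach_steps=bleach.n_steps,
        n_blinks=n_blinks,
        n_frames_above_floor=n_above,
    )
    failed = []
    if qc.n_bleach_steps > 1:
        failed.append(1)
    if qc.snr_background < criteria.min_snr_background:
        failed.append(2)
    if qc.snr_signal < criteria.min_snr_signal:
        failed.append(3)
    if qc.n_blinks > criteria.max_blinks:
        failed.append(4)
    if qc.n_frames_above_floor < criteria.min_frames_above_floor:
        failed.append(5)
    qc.failed_criteria = failed
    qc.passed = not failed
    return qc, fret


def select_traces(
    traces: Sequence[IntensityTrace],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[FretTrace], list[TraceQC]]:
    """Apply the five selection criteria to a trace collection.

    Returns the corrected FRET traces of the accepted molecules and the full
    QC report (one record per input trace, accepted or not).
    """
    accepted: list[FretTrace] = []
    report: list[TraceQC] = []
    for trace in traces:
        qc, fret = qc_trace(trace, criteria)
        report.append(qc)
        if qc.passed:
            accepted.append(fret)
    return accepted, report
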