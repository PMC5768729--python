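"""Shared fixtures: crafted intensity traces with known QC outcomes.

The builder places all pre-bleach noise on the acceptor channel and all
post-bleach noise on the donor channel, so the donor never dips toward the
dark threshold by accident and every crafted trace has a deterministic
selection verdict: total-intensity noise (hence both SNRs), the bleach step
structure, the blink count and the frames-above-floor count are controlled
independently.
"""

from __future__ import annotations

import numpy as np
import pytest

from fretgate import IntensityTrace


def crafted_trace(
    molecule_id: str,
    n_frames: int = 700,
    bleach_frame: int | None = 450,
    efret: float = 0.7,
    total: float = 1000.0,
    pre_sd: float = 25.0,
    post_sd: float = 25.0,
    blinks: tuple[tuple[int, int], ...] = (),
    extra_steps: tuple[tuple[int, float], ...] = (),
    seed: int = 0,
    frame_interval: float = 0.1,
) -> IntensityTrace:
    """Piecewise-constant two-channel trace with controlled QC properties.

    ``extra_steps`` inserts intermediate intensity plateaus
    ``(start_frame, level)`` between the full-intensity stretch and the
    background, producing multi-step "bleaching".  SNR_background is
    ``total / post_sd`` and SNR_signal is ``total / pre_sd``.
    """
    rng = np.random.default_rng(seed)
    n = n_frames
    b = n if bleach_frame is None else bleach_frame
    donor = np.zeros(n)
    acceptor = np.zeros(n)

    # live stretch: constant donor, totals fluctuate through the acceptor
    donor[:b] = total * (1.0 - efret)
    acceptor[:b] = total * efret + rng.normal(0.0, pre_sd, b)
    # intermediate plateaus (partial steps) before the background
    for start, level in extra_steps:
        donor[start:b] = level * (1.0 - efret)
        acceptor[start:b] = level * efret + rng.normal(0.0, pre_sd, b - start)
    # background: noise on the donor channel only
    donor[b:] = rng.normal(0.0, post_sd, n - b)
    acceptor[b:] = 0.0
    # blinks: both channels at (noisy) background
    for a0, a1 in blinks:
        donor[a0:a1] = rng.normal(0.0, post_sd, a1 - a0)
        acceptor[a0:a1] = 0.0
    return IntensityTrace(molecule_id, frame_interval, donor, acceptor)


def filter_suite() -> list[tuple[IntensityTrace, bool, list[int]]]:
    """Twenty crafted traces: expected verdict and failed criteria for each.

    Covers every failure mode of the five selection criteria plus passing
    traces at and away from the decision boundaries.
    """
    cases: list[tuple[IntensityTrace, bool, list[int]]] = []

    def add(trace, passed, failed):
        cases.append((trace, passed, failed))

    # --- passing traces -------------------------------------------------
    add(crafted_trace("pass_plain", seed=1), True, [])
    add(crafted_trace("pass_low_e", efret=0.3, seed=2), True, [])
    add(crafted_trace("pass_high_e", efret=0.85, seed=3), True, [])
    add(crafted_trace("pass_late_bleach", bleach_frame=650, seed=4), True, [])
    add(
        crafted_trace("pass_three_blinks", blinks=((100, 104), (200, 204), (300, 304)), seed=5),
        True,
        [],
    )
    add(crafted_trace("pass_no_bleach", bleach_frame=None, seed=6), True, [])
    add(crafted_trace("pass_boundary_frames", bleach_frame=320, seed=7), True, [])

    # --- criterion 1: multi-step photobleaching -------------------------
    add(
        crafted_trace("fail_two_steps", extra_steps=((300, 800.0),), seed=8),
        False,
        [1],
    )
    add(
        crafted_trace(
            "fail_three_steps", extra_steps=((250, 850.0), (350, 700.0)), seed=9
        ),
        False,
        [1],
    )

    # --- criterion 2: SNR vs background ---------------------------------
    add(crafted_trace("fail_snr_bg", post_sd=100.0, pre_sd=50.0, seed=10), False, [2])
    add(crafted_trace("fail_snr_bg_worse", post_sd=125.0, pre_sd=50.0, seed=11), False, [2])

    # --- criterion 3: SNR within the live trace -------------------------
    add(crafted_trace("fail_snr_sig", pre_sd=330.0, seed=12), False, [3])
    add(crafted_trace("fail_snr_sig_worse", pre_sd=500.0, seed=13), False, [3])

    # --- criterion 4: too many blinking events --------------------------
    add(
        crafted_trace(
            "fail_four_blinks",
            blinks=((80, 84), (160, 164), (240, 244), (320, 324)),
            seed=14,
        ),
        False,
        [4],
    )
    add(
        crafted_trace(
            "fail_five_blinks",
            blinks=((60, 63), (120, 123), (180, 183), (240, 243), (300, 303)),
            seed=15,
        ),
        False,
        [4],
    )

    # --- criterion 5: not enough frames above the FRET floor ------------
    add(crafted_trace("fail_short_bright", bleach_frame=200, seed=16), False, [5])
    add(crafted_trace("fail_dim", efret=0.10, seed=17), False, [5])
    add(crafted_trace("fail_dim_no_bleach", efret=0.10, bleach_frame=None, seed=18), False, [5])

    # --- combined failures ----------------------------------------------
    add(
        crafted_trace("fail_bg_and_short", bleach_frame=250, post_sd=100.0, pre_sd=50.0, seed=19),
        False,
        [2, 5],
    )
    add(
        crafted_trace(
            "fail_steps_and_blinks",
            extra_steps=((300, 800.0),),
            blinks=((80, 84), (120, 124), (160, 164), (200, 204)),
            seed=20,
        ),
        False,
        [1, 4],
    )
    assert len(cases) == 20
    return cases


@pytest.fixture(scope="session")
def filter_fixtures():
    return filter_suite()
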