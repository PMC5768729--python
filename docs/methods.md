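# Methods

`fretgate` implements a complete analysis chain for camera-based
single-molecule FRET recordings of a two-gate membrane transporter: synthetic
trace generation with known ground truth, trace correction and selection,
hidden-Markov state discovery and idealization, dwell/occupancy/transition
kinetics, Hill dose-response fitting, and a thermodynamic bound on the
coupling between the two gates. This note records the models, the defaults
and why, the numerical choices, and what the synthetic data does and does not
emulate.

## Generative model of a trace

A molecule occupies one of K conformational states with FRET efficiencies
`mu_k` (defaults: 0.47/0.63/0.79 for the intracellular labeling site,
0.55/0.67/0.79 for the extracellular site) and interconverts as a
continuous-time Markov chain with rate matrix Q (1/s). The chain is observed
at a fixed frame interval `dt` (default 0.1 s); per-frame transition
probabilities are the matrix exponential `expm(Q dt)`, which is exact and
avoids the first-order error of `I + Q dt` at fast rates. Initial states are
drawn from the chain's stationary distribution, so pooled occupancies are
unbiased estimates of it at any trace length.

Per frame the apparent efficiency is `e = mu_k + N(0, sigma_k)` (conformational
jitter, default `sigma_k` = 0.06), split into donor and acceptor signal counts
of a fixed total intensity (default 500 photons/frame). The raw acceptor
channel additionally receives a fixed fraction (0.165) of the donor signal
(spectral bleed-through). Both channels carry additive Gaussian background
noise (default s.d. 12) and, in the site presets, a shot-noise-like term with
s.d. `1.6 * sqrt(expected counts)` emulating photon statistics and camera
gain. With these defaults the selection-stage SNR statistics land near the
values typical of the targeted experiments (~30:1 against background, ~12:1
within the live trace); the base `SimulationConfig` keeps the shot term off so
noise components can be studied in isolation.

Photophysics: the donor bleaches once, at an exponentially distributed time
(default mean 100 s), after which both channels contain background only.
Blinks arrive as a Poisson process (default 0.01 events/s) with exponential
durations (default mean 0.4 s), truncated at the bleach; a dark donor excites
no acceptor, so both channels drop to background during a blink. Acceptor
photophysics, triplet states beyond simple blinking, and raw-movie synthesis
are out of scope.

Default apo kinetics are reversible three-state chains constructed from
stationary targets and exchange fluxes (detailed balance): the intracellular
preset has stationary occupancies (0.63, 0.13, 0.24) — a dominant open
low-FRET state and a rarely visited (~13%) intermediate — with mean dwells of
roughly 2–10 s, and includes direct low<->high transitions. Dwells of seconds
rather than minutes keep a few transitions per trace visible within realistic
photobleaching-limited observation windows; the emphasis is statistical
structure, not literal apo time constants.

Ligand effects are modeled as Hill-law rate modulation: an affected rate is
scaled by `1 + (m - 1) * c^n / (c^n + EC50^n)`, moving from its base value to
`base * m` at saturation. The sodium-like preset destabilizes the open
low-FRET state fourfold (exits scaled up by m = 4, entries down by 1/m) with
EC50 = 55 mM and n = 2. Note that state occupancy is a nonlinear function of
the rates, so the apparent EC50 of the occupancy dose-response curve sits
below the rate-law EC50; recovery tests therefore compare fits of estimated
occupancies against the fit of the generating chain's *analytic* stationary
occupancies on the same concentration grid, which is the curve a perfect
estimator would see.

## Preprocessing and selection

FRET efficiency is `E = I_A / (I_A + I_D)` computed after subtracting 0.165
of the donor from the acceptor. Apparent-brightness (gamma) and
acceptor-to-donor crosstalk corrections are omitted (gamma ~ 1 and negligible
reverse crosstalk in the targeted instrument configuration). E is set to
exactly 0 on dark frames: donor blinks, frames at/after the bleach, and
frames with non-positive total intensity.

Bleach detection runs penalized mean-shift segmentation (greedy binary
segmentation of the total intensity, SSE cost, penalty `10 * sigma^2 * ln n`
with sigma estimated robustly from first differences). Blink-like dips — a
segment far below two neighbours that sit at a common level — are merged away
before step counting. The bleach frame is the start of the trailing run of
segments at the background level; the step count is the number of significant
downward level changes that remain. Background statistics come from the final
post-bleach segment, or the trailing 10% of frames when no bleach is found.

Blink detection flags maximal pre-bleach runs where the donor falls below
`bg_mean + 3 * bg_sd` (donor-channel post-bleach statistics) *and* the total
intensity is simultaneously at background — the second condition is required
because in a genuine donor dark state no energy reaches the acceptor, whereas
a high-FRET frame can have a low donor count with a bright acceptor. For
traces without an observed bleach only the total-intensity test (within 3
noise s.d. of zero) is available.

SNRs use the bleach step of the total intensity: `snr_background` divides the
step magnitude by the post-bleach noise s.d., `snr_signal` by the pre-bleach
noise s.d. (excluding blink frames). Traces without a bleach, or without at
least 5 frames on both sides of it, report infinite sentinels.

The five selection criteria: (1) no multi-step photobleaching — a trace
showing zero or one downward step passes, since both are consistent with a
single molecule, while two or more partial steps indicate an aggregate;
(2) `snr_background >= 15`; (3) `snr_signal >= 4`; (4) fewer than 4 blinking
events; (5) E strictly above 0.15 on at least 300 non-dark frames (not
necessarily contiguous — the total count is used).

## State discovery and idealization

Model discovery pools the non-dark stretches of a deterministic seed-driven
subsample of at most 1500 molecules and fits Gaussian-emission HMMs by EM
(`hmmlearn`), for K in 1..5, stopping when the log-likelihood improves by
less than 1e-6 nats; non-convergence within the iteration cap (100) is
flagged and the best-so-far model returned. Initialization uses
quantile-spaced means, a shared width of `pooled s.d. / K`, and uniform
transitions; 5 seeded restarts guard against local optima (restart 0 is the
deterministic quantile init, the others perturb the means). K is selected by
BIC, a penalized-likelihood surrogate for evidence-based selection; the
model's `evidence` property is `-BIC/2`. States are always reported sorted by
mean.

Idealization uses the segmental K-means algorithm: each non-dark segment of a
trace receives its Viterbi path under the model (computed in log space; ties
break toward the lower state index), then the per-trace emission parameters
and transition frequencies are re-estimated from the assignment and the two
steps alternate until the path is stable (at most 20 cycles; states the trace
never visits keep the shared-model parameters, and a re-estimate that would
break the mean ordering is discarded). A dark gap restarts the chain at the
model's initial distribution and splits dwells — conservative, in that it can
only shorten dwells, never fabricate long ones.

Outlier removal drops traces whose assigned frames deviate from their state
means by more than a threshold (default 1) in units of the state widths,
averaged over the trace. The per-trace mean is used rather than any-frame
deviation, which would reject nearly everything at realistic widths.

## Kinetics

Dwells are maximal runs of one label; runs touching the trace start/end or a
dark gap are censored. Mean dwell times average uncensored dwells only
(censoring biases durations downward), while occupancy fractions pool all
assigned frames (censoring does not bias time fractions). Because dwells are
measured in whole frames, the expected dwell of a state with exit rate k is
`dt / (1 - P_stay)` with `P_stay = expm(Q dt)_kk`, not `1/k`; tests compare
against this discretized closed form. Transitions are label changes within
contiguous assigned stretches; changes across a dark gap are not counted,
keeping dwell lists, transition counts and density plots mutually consistent.

Transition density plots accumulate one count per transition at the observed
mean E of the preceding and following dwells (observed values, not idealized
state means), on a 50x50 grid over [0,1]^2 (~0.02 FRET resolution), and are
normalized to transitions per molecule per second of assigned time, so the
integrated density times the total assigned time returns the transition
count exactly.

Pooled FRET histograms (bin width 0.02) are fitted with a K-component
Gaussian mixture (scikit-learn EM, 3 inits, components sorted by mean).

Dose-response curves are fit by unweighted least squares to
`r(c) = r0 + (r_inf - r0) * c^n / (c^n + EC50^n)` with the Hill coefficient
fixed and EC50 and both asymptotes free; at least 4 distinct concentrations
are required and a flat response raises an error (EC50 unidentifiable). The
stored `floor`/`ceiling` are the sorted asymptotes, so decreasing responses
are handled naturally.

## Coupling bound

For two binary gates with marginal open-state probabilities p(x), p(y), the
thermodynamic coupling function `ddA = -kT ln(p(x,y) / (p(x) p(y)))` gives
the free-energy cost of co-occupancy relative to independence. With only the
marginals measured, the joint probability is bounded below by
`p' = min(p_x, p_y) - (1 - max(p_x, p_y))`, floored at 0; substituting p'
yields the *maximum* destabilization consistent with the data. The bound is
informative only when both marginals exceed 0.5 (otherwise p' = 0 and the
sentinel is +inf, with a warning). Energies are reported in kT with kT = 1.
For equal marginals the closed form is `-ln((2p - 1) / p^2)`; at p = 0.65 on
both faces this gives 0.342 kT.

## What passing tests show — and don't

The synthetic generator reproduces the statistical structure the pipeline
assumes: Gaussian state emissions, Markovian kinetics, single-step bleaching,
simple blinking, fixed bleed-through, stationary initial conditions. Real
recordings violate several of these in ways the tests cannot probe:
non-Gaussian and state-dependent noise, slow drifts and baseline wander,
acceptor photophysics, heterogeneous molecules, non-Markovian kinetics, and
day-to-day instrument variation. Recovery results on synthetic data therefore
validate the estimators under their stated assumptions, not the biology of
any particular dataset.

Problem sizes in the test suite (e.g. 300 traces x 600 frames for the
end-to-end recovery check, 200 traces per concentration for titrations) were
chosen as the smallest sets at which the measured quantities are statistically
stable at the asserted tolerances.

## Known limitations

- No rate-matrix maximum-likelihood estimation; kinetics are summarized by
  empirical dwell means and transition counts.
- The variational machinery of evidence-based HMM selection is approximated
  by maximum likelihood + BIC; for the well-separated states targeted here
  the two agree on K, but BIC can differ from a full evidence calculation for
  heavily overlapping states or tiny datasets.
- SNR estimators are one consistent reading of their verbal definitions
  (step magnitude over post- vs. pre-bleach noise); instruments and software
  differ in the exact convention.
- Traces that never bleach carry infinite SNR sentinels and pass criteria
  1-3 by convention; with long-lived fluorophores this admits traces a
  stricter "must bleach" rule would reject.
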