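# fretgate

Simulation and analysis of single-molecule FRET (smFRET) trajectories for
two-gate membrane transporters — the kind of recording used to watch a
neurotransmitter:sodium-symporter homolog open and close its extracellular
and intracellular gates one molecule at a time.

The package covers the full analysis chain as an importable library:

- **`fretgate.simulate`** — synthetic donor/acceptor intensity traces with
  known ground truth: Gaussian FRET states, continuous-time Markov kinetics
  (discretized exactly via the matrix exponential), ligand-dependent rate
  modulation along Hill laws, single-step donor photobleaching, blinking,
  spectral bleed-through and photon noise.
- **`fretgate.preprocess`** — bleed-through correction
  (`I_A' = I_A - 0.165 I_D`), FRET efficiency `E = I_A / (I_A + I_D)` with
  dark-state zeroing, change-point bleach detection, blink detection, SNR
  metrics, and the five-way single-molecule selection filter.
- **`fretgate.idealize`** — Gaussian-HMM state discovery across traces by EM
  with a 1e-6 convergence rule and BIC-based selection of the state count,
  then per-trace segmental K-means (Viterbi) idealization and model-deviation
  outlier removal.
- **`fretgate.kinetics`** — dwell extraction with censoring, state
  occupancies and mean dwell times, transition density plots, Gaussian
  mixture fits of FRET histograms, and Hill dose-response fits with fixed
  Hill coefficient.
- **`fretgate.coupling`** — the thermodynamic coupling function
  `ddA = -kT ln(p(x,y)/(p(x)p(y)))` and the minimal-joint bound
  `p' = min(p_x,p_y) - (1 - max(p_x,p_y))`, which together turn the measured
  open-state occupancies of the two gates into an upper bound on their
  allosteric coupling.

The science in brief: if a transporter's two gates were rigidly coupled
(strict alternating access), both could never be open at once. Measuring
~60-70% open-state occupancy on *both* faces in the apo state bounds the
free-energy penalty of the doubly open conformation: with marginals of 0.65
the worst-case coupling is `-ln(0.30/0.4225) = 0.34 kT` — far less than a
hydrogen bond, so the gates move as largely independent domains.

## Worked example

Simulate intracellular-site traces (three states at FRET 0.47/0.63/0.79,
with the intermediate state holding ~13% of the stationary occupancy), run
selection, discover the state model, idealize, and summarize the kinetics:

```python
import fretgate as fg

cfg = fg.intracellular_site(n_traces=120, n_frames=600, seed=11)
traces, truths = fg.simulate_dataset(cfg)
accepted, report = fg.select_traces(traces)
model, per_k = fg.discover_model(accepted, seed=11)
ideals = fg.idealize_dataset(accepted, model)
occ = fg.occupancy(ideals, cfg.frame_interval, n_states=model.n_states)
```

Running `examples/04_dwell_kinetics.py` (the same pipeline with the known
generating model) prints:

```
state   occupancy  (truth)   mean dwell [s]
  1      0.633     (0.630)     8.16
  2      0.122     (0.130)     2.09
  3      0.245     (0.240)     5.47
transitions: 768  (0.151 per second of assigned time)
TDP integrates back to 768 transitions over 5098 s of assigned time
```

i.e. the estimated time fractions track the generating chain's stationary
distribution to within sampling error, the rare intermediate state is
correctly recovered near 13%, and the transition-density bookkeeping is
exactly conservative. `examples/03_state_discovery.py` shows the model
selection step picking K = 3 over K in 1..5 and recovering the state means to
three decimals; `examples/05_dose_response.py` refits a simulated sodium
titration's occupancy curve; and `examples/06_coupling_bound.py` prints the
coupling bound:

```
marginal open-state occupancies:   0.65 / 0.65
independence joint probability:    0.4225
minimal consistent joint:          0.3000
max allosteric destabilization:    0.342 kT
```

Each script in `examples/` is a short narrative: it builds or loads a small
input, runs one capability, and explains what the printed numbers mean.

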