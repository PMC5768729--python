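"""Occupancies, mean dwell times and the transition density plot.

Runs the full pipeline on a simulated dataset and prints the kinetic summary
that the dose-response and coupling analyses consume.
"""

import numpy as np

import fretgate as fg

cfg = fg.intracellular_site(n_traces=120, n_frames=600, seed=11)
traces, _ = fg.simulate_dataset(cfg)
accepted, _ = fg.select_traces(traces)
model = fg.HmmModel(
    means=cfg.state_means,
    sigmas=cfg.state_sigmas,
    initial_probs=fg.stationary_distribution(cfg.rate_matrix()),
    transition_probs=fg.discretize_rates(cfg.rate_matrix(), cfg.frame_interval),
)
ideals = fg.idealize_dataset(accepted, model)

occ = fg.occupancy(ideals, cfg.frame_interval, n_states=3)
pi = fg.stationary_distribution(cfg.rate_matrix())
print("state   occupancy  (truth)   mean dwell [s]")
for s, frac, t_pi, dw in zip(occ.states, occ.fractions, pi, occ.mean_dwell_times):
    print(f"  {s}      {frac:.3f}     ({t_pi:.3f})     {dw:.2f}")
print(f"transitions: {occ.n_transitions}  "
      f"({occ.mean_transition_rate:.3f} per second of assigned time)")

tdp = fg.transition_density(ideals, accepted, n_bins=50)
total = tdp.density.sum() * tdp.total_assigned_time
print(f"TDP integrates back to {total:.0f} transitions over "
      f"{tdp.total_assigned_time:.0f} s of assigned time")
# Mean dwell times use uncensored dwells only; occupancy pools all assigned
# frames, so the two summaries weight the data differently by design.
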