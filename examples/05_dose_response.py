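"""Ion titration: occupancy dose-response and Hill fit with fixed n.

Simulates a sodium-like titration in which the ion destabilizes the open
low-FRET state (rate modulation along a Hill law, EC50 = 55 mM, n = 2),
estimates the low-FRET occupancy at each concentration from simulated
traces, and refits the dose-response curve.
"""

import numpy as np

import fretgate as fg

mod = fg.sodium_titration(ec50=55.0, hill_n=2.0, fold=4.0)
concs = np.array([0.0, 5.0, 15.0, 35.0, 55.0, 90.0, 150.0, 300.0])
q0 = fg.extracellular_site().rate_matrix()

estimates = []
for i, c in enumerate(concs):
    cfg = fg.extracellular_site(n_traces=60, n_frames=450, seed=500 + i)
    traces, _ = fg.simulate_dataset(cfg, [fg.with_concentration(mod, c)])
    accepted, _ = fg.select_traces(traces)
    q_c = fg.modulate_rates(q0, mod, c)
    model = fg.HmmModel(
        means=cfg.state_means,
        sigmas=cfg.state_sigmas,
        initial_probs=fg.stationary_distribution(q_c),
        transition_probs=fg.discretize_rates(q_c, cfg.frame_interval),
    )
    ideals = fg.idealize_dataset(accepted, model)
    estimates.append(fg.occupancy(ideals, cfg.frame_interval, n_states=3).fractions[0])
    print(f"[Na+] = {c:5.0f} mM   low-FRET occupancy {estimates[-1]:.3f}")

fit = fg.fit_hill(concs, estimates, hill_n=2.0)
ref = [fg.stationary_distribution(fg.modulate_rates(q0, mod, c))[0] for c in concs]
ref_fit = fg.fit_hill(concs, ref, hill_n=2.0)
print(f"fitted EC50: {fit.ec50:.1f} mM "
      f"(analytic occupancy-curve EC50: {ref_fit.ec50:.1f} mM)")
# The occupancy-curve EC50 sits below the rate-law EC50 (55 mM) because
# state occupancy is a nonlinear function of the modulated rates; the fit is
# compared against the analytic occupancy curve on the same grid.
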