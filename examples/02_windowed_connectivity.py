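"""Motion QC and tapered sliding-window connectivity for one session.

Simulates one session's component time series, applies the framewise
displacement exclusion rule, and converts the series into Fisher-z window
vectors with the default 25-TR tapered window.
"""

import numpy as np

import airdfc as a

layout = a.NetworkLayout.small()
templates = a.build_state_templates(layout, seed=0)
model = a.StateSequenceModel.symmetric(5, self_transition=0.9)
sequence = a.simulate_state_sequence(model, 60, seed=2)
ts = a.simulate_component_timeseries(templates, sequence, 25, observation_noise_sd=0.2, seed=2)

fd_good = np.abs(np.random.default_rng(2).normal(0.08, 0.03, ts.shape[0]))
decision = a.qc_filter(fd_good)
print(f"QC on a low-motion trace: keep={decision.keep} (mean FD {decision.mean_fd:.3f} mm)")
decision_bad = a.qc_filter(np.full(100, 0.3))
print(f"QC on constant 0.30 mm:   keep={decision_bad.keep} -> {decision_bad.reasons[0]}")

spec = a.WindowSpec(width=25, step=1, taper_sigma=3.0)
taper = a.make_taper(spec)
stack = a.windowed_correlation(ts, spec)
print(f"taper: length {taper.size}, sum {taper.sum():.3f}, center/edge ratio "
      f"{taper[12] / taper[0]:.2f}")
print(f"window stack: {stack.n_windows} windows x {stack.n_edges} edges "
      f"(C(12,2) = 66 Fisher-z values per window)")
print("Each row summarizes the connectivity pattern inside one 25-TR window;")
print("clustering these rows across sessions identifies the dynamic states.")
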