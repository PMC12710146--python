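"""A miniature current sweep with full MCF analysis per series.

For each applied current density one series is simulated, downsampled
to 3125 Hz and pushed through the laminar-length pipeline; the table
mirrors the study's exponent-vs-current relation at toy scale (10 s
series; the acceptance script uses 20-30 s replicates).
"""

import hhcrit as hc

df = hc.run_sweep(currents=(-0.2, 0.0, 0.3), n_replicates=1,
                  duration_s=10.0, base_seed=1, verbose=True)
cols = ["Iex", "p2", "p3", "r2", "firing_rate", "is_critical"]
print()
print(df[cols].to_string(index=False,
                         float_format=lambda v: f"{v:.3f}"))
print("\np2 grows with depolarization while the hyperpolarized series")
print("carries a clear exponential component (larger p3): criticality")
print("lives next to the spiking bifurcation, not away from it.")
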