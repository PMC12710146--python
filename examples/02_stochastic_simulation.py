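"""Event-driven stochastic simulation of the channel ensemble.

1800 Na+ and 540 K+ channels hop between their gating states at
voltage-dependent rates; between transitions the membrane potential
relaxes exponentially under frozen conductances.  The trace is recorded
at 200 kHz and decimated to 3125 Hz for analysis.
"""

import numpy as np

import hhcrit as hc

for iex, dur in [(0.0, 5.0), (0.35, 5.0)]:
    cfg = hc.SimConfig(Iex=iex, duration_s=dur, seed=7)
    raw = hc.simulate(cfg)
    tr = hc.downsample(raw, cfg.out_rate)
    spikes = hc.detect_spikes(tr)
    sub, _ = hc.remove_spikes(tr, spikes)
    print(f"Iex = {iex:+.2f} uA/cm^2 ({dur:.0f} s, seed {cfg.seed}):")
    print(f"  channel-state transitions : {raw.meta['n_events']:,}")
    print(f"  mean V                    : {np.mean(tr.values):8.3f} mV "
          f"(deterministic Vr = {hc.find_fixed_point(iex):.3f})")
    print(f"  subthreshold sd           : {np.std(sub.values):8.3f} mV")
    print(f"  spikes                    : {len(spikes)} "
          f"({spikes.firing_rate:.2f} Hz)")

print("\nDepolarization moves the mean toward the bifurcation, widens")
print("the subthreshold fluctuations (critical slowing down) and turns")
print("on fluctuation-driven firing; at rest the trace is quiescent.")
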