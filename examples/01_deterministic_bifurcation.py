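"""Resting potentials and the spiking bifurcation of the deterministic model.

The type-I membrane sits at a stable resting potential Vr(Iex) until the
applied current density reaches the rheobase Ic, where the fixed point
collides with the spiking threshold (saddle-node bifurcation) at the
membrane potential Vc.
"""

import numpy as np

import hhcrit as hc

for iex in (-0.2, 0.0, 0.2, 0.35):
    print(f"Vr({iex:+.2f} uA/cm^2) = {hc.find_fixed_point(iex):8.3f} mV")

bif = hc.find_bifurcation()
print(f"\nrheobase Ic = {bif.Ic:.4f} uA/cm^2")
print(f"bifurcation potential Vc = {bif.Vc:.3f} mV")
print(f"Vc - Vr(0) = {bif.Vc - bif.Vr(0.0):.3f} mV")
print("\nThe resting potential creeps toward Vc as Iex approaches Ic;")
print("above Ic the model fires repetitively at arbitrarily low rates")
print("(type-I onset).  All subthreshold currents in the stochastic")
print("study sweep (up to 0.35) stay below this rheobase: every spike")
print("there is fluctuation-driven.")
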