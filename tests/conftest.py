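"""Shared fixtures: simulated traces and map trajectories are expensive,
so they are built once per session and reused across test modules."""

import numpy as np
import pytest

import hhcrit as hc

# fixed study seeds for the desk-scale runs
SWEEP_SEED = 42
SWEEP_SPEC = {           # Iex -> duration_s
    -0.2: 20.0,
    0.0: 20.0,
    0.1: 20.0,
    0.2: 20.0,
    0.3: 30.0,
    0.35: 30.0,
}


@pytest.fixture(scope="session")
def sweep_traces():
    """Downsampled traces + spikes + MCF for the desk-scale current sweep."""
    out = {}
    for i, (iex, dur) in enumerate(SWEEP_SPEC.items()):
        tr = hc.simulate_downsampled(iex, dur, seed=SWEEP_SEED + i)
        spikes = hc.detect_spikes(tr)
        res = hc.analyze_trace(tr)
        out[iex] = {"trace": tr, "spikes": spikes, "mcf": res}
    return out


@pytest.fixture(scope="session")
def sweep_table(sweep_traces):
    import pandas as pd
    rows = []
    for iex, d in sweep_traces.items():
        b = d["mcf"].best
        rows.append({"Iex": iex, "p2": b.p2, "p3": b.p3, "r2": b.r2,
                     "firing_rate": d["spikes"].firing_rate,
                     "is_critical": d["mcf"].is_critical, "failed": False})
    # intermediate spiking currents span two decades of firing rate and
    # anchor the firing-rate-vs-exponent relation
    for j, iex in enumerate((0.25, 0.27, 0.32)):
        tr = hc.simulate_downsampled(iex, 30.0, seed=SWEEP_SEED + 200 + j)
        spikes = hc.detect_spikes(tr)
        res = hc.analyze_trace(tr)
        b = res.best
        rows.append({"Iex": iex, "p2": b.p2, "p3": b.p3, "r2": b.r2,
                     "firing_rate": spikes.firing_rate,
                     "is_critical": res.is_critical, "failed": False})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def map_results():
    """MCF scans of intermittency-map trajectories with known exponents."""
    out = {}
    for z in (1.7, 2.0, 2.5):
        cfg = hc.CriticalMapConfig(z=z, n=1_000_000, seed=5)
        out[z] = hc.scan_phiR(hc.iterate_map(cfg))
    return out


@pytest.fixture(scope="session")
def rest_trace(sweep_traces):
    return sweep_traces[0.0]["trace"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
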