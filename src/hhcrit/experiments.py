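"""Study pipelines composing the simulator with the MCF analysis.

These reproduce, at configurable scale, the computational experiments
of the study: the external-current sweep with per-series criticality
exponents, the two empirical relations (p2 vs Iex, firing rate vs
p2 - 1), the white-noise addition experiment, the K+-blockade variant,
and the membrane-potential histogram / bifurcation summary.

Defaults are a desk-scale profile (tens of seconds per series, a few
currents); the full study protocol (13 currents x 3 replicates x
>100 s) is the same code at larger arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gillespie import (SimConfig, VoltageTrace, add_noise, detect_spikes,
                        downsample, remove_spikes, simulate)
from .hh import ModelParams, find_fixed_point
from .mcf import MCFResult, scan_phiR, turning_points, estimate_phi0

__all__ = [
    "SWEEP_CURRENTS_FULL", "SWEEP_CURRENTS_CI",
    "RelationFit", "analyze_trace", "simulate_downsampled",
    "run_sweep", "fit_relations", "noise_experiment",
    "blocked_K_experiment", "bifurcation_summary",
]

# the study's 13 current densities (uA cm^-2) and the desk-scale subset
SWEEP_CURRENTS_FULL = (-0.2, -0.1, -0.05, 0.0, 0.05, 0.1, 0.15,
                       0.2, 0.25, 0.27, 0.3, 0.32, 0.35)
SWEEP_CURRENTS_CI = (-0.2, 0.0, 0.2, 0.3, 0.35)

SUBTHRESHOLD_CAP = -40.0   # mV; everything above is spike territory


def _child_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base_seed)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def analyze_trace(trace: VoltageTrace, sub_cap: Optional[float] =
                  SUBTHRESHOLD_CAP, grid_size: int = 40,
                  flip: bool = False, **mcf_kwargs) -> MCFResult:
    """Run the MCF pipeline on a (downsampled) voltage trace.

    The fixed-point estimate and the PhiR grid are restricted to the
    subthreshold regime (below ``sub_cap``): spikes terminate laminar
    runs but play no role in delimiting the laminar region.  ``flip``
    negates the series for regimes where the stable point sits at the
    top of the fluctuation band (K+-blocked plateau).
    """
    x = np.asarray(trace.values, dtype=float)
    if flip:
        x = -x
        sub_cap = None
    sub = x[x < sub_cap] if sub_cap is not None else x
    tv = turning_points(x)
    tv_sub = tv[tv < sub_cap] if sub_cap is not None else tv
    phi0, binw = estimate_phi0(tv_sub)
    upper = float(np.quantile(sub, 0.999))
    return scan_phiR(x, phi0=phi0, bin_width=binw, upper=upper,
                     grid_size=grid_size, rate=trace.rate, **mcf_kwargs)


def simulate_downsampled(iex: float, duration_s: float, seed: int,
                         params: ModelParams = ModelParams(),
                         v0: Optional[float] = None,
                         out_rate: float = 3125.0) -> VoltageTrace:
    cfg = SimConfig(params=params, Iex=iex, duration_s=duration_s,
                    seed=seed, V0=v0, out_rate=out_rate)
    return downsample(simulate(cfg), out_rate)


def run_sweep(currents: Sequence[float] = SWEEP_CURRENTS_CI,
              n_replicates: int = 2, duration_s: float = 20.0,
              base_seed: int = 0,
              params: ModelParams = ModelParams(),
              verbose: bool = False) -> pd.DataFrame:
    """Simulate + analyze one series per (current, replicate).

    Individual failures are recorded (``failed=True``) and the sweep
    continues.  Deterministic for a fixed base_seed.
    """
    rows = []
    for ci, iex in enumerate(currents):
        for rep in range(n_replicates):
            seed = _child_seed(base_seed, ci, rep)
            row = {"Iex": iex, "replicate": rep, "seed": seed,
                   "failed": False}
            try:
                tr = simulate_downsampled(iex, duration_s, seed, params)
                spikes = detect_spikes(tr)
                res = analyze_trace(tr)
                best = res.best
                row.update(
                    p2=best.p2 if best else np.nan,
                    p3=best.p3 if best else np.nan,
                    r2=best.r2 if best else np.nan,
                    phi0=res.phi0,
                    phiR=best.phiR if best else np.nan,
                    n_lengths=best.n_lengths if best else 0,
                    firing_rate=spikes.firing_rate,
                    n_spikes=len(spikes),
                    is_critical=res.is_critical,
                )
            except Exception as exc:   # keep sweeping
                row.update(failed=True, error=str(exc), p2=np.nan,
                           p3=np.nan, r2=np.nan, firing_rate=np.nan,
                           is_critical=False)
            if verbose:
                print(f"Iex={iex:+.2f} rep={rep}: "
                      + (f"p2={row.get('p2', np.nan):.3f} "
                         f"p3={row.get('p3', np.nan):.4f} "
                         f"rate={row.get('firing_rate', np.nan):.2f} Hz"
                         if not row["failed"] else "FAILED"))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RelationFit:
    """A fitted empirical relation across sweep rows."""
    kind: str                  # 'linear_p2_vs_I' | 'exp_rate_vs_p2minus1'
    coefficients: tuple        # (intercept, slope) / (a, b): a*exp(b*(p2-1))
    r2: float
    n: int


def _ols(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    pred = intercept + slope * x
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return intercept, slope, r2


def fit_relations(table: pd.DataFrame, p3_max: float = 0.02):
    """Fit p2 ~ Iex (linear) and firing rate ~ exp(b*(p2-1)).

    Only rows in or near the critical regime (p3 <= p3_max) enter the
    linear fit; the exponential relation uses spiking rows and is fitted
    as a linear regression on the log rate, matching the theoretical
    form ln(rate) ~ (p2 - 1).
    """
    df = table[~table["failed"]].dropna(subset=["p2", "p3"])
    near = df[df["p3"] <= p3_max]
    if len(near) < 6:
        raise ValueError("need >= 6 critical/near-critical rows")
    ic, sl, r2 = _ols(near["Iex"].to_numpy(), near["p2"].to_numpy())
    linear = RelationFit("linear_p2_vs_I", (ic, sl), r2, len(near))
    spiking = df[df["firing_rate"] > 0]
    if len(spiking) < 2:
        import warnings
        warnings.warn("fewer than 2 spiking rows: exponential fit skipped")
        return linear, None
    x = spiking["p2"].to_numpy() - 1.0
    y = np.log(spiking["firing_rate"].to_numpy())
    ic, sl, r2 = _ols(x, y)
    expo = RelationFit("exp_rate_vs_p2minus1", (float(np.exp(ic)), sl),
                       r2, len(spiking))
    return linear, expo


def noise_experiment(iex: float = 0.0,
                     relative_sds: Sequence[float] = (0.1,),
                     seeds: Sequence[int] = (0,),
                     duration_s: float = 20.0,
                     params: ModelParams = ModelParams(),
                     base_seed: int = 0) -> pd.DataFrame:
    """MCF exponents before/after white-noise addition.

    Noise is zero-mean Gaussian with sigma = relative_sd * sd of the
    spike-removed trace, added to the 3125 Hz series; both analyses
    re-estimate Phi0 and PhiR independently.
    """
    rows = []
    for si, seed_key in enumerate(seeds):
        seed = _child_seed(base_seed, 11, si, int(seed_key))
        tr = simulate_downsampled(iex, duration_s, seed, params)
        before = analyze_trace(tr)
        for sd in relative_sds:
            noisy = add_noise(tr, sd, rng=np.random.default_rng(
                _child_seed(base_seed, 13, si, int(round(sd * 1e6)))))
            after = analyze_trace(noisy)
            rows.append({
                "Iex": iex, "seed": seed, "relative_sd": sd,
                "p2_before": before.best.p2 if before.best else np.nan,
                "p3_before": before.best.p3 if before.best else np.nan,
                "p2_after": after.best.p2 if after.best else np.nan,
                "p3_after": after.best.p3 if after.best else np.nan,
                "critical_before": before.is_critical,
                "critical_after": after.is_critical,
            })
    return pd.DataFrame(rows)


def blocked_K_experiment(duration_s: float = 10.0, seed: int = 0,
                         params: ModelParams = ModelParams(),
                         plateau_v0: float = -20.0,
                         transient_s: float = 0.5,
                         noise_sd: float = 0.1) -> dict:
    """The K+-channel blockade experiment.

    (i) At rest the subthreshold dynamics of the blocked model match the
    full model (K+ current is negligible between spikes); (ii) once
    depolarized past threshold the blocked model cannot repolarize and
    fluctuates around a supra-threshold plateau, whose fluctuations are
    not critical -- and white-noise addition does not rescue them.
    """
    blocked = params.blocked()
    s1 = _child_seed(seed, 21)
    full_tr = simulate_downsampled(0.0, duration_s, s1, params)
    blocked_tr = simulate_downsampled(0.0, duration_s, s1, blocked)
    full_res = analyze_trace(full_tr)
    blocked_res = analyze_trace(blocked_tr)

    plateau_tr = simulate_downsampled(0.0, duration_s,
                                      _child_seed(seed, 22), blocked,
                                      v0=plateau_v0)
    cut = int(round(transient_s * plateau_tr.rate))
    plateau = VoltageTrace(rate=plateau_tr.rate,
                           values=plateau_tr.values[cut:],
                           t_start=transient_s, meta=dict(plateau_tr.meta))
    plateau_res = analyze_trace(plateau, flip=True)
    noisy = add_noise(plateau, noise_sd,
                      rng=np.random.default_rng(_child_seed(seed, 23)))
    noisy_res = analyze_trace(noisy, flip=True)
    v_plateau_det = find_fixed_point(0.0, blocked, v_lo=-40.0, v_hi=5.0)
    return {
        "subthreshold": {
            "full": full_res, "blocked": blocked_res,
            "verdicts_match": full_res.is_critical ==
                              blocked_res.is_critical,
        },
        "plateau": {
            "mean_mV": float(np.mean(plateau.values)),
            "sd_mV": float(np.std(plateau.values)),
            "deterministic_root_mV": float(v_plateau_det),
            "mcf": plateau_res,
            "mcf_after_noise": noisy_res,
        },
    }


def bifurcation_summary(currents: Sequence[float] = (-0.2, 0.0, 0.2, 0.3),
                        duration_s: float = 10.0, base_seed: int = 0,
                        params: ModelParams = ModelParams(),
                        bins: int = 100) -> dict:
    """Membrane-potential histograms vs the deterministic fixed point.

    For each subthreshold current: the mode and spread of the (spike-
    removed) voltage distribution against the deterministic resting
    potential Vr(Iex); depolarization moves the mode toward the
    bifurcation and widens the distribution (critical slowing down).
    A K+-blocked supra-threshold histogram is reported alongside.
    """
    rows = []
    for ci, iex in enumerate(currents):
        seed = _child_seed(base_seed, 31, ci)
        tr = simulate_downsampled(iex, duration_s, seed, params)
        spikes = detect_spikes(tr)
        sub, _ = remove_spikes(tr, spikes)
        counts, edges = np.histogram(sub.values, bins=bins)
        mode = float(0.5 * (edges[np.argmax(counts)]
                            + edges[np.argmax(counts) + 1]))
        rows.append({"Iex": iex, "seed": seed,
                     "mode_mV": mode,
                     "mean_mV": float(np.mean(sub.values)),
                     "sd_mV": float(np.std(sub.values)),
                     "Vr_mV": find_fixed_point(iex, params)})
    blocked = params.blocked()
    btr = simulate_downsampled(0.0, duration_s, _child_seed(base_seed, 32),
                               blocked, v0=-20.0)
    cut = int(round(0.5 * btr.rate))
    bvals = btr.values[cut:]
    return {
        "table": pd.DataFrame(rows),
        "blocked_plateau": {"mean_mV": float(np.mean(bvals)),
                            "sd_mV": float(np.std(bvals))},
    }
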