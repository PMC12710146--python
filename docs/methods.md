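# Methods

## Membrane model

Space-clamped Hodgkin–Huxley membrane with a type-I (integrator)
parameter set: C = 1 µF/cm², ḡ_Na = 50, ḡ_K = 10, g_L = 0.187 mS/cm²,
E_Na = 50, E_K = −95, E_L = −63.563 mV, channel densities ρ_Na = 60,
ρ_K = 18 µm⁻² on A = 30 µm² (1800 Na⁺, 540 K⁺ channels).  The rate
functions α_x(V), β_x(V) are the standard linear-over-exponential
forms; at their removable singularities (V = −50, −52, −25 mV) the
code switches to a first-order Taylor expansion inside |ΔV| < 10⁻⁶ mV,
which removes platform-dependent cancellation.  The small area is the
point, not a compromise: channel-number fluctuations must be large
enough to produce millivolt-scale subthreshold noise.

Deterministic analyses (fixed points, voltage clamp, rheobase) use the
same rate functions.  `find_fixed_point` brackets the steady-state
current balance on a voltage grid and polishes the stable root
(negative slope) with Brent's method to |F| < 10⁻¹⁰.
`find_bifurcation` bisects the applied current between "stable fixed
point, no repetitive firing" and "repetitive firing" to 10⁻⁴ µA/cm²;
firing is declared when the RK4 trajectory (dt = 0.01 ms) crosses 0 mV
upward at least twice after a 100 ms transient.  With the default
parameters this gives I_c ≈ 0.358 µA/cm² and V_c ≈ −33.9 mV, so the
entire stochastic sweep (−0.2 … 0.35 µA/cm²) is subthreshold: all
spiking in the stochastic model is fluctuation-driven.

## Exact stochastic simulation

Channels are aggregated into 13 states (Na⁺: m_i h_j, i ≤ 3, j ≤ 1;
K⁺: n_k, k ≤ 4); the 28 one-gate transitions carry the scheme's
combinatorial multiplicities (3α_m, 2β_m, 4α_n, …) in a fixed canonical
order so event indices and seeded runs are reproducible.  Each
iteration draws the dwell time ttr = ln(1/r₁)/λ from the total
propensity λ = Σψ, advances V over the dwell interval with the exact
exponential solution of the (then linear, frozen-conductance) membrane
equation, fills the 200 kHz grid samples inside the interval from the
same closed form, then selects the fired transition by inverse-CDF on
the propensity vector (right-inclusive, matching the r₂ ∈ [0, λ]
convention) and updates the counts.  Single-channel conductance is
ḡ/N, i.e. the macroscopic conductance is ḡ times the open fraction.
r₁ is drawn from (0, 1] so the logarithm is always defined.  The event
loop is numba-compiled (~2.5·10⁶ events/s on one core; a resting
membrane generates ≈ 2.5·10⁶ transitions per simulated second).
Initial channel states are drawn from the equilibrium binomial-product
distribution at V₀ (default: the deterministic resting potential), one
independent categorical draw per channel, which keeps totals exact and
minimizes transients.

Downsampling to 3125 Hz keeps every 64th sample with no anti-alias
filter: the analysis needs the raw fluctuation statistics at the
coarser timescale, and low-pass filtering would correlate neighbouring
samples and distort run lengths.  Spike detection uses upward crossings
of −20 mV with a 2 ms lockout; spike excision removes a configurable
window (default ±10 ms) and reports the join indices so run-based
analyses never span a cut.

## MCF estimator

* **Fixed point Φ₀** — histogram of the turning-point (local extrema)
  values, 100 bins; scanning from the left, Φ₀ is the left edge of the
  first bin reaching 20 % of the maximal count.  For membrane traces
  the histogram and the Φ_R grid are restricted to the subthreshold
  regime (< −40 mV); spikes only terminate runs.  Exact-tie plateaus
  contribute one extremum at their midpoint.
* **Band scan** — 40 equally spaced Φ_R candidates from Φ₀ + 2 bin
  widths to the 99.9th percentile of the (spike-removed) series.
* **Distribution and fit** — laminar lengths are kept in samples and
  log-binned (geometric edges, ratio 1.35, integer-aligned so short
  lengths get exact bins); the density is fitted in log space by
  trust-region-reflective least squares with bounds p1 > 0,
  p2 ∈ [0, 5], p3 ∈ [0, 1], multi-start on (p2, p3) ∈ {1.0, 1.5} ×
  {10⁻⁴, 0.01}, and Poisson inverse-variance weights (residuals scaled
  by √count).  Bins below ℓ = 4 samples are excluded: a run of one to
  three samples reflects the sampling grid more than the dynamics, and
  the power law of the theory is an asymptotic statement.  ℓ_min is the
  smallest value at which the map-oracle recovery (below) holds; it is
  exposed as an option because it shifts p2.  Weighted R² in log space
  is the goodness measure.  Fits need ≥ 50 lengths and ≥ 5 distinct
  values; non-convergence is flagged, not raised.
* **Selection and verdict** — every fit with p3 ≤ 0.005 counts as
  "p3 ≈ 0"; among them the best weighted R² wins, otherwise the literal
  p3 minimum (ties by R²).  A literal argmin-p3 rule degenerates: very
  wide bands produce few, long runs whose flat distribution fits with
  p3 → 0 and meaningless p2.  The series is called critical when the
  chosen p2 exceeds 1 and p3 ≤ 0.005 holds on ≥ 3 consecutive grid
  points.  On simulated traces this selection lands on the same
  (Φ₀, Φ_R) pairs the original figures report (rest: −63.55/−62.98 vs
  −63.55/−62.9; strongest depolarization: −61.48/−59.45 vs
  −61.5/−59.46).

## Synthetic map generator

`critical_map` iterates Φ_{n+1} = Φ_n + uΦ_n^z + ε on [0, 1] with
uniform reinjection into [0, 1) once the update exceeds 1.  Its job is
to be a *ground-truth oracle* for exponent recovery, which dictates the
defaults:

* **u = 30** — the laminar phase must end abruptly for the observed
  waiting times to be a clean power law.  The exact escape-time
  distribution is P(ℓ) ∝ (c + (z−1)uℓ)^(−z/(z−1)) with
  c = Φ_R^(1−z); for u of order 1 the shift c/((z−1)u) is one to two
  samples and biases any finite-window fit of p1ℓ^(−p2)e^(−ℓp3) low by
  0.2–0.6.  At u = 30 the shift is a few hundredths of a sample and
  recovery is unbiased from ℓ = 1.
* **ε Gaussian (sd 10⁻⁶), reflected at 0** — the noise term stands for
  finite-size fluctuations, the aggregate of many microscopic
  contributions, and its soft cutoff of the longest laminar phases is
  exactly the exponential correction e^(−ℓp3) the fit model carries.
  One-sided uniform noise (available as an option) instead caps the
  lengths with a hard wall the fit cannot represent.  The width sets
  the cutoff scale; 10⁻⁶ leaves 2–4 clean decades at n = 10⁶.

With these defaults the full pipeline recovers p = z/(z−1) within
±0.1 for z ∈ {1.7, 2.0, 2.5} (measured: 2.47/2.43, 2.06/2.00,
1.67/1.67) with p3 ≤ 0.005, while i.i.d. Gaussian input is rejected.
What the oracle does *not* emulate: the temporal correlation of a
membrane trace, spike excursions, or band entry from the boundary
rather than by reinjection.

## Study pipelines and problem sizes

The experiment layer composes simulate → downsample → spike detection →
MCF.  Desk-scale defaults: 20 s series for non-spiking currents, 30 s
for spiking ones, currents {−0.2, 0, 0.2, 0.3, 0.35} µA/cm², three
replicates in the acceptance script (the original protocol is 13
currents × ≥3 replicates × >100 s; the same code runs it by changing
arguments).  Noise addition draws zero-mean Gaussian samples with
sd = 0.1 × sd(spike-removed trace) and re-estimates Φ₀/Φ_R from
scratch on the noisy series.  The K⁺-blockade experiment (i) compares
full and blocked models at rest under matched seeds and (ii) starts the
blocked model at −20 mV, discards 0.5 s of transient and analyzes the
plateau; because the stable point there sits at the *top* of the
fluctuation band, the plateau series is negated before MCF so the
fixed point is again a left edge.  The blocked-model current balance
has its depolarized stable root at −8.42 mV; the stochastic plateau
mean is −8.3 ± 0.3 mV across seeds.

## Numerical choices and degenerate inputs

Voltage never leaves [E_K, E_Na] (the exponential update relaxes toward
a convex combination of reversal potentials for the sweep's currents).
λ = 0 (possible only in channel-free configurations) freezes the trace
at its closed-form relaxation; negative counts raise immediately.
Constant series yield no turning points and an estimation error rather
than a silent Φ₀.  All randomness flows from explicit seeds: the
simulator from `SimConfig.seed` (per-segment streams for staircase
protocols), the pipelines from `SeedSequence`-derived child seeds, so
every table in the tests and the acceptance script is bit-reproducible.

## Limitations

* The absolute p2 calibration at depolarized currents falls short of
  the original report.  Our traces reproduce the original turning-point
  histograms (Φ₀ within 0.1 mV at every current), firing behaviour,
  fluctuation growth, and every qualitative relation — p2 increasing
  with current, hyperpolarized series exponential (p2 ≈ 0.46–0.55 with
  clearly positive p3), noise enhancement at I_ex ≥ 0 but not for
  hyperpolarized series, blocked-K equivalence at rest — but the fitted
  exponents at 0.3–0.35 µA/cm² are ≈ 0.7–0.9 against the reported
  1.125–1.18, and consequently spiking series fall just short of the
  p2 > 1 criticality verdict.  The gap is robust to fit space,
  weighting, binning, minimum length, spike excision, block-average vs
  decimation downsampling, halved sampling rates, durations 20–100 s
  and seeds; the original least-squares configuration (fit space,
  weights, fitted range, sample vs ms units) is not described at the
  level needed to reproduce its calibration, and we chose not to tune
  the estimator per published value at the cost of the map-oracle
  validation.  Conclusions that depend only on orderings and verdict
  contrasts are unaffected.
* The p3 ≤ 0.005 tolerance (per sample) and the 3-consecutive-points
  rule operationalize "p3 ≈ 0 over a range"; the original threshold is
  unstated.
* Replicate scatter of p2 at 20–30 s is ±0.05–0.1 (larger at rest,
  where a series yields only ~700 laminar lengths); the acceptance
  script therefore averages three replicates per current.
* The membrane is space-clamped: no cable structure, no channel
  clustering, no synaptic input, no pump dynamics, temperature fixed.
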