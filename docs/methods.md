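# Methods

## Two-compartment turnover model (`arcloop.kinetics`)

Arc mRNA (`M`) and protein (`P`) are modeled in baseline-normalized units
(basal steady state = 1) with zero-order transcription and first-order
decay, translation and degradation:

    dM/dt = r·u_tx − (k_nt + k_tdd·u_tl)·M
    dP/dt = k_tl·u_tl·M − k_p·P

Pharmacology enters only through the transcription scale `u_tx` and the
translation scale `u_tl`, both in [0, 1]. The defining kinetic feature is
translation-dependent decay (TDD): the mRNA decay component `k_tdd` is
gated by translation, so a translation block (cycloheximide, `u_tl = 0`)
simultaneously halts protein synthesis and stabilizes the message. The TDD
term is taken to scale *linearly* with `u_tl`; the data only probe
`u_tl ∈ {0, 1}`, so linear interpolation is the simplest contract for
intermediate values.

Default rate constants (1/h), chosen so that both basal steady states are
exactly 1:

| parameter | default | meaning |
|---|---|---|
| `r` | 1.6 | transcription (normalized abundance/h) |
| `k_nt` | 0.98 | translation-independent mRNA decay |
| `k_tdd` | 0.62 | translation-dependent mRNA decay |
| `k_p` | √(1.6² − 0.8²) ≈ 1.3856 | protein degradation |
| `k_tl` | = `k_p` | translation (closes P* = 1) |

`k_p` is kept at the exact quadrature value rather than the rounded
1.36 1/h so that the correction operation and the simulator are mutually
consistent; the rounded value is reproduced within 2%. The total basal
mRNA decay is `k_nt + k_tdd = 1.6` 1/h exactly, and the implied half-lives
are ln2/1.6 ≈ 26 min (mRNA) and ln2/1.3856 ≈ 30 min (protein).

Condition presets: BASAL (1,1), ACTD (0,1), CHX (1,0), ACTD_CHX (0,0),
RAPAMYCIN (1,1; mTORC1 inhibition leaves global Arc turnover unchanged,
so it is bit-identical to BASAL by construction), and TTX (0.625, 1).
The TTX transcription scale 0.625 is back-solved from the observation
that mRNA reaches ~64% of baseline 2 h after activity blockade:
M(2) = 0.625 + 0.375·e^(−3.2) = 0.640, with decay constants unchanged
(passive degradation alone accounts for the loss).

Because the system is piecewise linear, each segment of a drug schedule is
solved in closed form: the mRNA relaxes exponentially to the segment
steady state and the protein is the double-exponential convolution of that
relaxation with its own decay. Degenerate rate combinations (`k_m = 0`,
`k_p = 0`, `k_p = k_m` within 1e-9 relative) take their analytic limits.
Segments are chained with continuous state. The closed form is the
authoritative solver; tests verify agreement with adaptive numeric
integration to 1e-6 relative on randomized parameters and schedules.
Units are hours and % of baseline throughout.

## Rate estimation (`arcloop.estimate`)

The estimation pipeline mirrors how the constants are derived from
inhibitor-chase experiments:

1. **Exponential fits.** Default is ordinary least squares of ln(value) on
   time (`log_linear`); a `nonlinear_plateau` model
   `plateau + (100 − plateau)·e^(−kt)` is available for curves that settle
   above zero (activity-blockade mRNA). Standard errors come from the
   regression (or the curve-fit covariance).
2. **TDD decomposition.** `k_tdd = k_deg − k_deg,CHX`, with the TDD share
   `k_tdd / k_deg`; a negative difference is rejected as unphysical.
3. **Production by balance.** At steady state `r = k_deg · M*`.
4. **Production by accumulation.** Under a translation block the t = 0
   balance is `slope₀ = r − k_nt·M₀`, so `r = slope₀ + k_nt·M₀`. In the
   full pipeline the initial slope is estimated from the first two samples
   of the CHX mRNA curve as a secant corrected for exponential sampling
   bias by the factor `k·Δt / (1 − e^(−k·Δt))` (with `k` the fitted
   `k_nt`); the correction is exact at zero noise, which makes the
   balance- and accumulation-based estimates agree to numerical precision
   on model-generated data. (On the real curves the two estimates differ —
   1.6 vs 1.9 1/h — a feature of the data, not of the pipeline.)
5. **Protein-rate correction.** The apparent protein decay under a
   transcription block (`k_app`, fitted over a configurable window,
   default 0–2 h) underestimates degradation because residual mRNA keeps
   producing protein. Two corrections are offered:
   - `sqrt` (default): `k_p = √(k_deg² − k_app²)`. **This is a local
     approximation**: it is accurate (≲1%) where `k_app ≈ k_deg/2` — the
     regime the experiments actually occupy (0.8 vs 1.6 1/h) — but its
     error grows to tens or hundreds of percent for `k_p ≪ k_deg`. Tests
     assert 5% accuracy only on the valid ridge.
   - `deconvolve`: least-squares fit of the full two-compartment protein
     solution with `k_m` fixed; exact at zero noise for any rate
     combination, and the method of choice away from the operating regime.

Western normalization divides each target band by its reference (phospho
by total; otherwise by a loading control) and expresses the ratio as % of
the control-group mean ratio. qPCR uses delta-delta-Ct with a default
amplification efficiency of 2.0 fold/cycle (not experimentally
constrained; configurable).

## Closed feedback loop (`arcloop.feedback`)

The homeostatic loop couples five stages. The wiring
(activity → Ca → ERK → Arc transcription → Arc protein → synaptic weight
→ activity) is fixed by the biology; the functional forms below are this
package's minimal choices that reproduce the fixed point and the observed
timing:

- activity (algebraic): `a = a0 · drive · w · s_na`;
- calcium sensor: `c = s_ca · a/a0` (NMDAR and L-VGCC lumped into one
  factor — their separate contributions are not quantified);
- ERK controller: `de/dt = (u_erk·c − e)/tau_e`;
- transcription actuator: `r_eff = r·(beta + (1 − beta)·e^n_hill)`;
- turnover: the two-compartment model above with `u_tx = u_tl = 1`;
- plant: `dw/dt = −k_w·eta·(p − 1)·w`, clipped softly to `w_bounds`
  (derivative zeroed at the bounds to avoid stiff discontinuities).

The interior fixed point exhibits exact adaptation: for any sustained
drive `D` with `1/D` inside the weight bounds, the unique equilibrium is
`a = a0`, `e = m = p = 1`, `w = 1/D`.

The floor `beta = 0.625` ties the loop to the open-loop TTX preset with no
extra parameters: with spiking silenced, transcription falls to
`r·beta`, reproducing the 64%-at-2-h mRNA landmark and an initial mRNA
slope of −0.6 1/h — about 3-fold slower than the −1.6 1/h seen under a
full transcription block.

Defaults: `a0 = 7.52` Hz (baseline network rate), `D_ptx = 3`
(disinhibition), `n_hill = 2`, `k_w = 0.15` 1/h, `w_bounds = (0.1, 3)`,
`tau_e = 0.5` h, `eta = 1`. `tau_e` and `k_w` were calibrated once, as a
documented step, against the picrotoxin landmarks (mRNA peak 2 ± 0.5 h,
spike-rate recovery within 12 h); with these values the simulator gives an
ERK peak at 1.4 h, mRNA peak at 2.05 h, protein peak at 2.8 h and
spike-rate recovery (10% band) at 5.8 h, with a slight undershoot of the
baseline afterwards (minimum ≈ 99% of baseline; observed but not asserted,
since its depth is not experimentally quantified). `D_tsc = 20` for the
Tsc1-knockout preset is chosen above `1/w_min = 10` so that synaptic
down-scaling saturates and cannot absorb the perturbation, leaving the
loop tonically engaged (`e, p > 1`) — blocking spiking or the calcium
sensor then collapses transcription to the `beta` floor.

Drug presets that the experiments applied on the picrotoxin background
(U0126, CPP+nimodipine, MPEP, AIDA, NASPM, rapamycin) include the PTX
drive step; MPEP/AIDA/NASPM/rapamycin change no parameter and are
therefore bit-identical to PTX. The mTOR arm is represented only by this
rapamycin no-op; p-S6 dynamics are not modeled. Integration is LSODA with
rtol 1e-8, with protocol events applied exactly at their breakpoints;
output is sampled on a regular grid (default 0.05 h).

## MEA spike detection (`arcloop.mea`)

Multi-unit spikes are detected per channel as the first sample whose
absolute voltage reaches a fixed ±0.009 mV threshold (inclusive, both
polarities), followed by a 2 ms refractory dead time so one biphasic
waveform is counted once. No spike sorting or trough alignment is
performed. The summary statistic is the mean over channels of each
channel's count/duration. Noise scale is estimated robustly as MAD/0.6745.

**Threshold geometry.** The 0.009 mV threshold is "2× baseline", where
baseline is read as the noise *envelope* (~3σ), giving a noise sd of
0.0015 mV and a 6σ threshold. This reading is forced by level-crossing
statistics: for Gaussian noise at threshold `u`, the expected
suprathreshold rate is ~`2·Φ̄(u/σ)·f_s`; at 2σ that is ≈ 9×10² events/s
at 20 kHz — a detector operating there would be all noise — while at 6σ it
is ≈ 4×10⁻⁵ events/s (≈ 0.01 crossings per channel per 2-minute
recording), matching the observation that a silenced culture registers
zero spikes. An adaptive per-channel threshold (multiple × MAD estimate)
is available as an option. The synthetic-trace sampling rate defaults to
20 kHz (not experimentally stated).

A burst metric (fraction of spikes in runs of ≥ 3 spikes with ISIs
≤ 100 ms) quantifies the bursting firing pattern; the thresholds are
conventions, as bursts were shown but not quantified.

## Synthetic data (`arcloop.synth`)

Generators are pure functions of an explicit integer seed.

- **Time-course tables** multiply deterministic trajectories by i.i.d.
  unit-mean noise factors per (time, replicate, analyte). Default noise is
  multiplicative lognormal with CV 0.10 and 3 replicates — %-of-baseline
  western/qPCR readouts are ratio-scale and strictly positive, and the
  reported error bars are of roughly this size, but no CV is stated, so
  this is an assumption. A zero-truncated Gaussian alternative is
  provided. Default sampling grids: {0, 0.5, 1, 2, 4, 6} h for inhibitor
  chases, {0, 0.5, 1, 2, 6, 12, 24, 48} h for activity protocols
  (figure-apparent designs; configurable).
- **qPCR tables** plant relative quantities as Ct pairs invertible by
  delta-delta-Ct, with Gaussian Ct noise in cycles.
- **Recordings** are Gaussian baseline noise plus a biphasic template (one
  cycle of a damped sine, 1.5 ms — an invented but typical extracellular
  waveform) at Poisson, bursting, or user-supplied times; ground-truth
  times are returned alongside.

What the generators do *not* emulate: blot saturation/nonlinearity,
primer-efficiency variation, electrode cross-talk, spike-waveform
diversity or overlap sorting, and non-stationary network states. Passing
round trips therefore demonstrate estimator correctness under the model's
own assumptions, not robustness to these real-data features.

## Numerical conventions and degenerate inputs

- Hours and % of baseline everywhere; rate constants in 1/h.
- `peak_time` breaks ties toward the earliest time; `recovery_time`
  requires the variable to stay inside the band through the end of the
  trajectory and returns a sentinel (None) otherwise.
- `u_tx = u_tl = 0` with `k_nt = 0` freezes the mRNA pool: simulation
  proceeds, steady-state queries raise.
- Log-linear fits require strictly positive values and ≥ 3 points;
  constant series fit `k = 0` exactly.
- Problem sizes used by the shipped checks (5-point chases, 200
  Monte-Carlo tables, 48-h loop simulations at 0.05-h output steps,
  10-s × 4–8-channel recordings) were chosen as the smallest designs that
  exercise every code path at stable statistics.

## Known limitations

- The quadrature protein-rate correction is valid only near its operating
  regime (see above); use `method="deconvolve"` elsewhere.
- The calcium sensor is a single lumped factor; receptor subtypes,
  mGluR-dependent local translation, and nuclear Arc are out of scope.
- Abundances are deterministic means — no intrinsic (Gillespie) noise.
- The prose half-lives sometimes quoted for these species (~45/~90 min)
  are figure-read values inconsistent with ln2/k of the printed constants
  (26/52 min apparent); the package works exclusively with the rate
  constants.
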