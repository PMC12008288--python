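# Methods

## Model

Brain activity is treated as a linear time-invariant network system.
A state is the vector `x(t)` of regional BOLD amplitudes at one fMRI
volume (N regions; the canonical layout is 116 = 100 cortical + 16
subcortical parcels, TR = 2 s). Dynamics follow

    dx/dt = A x(t) + B u(t)

with `A` derived from the weighted structural connectome and
`B = diag(v)` a diagonal control strategy. For every pair of adjacent
volumes `(x0, xf)` the minimum-energy input steering the system from
`x0` to `xf` over a horizon `T` is

    u*(t) = Bᵀ e^{Aᵀ(T−t)} W_T⁻¹ d,    d = xf − e^{AT} x0,
    W_T   = ∫₀ᵀ e^{As} B Bᵀ e^{Aᵀs} ds,

giving regional energies `E_i = ∫₀ᵀ u_i*(t)² dt`, network energies
(sums over the seven Yeo networks plus subcortex), and the global
minimum energy `E_min = Σ_i E_i = dᵀ W_T⁻¹ d`. Repeating this over all
V − 1 adjacent-volume transitions yields an energy time-series per
subject and condition.

Assumptions worth keeping in mind: linearity of the dynamics, a common
structural network across subjects, transitions treated independently
with a fixed horizon, and BOLD amplitude as a meaningful state variable
(un-normalized energy scales quadratically with state magnitude — the
state-normalization variants below exist precisely to separate
magnitude from geometry).

## Stabilization of A

The raw connectome `W` (nonnegative, symmetric, zero diagonal) is
mapped to

    A = W / (λ_max(W) + c) − I,    c > 0 (default 1),

placing all eigenvalues in `[−2, −c/(λ_max + c)]`. This is the standard
continuous-time convention in the network-control literature this
analysis descends from; `c` (config `stabilization.c`) sets how close
the slowest mode sits to marginal stability. Matrices failing symmetry
beyond 1e−8 relative are rejected rather than silently symmetrized;
asymmetries below that are averaged away.

## Numerics

- **Gramian:** Van Loan's block matrix-exponential identity — one
  `expm` of a 2N × 2N block matrix per (A, B, T); symmetrized and
  Cholesky-factorized. Condition numbers above 1e12 log a warning and
  fall back to nothing more exotic than the symmetric solve.
- **Trajectory integral:** `u*(t)` is evaluated on a uniform grid of
  `integration_steps` points (default 1001, odd) and `E_i` integrated
  with composite Simpson. Simpson rather than trapezoid because the
  package asserts agreement between the integrated `Σ E_i` and the
  closed form `dᵀW⁻¹d` at 1e−6 relative; trapezoid at 1001 points sits
  right at that boundary (~1.4e−6) while Simpson reaches ~1e−10 at the
  same cost. The odd-grid constraint is what Simpson needs.
- **Propagator reuse:** the grid propagators `e^{Aᵀ(T−t_k)}` depend
  only on (A, T, grid) and are computed once by stable forward
  stepping, then shared across all transitions, subjects and schedule
  columns. Gramians are factorized once per unique schedule column
  (uniform schedules therefore use exactly one).
- **Degenerate inputs:** zero transitions give exactly zero energy;
  non-finite states, non-positive control weights, and mismatched
  shapes raise immediately.

## State normalization variants

Four variants besides `none`: `radial` rescales only the target state
along `xf − x0` to unit inter-state distance (the source state is the
anchor); `l2` divides every state by its own norm; `distance` divides
both states of a pair by their distance; `double` applies `l2` then
`distance`. The pairwise variants break the chain property (a volume no
longer has a single scale), so normalized series store explicit
(x0, xf) pairs per transition; energy code consumes either layout.
Zero-norm states and zero-distance pairs are errors, not skips.

## Signal diversity

Each 2-s epoch of each channel is binarized at its own mean (strict
`>`, ties to 0) and parsed with the Lempel–Ziv 1976 exhaustive history:
each word is the shortest extension not reproducible from the text
preceding its final symbol (overlapping copies allowed). The count is
the raw dictionary size, averaged across channels per epoch; no length
normalization is applied. An O(n³) explicit-enumeration parser
(`lz76_bruteforce`) ships alongside as an independent oracle; the two
agree on all 8190 binary strings of length ≤ 12.

For alignment to the volume grid the series is convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, 32 s
support, unit sum; all config-exposed) sampled at the epoch rate, then
mapped to volumes — one-to-one when epochs and TR are both 2 s,
block-averaged when the epoch rate is an integer multiple of the volume
rate.

## Inference

- **Condition contrast:** cluster-based paired permutation test.
  Per-time-point paired t statistics are thresholded at the two-tailed
  t critical value for α = 0.05; contiguous same-signed supra-threshold
  runs are clusters scored by the sum of t (mass). The null is the
  maximum |mass| over random per-subject sign flips (both tails), which
  controls the familywise error over time; calibration simulations in
  the test-suite confirm the nominal rate. The cluster-forming
  statistic (paired t) and threshold are config-exposed since field
  practice varies.
- **Correlations:** Spearman, two-tailed permutation p-values with the
  add-one convention `(1 + #exceed)/(1 + n_perm)`. With a covariate of
  non-interest (e.g. framewise displacement) both variables are
  rank-transformed, residualized on the ranked covariate by least
  squares, and the residuals correlated. Benjamini–Hochberg step-up
  correction (via statsmodels) across test families.
- **Spatial maps:** spin permutations — uniform random 3-D rotations of
  the cortical parcel centroids on the unit sphere, greedy
  nearest-neighbour reassignment (duplicates allowed) — preserve the
  map's spatial autocorrelation while randomizing anatomy. Subcortical
  parcels cannot be spun: associations including them report rho
  without a p-value. Precomputed permutation index arrays can be
  supplied directly, so published atlas spins plug in bit-exactly.
- **Dominance analysis:** OLS over all 2^p − 1 predictor subsets.
  A predictor's total dominance averages its R² increment — within each
  subset size, then across sizes — over all subsets excluding it;
  percent importance divides by the full-model R², so importances sum
  to 100. Increments use unadjusted R² (the canonical algorithm);
  the full-model adjusted R² is reported alongside by callers that want
  it. Collinear designs are rejected.

## Regional metrics

Three per-region maps summarize a drug's spatial fingerprint: (1)
relative post-vs-pre change in mean energy over equal windows either
side of the injection (default 8 min, clamped to the data; the
"adjusted by" arithmetic is the ratio form — the absolute difference is
available via `relative=False`); (2) Spearman coupling of each region's
group-mean energy series with the aligned diversity series; (3) the
same for per-minute windowed energy against intensity ratings (the
rating at the end of minute m pairs with the window covering minute m;
trailing partial windows are dropped, never padded). Group-mean series
are correlated, not per-subject averages of correlations.

## Pharmacokinetics and the time-varying strategy

Plasma concentration follows a linear mammillary model (1–3
compartments, zero-order infusion over 30 s, optional flush input),
solved exactly between breakpoints with an augmented matrix
exponential. An effect compartment `dCe/dt = ke0 (Cp − Ce)` lags the
plasma curve and stands in for biophase concentration. Default
parameters are a documented synthetic two-compartment set (V = 30/60 L,
k10 = 0.8, k12 = 0.6, k21 = 0.3 /min, ke0 = 0.5 /min, 20 mg over
30 s) — plausible for a rapidly redistributing tryptamine but not
literature estimates; externally simulated curves can be imported as
TSV to reproduce a published model bit-exactly.

The control schedule applies only to post-injection transitions
(pre-injection is uniform, v = 1): additive mode
`v_i(t) = 1 + α(c̃(t) + ρ̃_i)` (default — it is the printed equation
form) or multiplicative `v_i(t) = 1 + α c̃(t) ρ̃_i`. Because
concentration (ng/mL) and receptor density (Bmax, a.u.) have no common
unit, `c̃` is the effect curve rescaled to unit peak and `ρ̃` the
density rescaled to unit mean (both config-exposed), making α
dimensionless. `α` is fitted by grid search (default grid 1, 10, …, 70)
minimizing the Euclidean distance between group-mean simulated and
empirical global energy over the full series (post-injection-only
distance is a config option). Model variants swap effect-site for
plasma concentration or the receptor map for a uniform vector of equal
sum.

## Synthetic study conditions

The generator emulates the scanning design: 116 regions (100 cortical),
14 subjects, 840 volumes at TR = 2 s with injection at volume 240 (end
of minute 8) — these are the defaults; tests and the acceptance script
run reduced geometries noted below. Components:

- **Connectome:** eight modules matching the network assignment,
  weights = within/between-module factor × exponential distance decay ×
  lognormal noise, on seeded 3-D centroids (cortical on the unit
  sphere).
- **Receptor maps:** lognormal transform of a Gaussian process on the
  sphere (squared-exponential kernel in chordal distance, length scale
  0.6 — Moran's I > 0.3; near-iid as the scale → 0). Subcortical
  densities iid.
- **BOLD:** placebo `x_{t+1} = 0.6(0.7 I + 0.3 Ŵ) x_t + ε`,
  `ε ~ N(0, noise_sd²)` — temporally autocorrelated and network-coupled.
  The drug condition shares the placebo noise realization and applies
  the amplitude scale `s_i(t) = 1 − β_s g(t)(γ ρ̃_i + 1 − γ)` with
  `g(t)` a difference-of-exponentials gate (rise 50 s, decay 330 s,
  matching the effect-compartment shape), `ρ̃` the unit-maximum receptor
  map, defaults β = 0.35 (peak fractional damping), γ = 0.8 (receptor
  share), and a per-subject lognormal random effect (σ = 0.15) on β.
  Multiplicative damping was chosen because energy's quadratic
  dependence on amplitude makes the planted effect direction
  analytically predictable, which is what the recovery tests exploit.
- **References:** diversity = 40 − 5·standardized(global energy) +
  N(0,1) noise (inverse coupling by construction); intensity = 0–10
  discretized rise-and-decay on the minute grid, zero pre-injection.

What passing tests on these data do show: the estimator recovers
planted effect directions and magnitudes through the full pipeline,
the statistics are calibrated under the null, and the α grid search
identifies a planted schedule across independent cohorts. What they do
not show: robustness to haemodynamic confounds, head motion,
physiological noise, inter-subject structural variability, or
non-linear neural dynamics — none of which the generator emulates.

## Problem sizes in the shipped checks

The test-suite fixture uses 40 regions / 6 subjects / 240 volumes; the
end-to-end recovery checks use 48 regions (40 cortical) / 8 subjects /
300 volumes with injection at volume 91 (50 seeds for effect
directions, 20 for α recovery), 500–1000 permutations, 300 spins and a
101-point integration grid; `scripts/acceptance.py` runs the same
geometry with 2000 cluster permutations, 10,000 correlation
permutations and 1000 spins. Statistical calibration uses the full 14
subjects × 600 time-points × 200 replicates × 1000 permutations.
These sizes are the package's chosen desk-scale study conditions; the
generator's defaults above remain the canonical geometry.

## Known limitations

- A single group-level connectome; no subject-level networks.
- Transitions are adjacent volumes at lag 1; scrubbing and other
  preprocessing are upstream concerns.
- The replication of the deposited empirical dataset (fraction of
  significant post-injection time-points; fitted α) requires the
  published subject data and runs only when those are unpacked under
  `data/empirical/`.
- The time-varying Gramian path recomputes one 2N × 2N exponential per
  unique schedule column; for very long scans with fully time-varying
  schedules this dominates runtime.
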