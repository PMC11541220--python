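# Methods

## Model and observable

A single protein held in a nanoaperture optical trap shifts the transmitted
laser power according to its polarizability, so the photodiode voltage V is
a one-dimensional reaction coordinate for conformation.  Over a long trace
the voltage samples the stationary distribution

    p_obs(V) = (P ⊗ C)(V),

where P(V) is the Boltzmann distribution of the conformational coordinate,
P ∝ exp(−U(V)/k_BT), and C(V) is a Gaussian point-spread function (PSF)
produced by translational/rotational motion of the molecule and detection
noise.  The package recovers U from p_obs by histogramming, Lucy–Richardson
(LR) deconvolution of C, and Boltzmann inversion, and then checks the
result kinetically: the landscape's activation energies and curvatures, via
Kramers' viscous-limit rate, fix a slice-resolution Markov chain up to one
dimensionless prefactor A, whose simulated dwell statistics must match the
measured ones.

Assumptions inherited from the measurement physics:

- The PSF is Gaussian, state-independent, and known (σ defaults to
  13.4 mV).  Per-state PSFs are deliberately not implemented.
- Kinetics slower than the 100 ms recognition slice are resolvable;
  anything faster is declared unresolvable and averaged away.
- Only nearest-neighbour transitions occur (N↔F↔E); direct N↔E hops are
  forbidden in both the generator and the Kramers model.
- Stage drift is slow: constant within a 20 s segment.

## Synthetic traces: what the generator emulates

`simulate_trace` is the forward model used for all validation:

1. A discrete-time Markov chain over 2 or 3 states, one step per 100 ms
   slice.  Off-diagonals are `P = const·exp(−E_A)` with constants chained
   from A by curvature ratios (`B = A·ω_F/ω_N`,
   `C = A·(ω_FE/ω_NF)(ω_F/ω_E)`, `D = A·(ω_FE/ω_NF)(ω_E/ω_F)`); dwells are
   geometric by construction.
2. Per-sample conformational breadth: within state i the voltage is drawn
   from N(level_i, 1/ω_i), the Boltzmann width of a quadratic well with
   curvature ω_i (k_BT/V²).  The long-run pre-PSF density is therefore the
   Gaussian-mixture landscape Σ π_i N(level_i, 1/ω_i) with π the chain's
   stationary distribution — a landscape with finite, recoverable barrier
   heights.  (`render_trace` without `state_sigmas` gives the plain
   piecewise-constant telegraph signal instead.)
3. Instrument effects: additive Gaussian PSF noise (σ = 13.4 mV), stage
   drift (default: an independent zero-mean Gaussian offset per 20 s
   segment, sd 5 mV, chosen to exercise the segment-wise correction), and
   ADC quantization to an LSB grid (2.441 mV, round half away from zero).

`design_three_state_spec` solves the inverse design problem: given target
ΔG values and saddle heights it chooses mixture weights from the Gibbs
factors and root-finds the level spacings so that the −log of the realized
mixture has exactly the requested extremum values.  Equal well curvatures
make the chain's stationary distribution coincide with the mixture weights
(detailed balance), so thermodynamic ground truth and kinetic ground truth
are mutually consistent.  `analytic_landscape` evaluates that realized
landscape exactly and is the oracle all recovery tests compare against.

Default geometry: well sd 25 mV (ω = 1600 k_BT/V²), about twice the PSF
width.  Deconvolution is only well-conditioned when the landscape structure
is wider than the PSF — with wells narrower than the PSF the dip region
carries essentially no recoverable information and no iteration count
restores a 3.5 k_BT barrier.  The resulting level spacings (~5.3 well-sd,
~130 mV) are of the scale seen between conformational levels in trapping
transmission traces.

What the generator does **not** emulate: shot-noise scaling with laser
power, the trap-formation transient, within-well temporal correlation of
the conformational jitter (samples are drawn i.i.d.; only the marginal
distribution matters for the landscape), 1/f detector noise, and
aggregation events.  Passing recovery tests therefore demonstrates
correctness of the inference chain under the stated noise model, not
robustness to every artifact of real recordings.

## Numerical choices

- **Histogram**: 100 equal-width bins spanning [min, max] of the samples,
  normalized, zero-padded by 14 bins per side to 128 (power of two; the
  padding also makes circular-convolution wraparound act only on empty
  bins).
- **LR deconvolution**: 51 iterations, multiplicative updates with circular
  FFT convolutions, mirrored kernel for the adjoint step, division floored
  at 1e-12 (logged), output renormalized.  The damping threshold (default
  √0.0001) suppresses the per-bin correction where the reblur residual is
  below the threshold *in counts*: damping exists to stop amplification of
  counting noise, so the residual is compared as `n_samples·|p − P⊗C|`,
  and an analytic PDF (no counts) is undamped.  For real trace sizes
  (≥10⁷ samples) the damping is effectively inactive, matching deconvolution
  of raw counts with a 0.01 threshold.
- **Boltzmann inversion**: support floor 1e-6 of total probability (below
  one count in any realistic trace) guards −ln 0; energies are reported
  relative to the supported minimum; the k_BT→kcal/mol conversion happens
  only in the thermo layer (R = 1.98720425×10⁻³ kcal/(mol·K)) so
  temperature enters the energy scale exactly once.
- **Feature extraction**: extrema are localized on a 3-bin moving average
  (then re-anchored to the raw curve within ±1 bin); energies are always
  read from the raw landscape.  Saddles are raw maxima between adjacent
  minima.  Curvatures come from quadratic least squares over a ≤7-bin
  window clipped to the monotone flanks; a wrong-sign quadratic raises (a
  mislocated extremum).  Whether ω should be U″ or some frequency-like
  transform of it is immaterial here: only ω ratios enter the kinetics, so
  ω ≡ 2|a| is used throughout.
- **1-D k-means**: two-cluster 1-D k-means is exactly solvable by threshold
  enumeration over the sorted values (prefix sums, ties to the lower
  cluster), so classification is deterministic — no seeds, no restarts.
  The three-state classification combines two two-state splits; the side
  split second is chosen by the lower total within-cluster sum of squares,
  because the first threshold can land between either state pair depending
  on occupancies.
- **Collapse to two states**: the second split is accepted only if its
  center separation exceeds 3× the pooled within-cluster sd.  The threshold
  must exceed 2.65: a two-means split of a *pure Gaussian* cluster always
  produces separation/pooled-sd = 2·0.798σ/0.603σ ≈ 2.65, so any smaller
  threshold hallucinates a third state on two-state (dimer) data.
- **Dwells**: the first and last runs are censored and excluded from mean
  residence times (standard dwell-time practice) but included in total
  occupancy, so time is conserved exactly.  Residence-route K uses total
  occupancy ratios; the mean-dwell-ratio variant is reported alongside.
- **Uncertainty model**: dwell durations are near-geometric (relative sd ≈
  1), so ln of a total occupancy time carries variance ≈ 1/n_dwells; the
  s.e. of ln K is √(1/n_i + 1/n_j).  The landscape-route K is an occupancy
  estimate of the same trace, so its s.e. is taken equal to the
  residence-route one and the route-consistency check uses the combined
  √2× value.  The fitted ln A inherits √(Σ 1/n_s)/n_states from the
  log-residence-time targets.
- **Prefactor fit**: τ_s(A) = step/(A·q_s) exactly, so the sum of squared
  log-τ residuals is minimized over ln A by an unconstrained quasi-Newton
  search (positivity is structural); the log loss handles residence times
  spanning orders of magnitude.
- **Drift correction**: per 20 s segment, states are recognized on the
  slice means and the reference-state mean (F; globally-majority cluster
  for two-state traces) is aligned to the first resolvable segment's value.
  Segments where the reference state cannot be resolved inherit the
  previous offset (logged).  Dithering precedes drift correction; the
  removed offsets are reported for audit.
- **Order-of-magnitude sizes**: validation simulations default to 1000 s
  (10⁴ steps); recovery fixtures use 1000 s × 100 kHz traces (10⁸ samples,
  ~2.5 GB peak working set, processed in memory); multi-temperature suites
  use 400 s per temperature.  These sizes put occupancy noise at the
  ~0.1 k_BT level, well under the 0.2 k_BT recovery criterion.

## Known limitations

- A per-slice classifier cannot beat the Bayes error of the slice-mean
  mixture: at a level spacing of 3× the slice-mean noise sd the attainable
  accuracy is ≈ 1 − Φ(−1.5)(1+π_F) ≲ 93% for any occupancy, and the
  hierarchical two-pass scheme adds a further bias because its first
  threshold is the midpoint of N and the pooled {F,E} center rather than
  the N|F boundary.  Accuracy above 95% needs ≳5× separation; the real
  measurement operates far above this (10⁴ samples per slice shrink the
  slice noise ~100× below the PSF width).
- With six temperature points the van 't Hoff standard errors carry 4
  residual degrees of freedom, so ±3 s.e. covers the truth with probability
  P(|t₄|<3) ≈ 0.96, not the Gaussian 0.997 — quoted intervals should be
  read as t-intervals.
- LR deconvolution is slightly conservative at 51 iterations: saddle
  heights are recovered with a small negative bias (≈0.1 k_BT at the
  default geometry, growing rapidly once wells are narrower than the PSF).
- ΔG estimates on finite traces are occupancy-limited: the s.e. is set by
  dwell counts, not by sample count, so minutes-long traces still carry
  ~0.1–0.5 k_BT of statistical noise.
- The F↔E transition need not be linear in T; `fit_enthalpy_entropy`
  reports curvature diagnostics rather than forcing a line, and no
  heat-capacity (ΔCp) model is provided.
- K_eq from the landscape equals the occupancy ratio exactly only when the
  well curvatures are equal; otherwise the Eq.-type curvature prefactors
  break exact Boltzmann balance by ln(ω_i/ω_j) — the model flags this
  rather than failing.
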