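# Methods

This note records the mechanistic model behind `dnadevice`, the default
parameter choices and why they were made, the design of the synthetic
ensembles, and the known limitations. Everything here is computed by the
package itself; no external data are required.

## 1. Trace model (`dnadevice.simkit`)

One expression spot is a birth–death process of nascent proteins tethered to
a single DNA:

1. **Initiation.** In *random* mode, initiation events form a Poisson
   process of rate k_tx. In *burst* mode, burst arrivals are Poisson with
   the same rate parameter; each burst contains a geometrically distributed
   number of initiations with mean ⟨Δn⟩, spaced by exponential intervals of
   mean τ_E.
2. **Residence.** Each protein stays tethered for
   T ~ Normal(ΔL/v, (0.1·ΔL/v)²), truncated to be non-negative by
   resampling. ΔL is the C-terminal extension length and v the effective
   elongation speed; the 10% coefficient of variation models elongation
   heterogeneity.
3. **Fluorescence onset.** A protein becomes fluorescent at
   t_init + t_fold + t_dye (co-translational folding delay plus dye binding
   time) — but only if it is still tethered at that moment. Proteins
   released earlier are never visible.
4. **Photobleaching.** From the onset of fluorescence, each protein bleaches
   after an exponential time with mean t_bleach.
5. **Signal.** I(t) = unit_brightness × #{fluorescent ∧ tethered ∧
   unbleached at t} + Gaussian camera noise, sampled every dt.

The trace is exactly the occupancy of its event list (tested as an
identity), and the long-run mean obeys Little's law,
⟨I⟩ = k_tx (T − t_fold), when bleaching is off.

Two consequences carry the analysis:

- **Ideal ACF.** Without bleaching, the normalized autocorrelation is the
  triangle G(τ) = (T_vis − τ)/(k_tx T_vis²) for τ < T_vis, with
  T_vis = T − t_fold the *visible* window (a protein is dark for its first
  t_fold seconds). The ensemble median ACF converges to this form within
  Monte-Carlo error.
- **Detection probability.** A protein is detected iff its residence exceeds
  t_fold + t_dye, i.e. P(detect) = Φ((T − t_fold − t_dye)/(0.1 T)), a
  logistic-shaped function of ΔL with midpoint L₀ = v·(t_fold + t_dye).

## 2. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| v (elongation) | 10 nt/s | typical effective transcription–translation speed in reconstituted/lysate systems |
| t_fold | 86 s | implied by the 862 nt detection threshold at v = 10 nt/s (L₀/v) |
| t_dye | 0 s (2 s available via `dye_binding_time`) | 1/(k·c) = 2 s at k = 10⁷ M⁻¹s⁻¹, c = 50 nM is negligible next to t_fold; kept explicit so it can be switched on |
| t_bleach | 90 s | measured single-fluorophore bleaching scale under imaging illumination |
| residence CV | 0.1 | modest elongation-time heterogeneity; sets the logistic width |
| dt | 4 s | same-channel frame period of alternating two-color acquisition |
| duration | 3600 s | one acquisition hour |
| k_tx | 0.01 s⁻¹ | *not a printed value.* One initiation per ~100 s per DNA is realistic for cell-free expression; chosen once, before any acceptance run, and never tuned. It sets overall trace amplitude but cancels out of τ_C and of the logistic midpoint, the two reported targets |
| ⟨Δn⟩, τ_E | 1 (off), 30 s | τ_E of tens of seconds matches initiation spacing within a promoter on-period; also not printed, chosen once with k_tx |
| P₀, K_D | 70 nM, 100 nM | RNAP concentration and rifampicin dissociation constant of the binding model |
| coloc radius | 7 px | DNA–protein co-localization cut (strict `<`) |
| min track length | 5 frames | rejects one-frame noise detections |
| aperture d | 3 px | photometry aperture diameter; ring [d/2, d] with 2σ/2σ clipping, ≤10 iterations |
| Mahalanobis threshold | 3 | applied literally to the **squared** distance; permissive (χ²₂ tail ≈ 0.22 for a homogeneous Gaussian reference) |

## 3. Findings from the package's own analysis

**Bleaching bounds τ_C.** With random birth and t_bleach = 90 s, the fitted
mono-exponential correlation time is ≈ 39 s at ΔL = 1980 nt and stays below
the 90 s bleaching time at every extension (t5 ≈ 0.65 min). The bound is
structural: bleaching truncates every protein's visible interval.

**Bursting raises τ_C but cannot beat the bleaching bound at these
parameters.** Burst mode (⟨Δn⟩ = 3, τ_E = 30 s) lifts τ_C from ≈ 41 s to
≈ 62 s at matched conditions — a >3 SE contrast — but scanning ⟨Δn⟩ up to 5
and τ_E up to 200 s never pushed the *simulated* τ_C above 90 s, because the
visible window is capped at T − t_fold = 112 s. The correct simulation-side
statement is therefore the contrast (burst τ_C ≫ random τ_C), and that is
what the test suite asserts; a measured τ_C above the simulated
bleaching-bound curve is evidence for correlated production precisely
because simulations cannot reach it.

**Feature-space degeneracy and reference design.** For noiseless monotone
ramps, F_max is proportional to the drift D, so the (D, F_max) covariance is
singular; the classifier detects this and refuses to fit. Physically
realistic traces carry stochastic fluctuations, so the synthetic generators
add Ornstein–Uhlenbeck (OU) noise (exact discretization; its spectrum is the
Lorentzian implied by Wiener–Khinchin, verified by test). A *homogeneous*
Gaussian reference cloud self-flags ≈ 22% of its own members at threshold 3
(the χ²₂ tail), so a ≤10% false-positive rate requires a heterogeneous
reference, like measured non-pulsing populations: `make_reference_ensemble`
draws ~90% weak accumulators and ~10% strong ones (fluctuation amplitude
tied to brightness). Against this reference, held-out non-pulsing traces are
flagged at 9–10% and planted pulses are recovered at 100%, robust across
seeds.

## 4. Numerical choices

- **ACF estimator.** Per-lag pair counts: G(k·dt) = [Σ δI_i δI_{i+k} /
  (N−k)] / μ², so G(0) = σ²/μ² exactly (population moments). Ensembles are
  combined by the pointwise **median** ACF for robustness to bright
  outliers; SEs come from bootstrap over spots (the only independent unit).
- **Mono-exponential fit.** g(τ) = G₀ e^(−τ/τ_C) by least squares over
  lags from one frame to 600 s, with non-negativity bounds. Fitting from
  the first non-zero lag avoids the white-noise spike at τ = 0.
- **Radial-symmetry localization.** Gradients on the half-pixel midpoint
  lattice via 45° cross-differences, 3×3 boxcar smoothing, |g|² weighting,
  and a 2×2 linear solve for the point minimizing weighted distance to all
  gradient lines. Accuracy ≤ 0.005 px noise-free; no iteration, no fitting.
- **Linking.** Per-frame-pair optimal assignment (Hungarian algorithm) with
  a search radius and gap memory. Track filtering: minimum length, then
  DBSCAN on track centroids; DBSCAN noise points (non-clustered singletons,
  e.g. beads) are discarded.
- **Photometry.** Background-subtracted aperture **sum**:
  Σ(aperture) − n_pix × sigma-clipped ring mean. Invariant to uniform
  background by construction (tested). Intensities are in arbitrary units;
  the small aperture clips the PSF shoulder, which rescales but does not
  distort trace statistics.
- **Determinism.** Every stochastic entry point takes a seed;
  `simulate_ensemble` spawns per-trace generators from a `SeedSequence`, so
  runs are bit-reproducible and byte-identical at the artifact level.

## 5. Problem sizes

Sizes are the package's own choice, set for <10 s per analysis on one CPU:
500 traces for ensemble ACF targets (bootstrap SE on τ_C ≈ 0.5 s, small
against the 90 s bound), 10⁴ Monte-Carlo repeats per length for detection
probabilities (binomial SE ≤ 0.5%, giving a midpoint SE of ~1 nt), 100-trace
ensembles for classifier evaluation, and 60-frame 64×64 movies for the image
chain.

## 6. Limitations

- The simulator treats initiation, elongation, folding, dye binding and
  bleaching as independent; no ribosome queuing, no mRNA-level dynamics, no
  shared-resource coupling between DNA molecules.
- t_fold, v, and t_bleach enter only through their ratios to the window and
  frame time; k_tx and τ_E are plausible defaults, not measured values.
- Measured-data phenomena (1/f-type spectra of regulated circuits, absolute
  pulse fractions, rifampicin dose-response amplitudes) depend on
  experimental noise structure and are exercised only on synthetic
  analogues here.
- The movie renderer uses a Gaussian PSF and Gaussian noise; no EMCCD
  excess noise, aberrations, or uneven illumination.
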