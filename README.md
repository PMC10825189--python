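# dnadevice

Simulation and analysis of single-molecule gene-expression imaging on
surface-tethered DNA.

## Scientific problem

In single-molecule TIRF experiments, individual DNA molecules are tethered to
a coverslip and transcribed/translated in a cell-free extract. Each nascent
protein carries a self-labeling tag that becomes fluorescent when a
fluorogenic dye binds, so a diffraction-limited "expression spot" on a DNA
molecule reports the number of nascent proteins currently tethered to it
through the RNAP–mRNA–ribosome complex. The intensity trace I(t) of one spot
is therefore a direct readout of stochastic gene expression on a single DNA.

The quantities of interest come from fluctuation analysis of these traces.
With initiation a Poisson process of rate k_tx and each protein tethered for
a residence time T = ΔL/v (extension length ΔL, elongation speed v), the
normalized autocorrelation

    G(τ) = ⟨δI(t) δI(t+τ)⟩ / ⟨I⟩²,     G(0) = σ²/μ²

has the closed triangular form

    G(τ) = (T − τ) / (k_tx T²) · H[T − τ]        (bleach-free limit)

so G(0)⁻¹ = k_tx T estimates the initiation rate and the τ-intercept the
residence time. A mono-exponential fit to the measured ensemble ACF gives an
apparent correlation time τ_C; photobleaching (exponential, mean t_bleach)
caps τ_C from above, while transcriptional bursting lengthens it. A protein
is only detected if it stays tethered longer than its co-translational
folding time t_fold ≈ 86 s, which makes detection probability a logistic
function of ΔL with midpoint L₀ = v·t_fold ≈ 860 nt. Pulsatile regulation is
detected in (drift D, maximal Fourier amplitude F_max) feature space by
Mahalanobis distance to a non-pulsing reference population, and transcription
inhibition by rifampicin follows the mass-action bound fraction

    f = [P₀ + r₀ + K_D − √((P₀ + r₀ + K_D)² − 4 P₀ r₀)] / (2 P₀).

The package implements the whole chain:

- `dnadevice.simkit` — stochastic simulator of nascent-protein intensity
  traces (random or bursty initiation, folding delay, dye binding,
  photobleaching, camera noise) and a synthetic two-channel TIRF movie
  renderer with fiducial beads and stage drift.
- `dnadevice.imgpipe` — image chain: bead-based drift correction, spot
  detection, radial-symmetry sub-pixel localization, track linking, DBSCAN
  filtering, DNA co-localization, sigma-clipped aperture photometry.
- `dnadevice.fluct` — ACF estimation, mono-exponential and ideal triangular
  models, logistic length fit, spot accounting (`FluctuationModel`,
  `LogisticLengthModel`).
- `dnadevice.models` — closed-form models: rifampicin–RNAP binding
  (`RifampicinResponseModel`), dye binding time, burst on-time.
- `dnadevice.pulses` — power spectra, (D, F_max) features, Mahalanobis pulse
  classification (`PulseClassifier`), pulsing factor, pulse alignment.
- `dnadevice.io` / `dnadevice.config` / `dnadevice.pipeline` /
  `dnadevice.cli` — trace/movie I/O, run configuration, pipeline driver, CLI.

Fitted models follow a statsmodels-style split: a `Model` holds data and
options, `.fit()` returns a `Results` object with parameters, standard
errors, `summary()`, and `to_frame()`.

## Worked example

Simulate 500 spot traces at the longest extension (ΔL = 1980 nt,
k_tx = 0.01 s⁻¹, 90 s photobleaching) and fit the ensemble ACF:

```python
from dnadevice.fluct import FluctuationModel
from dnadevice.simkit import SimConfig

config = SimConfig(gene_extension_length=1980, initiation_rate=0.01,
                   bleach_time=90.0, duration=3600, seed=42)
result = FluctuationModel.from_simulation(config, 500).fit(n_boot=100, seed=0)
print(result.summary())
```

```
Ensemble fluctuation analysis (median ACF, mono-exponential fit)
----------------------------------------------------------------
spots                     500
ACF delay window (s)      (1e-09, 600.0)
G(0) (median ACF)         1.614
G(0)^-1 (fit)             0.5403 +/- 0.008
tau_C (fit, s)            38.57 +/- 0.48
```

The fitted τ_C ≈ 0.64 min sits well below the 1.5 min bleaching time, as it
must for uncorrelated single-protein production. The mechanistic detection
sweep recovers the logistic threshold length, and the rifampicin response
model fits a dose curve:

```python
import numpy as np
from dnadevice.fluct import LogisticLengthModel
from dnadevice.simkit import SimConfig
from dnadevice.models import RifampicinResponseModel, fraction_bound

base = SimConfig(gene_extension_length=1, initiation_rate=0.01, seed=7)
fit = LogisticLengthModel.from_detection_sweep(
    base, [531, 730, 862, 1100, 1500, 1980], n_reps=10_000).fit()
print(f"logistic midpoint: {fit.midpoint:.1f} nt")

doses = np.array([0.0, 25.0, 50.0, 100.0, 200.0, 400.0])
rng = np.random.default_rng(1)
g0_inverse = 1.2 + 3.1 * (1 - fraction_bound(70.0, doses, 100.0)) \
    + rng.normal(0, 0.08, doses.size)
print(RifampicinResponseModel(doses, g0_inverse).fit().summary())
```

```
logistic midpoint: 860.0 nt
Rifampicin dose response of G(0)^-1
----------------------------------------
P0 (nM, fixed)    70
K_D (nM, fixed)   100
amplitude         3.102 +/- 0.11
baseline          1.219 +/- 0.075
RMS residual      0.0586
```

The same analyses are available from the command line:

```bash
dnadevice simulate --seed 1 --out demo
dnadevice acf demo/traces.csv --out demo/acf.csv
```

```
Ensemble fluctuation analysis (median ACF, mono-exponential fit)
----------------------------------------------------------------
spots                     50
ACF delay window (s)      (1e-09, 600.0)
G(0) (median ACF)         1.838
G(0)^-1 (fit)             0.4817
tau_C (fit, s)            38.72
```

`dnadevice process movie.tif` runs the image chain on an alternating
two-channel TIFF, `dnadevice pulses` classifies pulsatile traces against a
reference table, and `dnadevice all` runs every stage end to end.

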