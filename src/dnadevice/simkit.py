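"""Stochastic simulation of nascent-protein fluorescence on single DNA molecules.

The mechanistic model: coupled transcription–translation complexes initiate on a
gene with exponentially distributed waiting times (rate ``k_tx``), either
independently ("random" mode) or in transcriptional bursts ("burst" mode:
Poisson burst arrivals, geometric burst sizes, exponential within-burst
spacing).  Each complex traverses the gene of length ``ΔL`` at elongation speed
``v``; the total residence time is normally distributed around ``T = ΔL/v``
with coefficient of variation ``residence_cv`` (truncated at zero).  A nascent
HaloTag protein becomes fluorescent a fixed delay ``t_fold + t_dye`` after
initiation (co-translational folding plus dye binding); if the complex is
released first, the protein never fluoresces on the DNA.  Once fluorescent, a
protein bleaches after an exponential time of mean ``t_bleach``.  The recorded
trace is the number of proteins that are simultaneously fluorescent, tethered,
and unbleached, scaled by a unit brightness, plus additive Gaussian camera
noise.

The module also renders synthetic two-channel TIRF movies (Gaussian point
spread functions, fiducial beads, lateral stage drift) with a ground-truth
table, so the full image-processing chain can be exercised without any
experimental data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "ProteinEvent",
    "MovieSpec",
    "IntensityTrace",
    "simulate_trace",
    "detection_probability",
    "render_movie",
]

NEVER = math.inf


@dataclass(frozen=True)
class IntensityTrace:
    """Uniformly sampled fluorescence of one expression spot versus time."""

    t: np.ndarray  # seconds
    intensity: np.ndarray  # arbitrary units
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if t.shape != inten.shape:
            raise ValueError("time and intensity must have equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "intensity", inten)

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("trace too short to define a sampling interval")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError("trace is not uniformly sampled")
        return float(steps[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the coupled transcription–translation trace model.

    Times are seconds, lengths nucleotides, intensities arbitrary units.
    ``t_bleach`` is the mean of the exponential bleaching time whose clock
    starts when the protein becomes fluorescent; use ``math.inf`` to disable
    bleaching.  ``burst_mean_size`` and ``burst_spacing`` only matter in
    burst mode.
    """

    gene_extension_length: float  # ΔL, nt
    initiation_rate: float  # k_tx, events/s (burst arrivals in burst mode)
    elongation_speed: float = 10.0  # v, nt/s
    folding_time: float = 86.0  # co-translational folding, s
    dye_binding_time: float = 0.0  # s (≈2 s at 50 nM dye; neglected by default)
    bleach_time: float = 90.0  # mean of exponential, s
    residence_cv: float = 0.1
    burst_mean_size: float = 1.0  # ⟨Δn⟩ proteins per burst
    burst_spacing: float = 30.0  # τ_E, s, within-burst initiation spacing
    unit_brightness: float = 1.0  # a.u. per fluorescent protein
    noise_sigma: float = 0.0  # additive Gaussian camera noise, a.u.
    duration: float = 3600.0  # s
    dt: float = 4.0  # same-channel frame period, s
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.gene_extension_length >= 0, "gene_extension_length must be >= 0"),
            (self.elongation_speed > 0, "elongation_speed must be > 0"),
            (np.isfinite(self.initiation_rate) and self.initiation_rate >= 0,
             "initiation_rate must be finite and >= 0"),
            (self.folding_time >= 0, "folding_time must be >= 0"),
            (self.dye_binding_time >= 0, "dye_binding_time must be >= 0"),
            (self.bleach_time > 0, "bleach_time must be > 0 (inf disables bleaching)"),
            (self.residence_cv >= 0, "residence_cv must be >= 0"),
            (self.burst_mean_size >= 1, "burst_mean_size must be >= 1"),
            (self.burst_spacing >= 0, "burst_spacing must be >= 0"),
            (self.noise_sigma >= 0, "noise_sigma must be >= 0"),
            (self.dt > 0, "dt must be > 0"),
            (self.duration >= self.dt, "duration must be >= dt"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @property
    def residence_time(self) -> float:
        """Mean residence time T = ΔL / v in seconds."""
        return self.gene_extension_length / self.elongation_speed

    @property
    def maturation_delay(self) -> float:
        """Delay from initiation to fluorescence: t_fold + t_dye."""
        return self.folding_time + self.dye_binding_time

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ProteinEvent:
    """Ground-truth event times of one simulated nascent protein (seconds).

    ``t_fluoresce`` and ``t_bleach`` are ``math.inf`` ("never") when the
    protein is released before folding completes, or never bleaches.
    """

    t_init: float
    t_fluoresce: float
    t_release: float
    t_bleach: float

    def __post_init__(self) -> None:
        if self.t_init > self.t_release:
            raise ValueError("t_init must not exceed t_release")
        if np.isfinite(self.t_fluoresce) and self.t_fluoresce <= self.t_init:
            raise ValueError("finite t_fluoresce must follow t_init")

    @property
    def signal_start(self) -> float:
        return self.t_fluoresce

    @property
    def signal_end(self) -> float:
        return min(self.t_release, self.t_bleach)

    @property
    def detected(self) -> bool:
        """True when the protein fluoresces while still tethered."""
        return self.t_fluoresce < self.t_release


def _sample_residence(rng: np.random.Generator, T: float, cv: float, n: int) -> np.ndarray:
    """Residence times ~ Normal(T, (cv*T)^2), truncated at zero by resampling."""
    if T == 0 or cv == 0:
        return np.full(n, T)
    out = rng.normal(T, cv * T, size=n)
    bad = out < 0
    # resample negatives; probability mass below zero is tiny for cv ~ 0.1
    while bad.any():
        out[bad] = rng.normal(T, cv * T, size=int(bad.sum()))
        bad = out < 0
    return out


def _initiation_times(config: SimConfig, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Initiation times of a Poisson (random) or burst-structured process."""
    k = config.initiation_rate
    if k == 0:
        return np.empty(0)
    horizon = config.duration
    if mode == "random":
        n_exp = k * horizon
        n = rng.poisson(n_exp)
        return np.sort(rng.uniform(0.0, horizon, size=n))
    if mode == "burst":
        n_bursts = rng.poisson(k * horizon)
        starts = np.sort(rng.uniform(0.0, horizon, size=n_bursts))
        # geometric burst size with mean ⟨Δn⟩ (support 1, 2, ...)
        p = 1.0 / config.burst_mean_size
        sizes = rng.geometric(p, size=n_bursts)
        times = []
        for t0, size in zip(starts, sizes):
            gaps = rng.exponential(config.burst_spacing, size=size - 1) if size > 1 else np.empty(0)
            times.append(t0 + np.concatenate(([0.0], np.cumsum(gaps))))
        return np.sort(np.concatenate(times)) if times else np.empty(0)
    raise ValueError(f"unknown mode {mode!r}; use 'random' or 'burst'")


def _events_from_initiations(
    t_init: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> list[ProteinEvent]:
    n = len(t_init)
    T = config.residence_time
    residence = _sample_residence(rng, T, config.residence_cv, n)
    t_release = t_init + residence
    t_fluoresce = t_init + config.maturation_delay
    # a protein that is released before folding+dye binding never fluoresces
    never = t_fluoresce >= t_release
    t_fluoresce = np.where(never, NEVER, t_fluoresce)
    if np.isfinite(config.bleach_time):
        # independent bleaching clock per protein, started at t_fluoresce
        t_bleach = t_fluoresce + rng.exponential(config.bleach_time, size=n)
    else:
        t_bleach = np.full(n, NEVER)
    t_bleach = np.where(never, NEVER, t_bleach)
    return [
        ProteinEvent(float(a), float(b), float(c), float(d))
        for a, b, c, d in zip(t_init, t_fluoresce, t_release, t_bleach)
    ]


def occupancy(events: Sequence[ProteinEvent], t: np.ndarray) -> np.ndarray:
    """Number of fluorescent, tethered, unbleached proteins at each time."""
    t = np.asarray(t, dtype=float)
    count = np.zeros(len(t))
    for ev in events:
        if not np.isfinite(ev.signal_start):
            continue
        count += (t >= ev.signal_start) & (t < ev.signal_end)
    return count


def simulate_trace(
    config: SimConfig, mode: str = "random"
) -> tuple[IntensityTrace, list[ProteinEvent]]:
    """Simulate one expression-spot intensity trace.

    Parameters
    ----------
    config
        Model parameters; the RNG is seeded from ``config.seed`` so the
        result is bit-reproducible.
    mode
        ``"random"`` for independent single-protein initiations (Poisson
        with rate ``k_tx``) or ``"burst"`` for burst-structured initiations.

    Returns
    -------
    (trace, events)
        The sampled trace and the per-protein ground-truth event list.
    """
    rng = np.random.default_rng(config.seed)
    t_init = _initiation_times(config, mode, rng)
    events = _events_from_initiations(t_init, config, rng)
    n_frames = int(math.floor(config.duration / config.dt))
    t = np.arange(n_frames) * config.dt
    signal = config.unit_brightness * occupancy(events, t)
    if config.noise_sigma > 0:
        signal = signal + rng.normal(0.0, config.noise_sigma, size=n_frames)
    return IntensityTrace(t=t, intensity=signal), events


def simulate_ensemble(
    config: SimConfig, n_traces: int, mode: str = "random"
) -> list[IntensityTrace]:
    """Simulate ``n_traces`` independent traces, seeds derived from config.seed."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(n_traces) >> 1  # keep below 2**31
    return [
        simulate_trace(config.replace(seed=int(s)), mode=mode)[0] for s in seeds
    ]


def detection_probability(
    config: SimConfig, n_reps: int, *, method: str = "monte-carlo"
) -> float:
    """Probability that a nascent protein fluoresces while still on the DNA.

    A protein is detectable when its residence time exceeds the maturation
    delay ``t_fold + t_dye``.  ``method="monte-carlo"`` samples ``n_reps``
    residence times; ``method="analytic"`` evaluates the normal-tail closed
    form Phi((T - delay) / (cv*T)) of the same (untruncated) model.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    T = config.residence_time
    delay = config.maturation_delay
    if method == "analytic":
        if T == 0:
            return 0.0
        if config.residence_cv == 0:
            return float(T > delay)
        return float(norm.sf(delay, loc=T, scale=config.residence_cv * T))
    if method != "monte-carlo":
        raise ValueError(f"unknown method {method!r}")
    if T == 0:
        return 0.0
    rng = np.random.default_rng(config.seed)
    residence = _sample_residence(rng, T, config.residence_cv, n_reps)
    return float(np.mean(residence > delay))


def _ou_noise(rng: np.random.Generator, n: int, dt: float,
              sigma: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise (exact discretization).

    Emulates the slow expression fluctuations of real traces (bleach-limited
    protein turnover), whose autocorrelation is mono-exponential with
    timescale ``tau``.
    """
    if sigma == 0:
        return np.zeros(n)
    rho = math.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * math.sqrt(1 - rho**2), size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def make_pulse_trace(
    duration: float = 5400.0,
    dt: float = 4.0,
    amplitude: float = 100.0,
    center: float | None = None,
    width: float = 1200.0,
    noise_sigma: float = 10.0,
    ou_sigma: float = 10.0,
    ou_tau: float = 90.0,
    seed: int = 0,
    trace_id: str = "pulse",
) -> IntensityTrace:
    """Phenomenological pulsatile trace: a Gaussian pulse returning to baseline.

    Emulates a feedback-repressed expression burst (rise and decay over
    roughly ``width`` seconds) riding on correlated expression fluctuations
    (OU, timescale ``ou_tau``) plus white camera noise.  ``center`` defaults
    to a random position in the middle half of the trace.
    """
    rng = np.random.default_rng(seed)
    n = int(duration / dt)
    t = np.arange(n) * dt
    if center is None:
        center = float(rng.uniform(0.25, 0.75) * duration)
    signal = amplitude * np.exp(-((t - center) ** 2) / (2 * (width / 2.355) ** 2))
    signal = signal + _ou_noise(rng, n, dt, ou_sigma, ou_tau)
    signal = signal + rng.normal(0.0, noise_sigma, size=n)
    return IntensityTrace(t=t, intensity=signal, trace_id=trace_id)


def make_ramp_trace(
    duration: float = 5400.0,
    dt: float = 4.0,
    slope: float = 0.02,
    noise_sigma: float = 10.0,
    ou_sigma: float = 10.0,
    ou_tau: float = 90.0,
    seed: int = 0,
    trace_id: str = "ramp",
) -> IntensityTrace:
    """Phenomenological accumulation trace: monotone ramp plus fluctuations.

    Emulates unrepressed expression where proteins accumulate on the DNA,
    with the same correlated-plus-white noise model as
    :func:`make_pulse_trace`.
    """
    rng = np.random.default_rng(seed)
    n = int(duration / dt)
    t = np.arange(n) * dt
    signal = slope * t + _ou_noise(rng, n, dt, ou_sigma, ou_tau)
    signal = signal + rng.normal(0.0, noise_sigma, size=n)
    return IntensityTrace(t=t, intensity=signal, trace_id=trace_id)


def sample_burst_on_times(config: SimConfig, n_bursts: int, seed: int | None = None) -> np.ndarray:
    """Empirical on-times of isolated transcriptional bursts.

    For each burst (geometric size, exponential within-burst spacing), the
    on-time is the span from the first initiation to the release of the
    last-initiated protein.  Its expectation is the closed form
    ``(burst_mean_size - 1) * burst_spacing + residence_time``.
    """
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = 1.0 / config.burst_mean_size
    sizes = rng.geometric(p, size=n_bursts)
    out = np.empty(n_bursts)
    T = config.residence_time
    for i, size in enumerate(sizes):
        gaps = rng.exponential(config.burst_spacing, size=size - 1) if size > 1 else np.empty(0)
        inits = np.concatenate(([0.0], np.cumsum(gaps)))
        residence = _sample_residence(rng, T, config.residence_cv, size)
        out[i] = float(inits[-1] + residence[-1])
    return out


def make_reference_ensemble(n: int = 100, seed: int = 0) -> list[IntensityTrace]:
    """No-feedback circuit ensemble: accumulation traces in two brightness classes.

    Emulates the reference (weak-repressor) population: most spots are dim,
    slowly accumulating expression traces, with a ~10% minority of strong
    accumulators whose drift and fluctuation amplitude are an order of
    magnitude larger.  The heterogeneity inflates the (D, F_max) covariance
    the way a bimodal drift distribution does in measured populations, which
    is what makes the permissive Mahalanobis ellipse specific in practice.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if i % 10 == 0:
            slope = 0.1 * float(rng.uniform(0.5, 1.5))
            ou = 80.0
        else:
            slope = 0.008 * float(rng.uniform(0.7, 1.3))
            ou = 8.0
        out.append(make_ramp_trace(seed=seed + i, slope=slope, ou_sigma=ou,
                                   trace_id=f"ref_{i:03d}"))
    return out


def make_pulse_ensemble(n: int = 100, seed: int = 1000) -> list[IntensityTrace]:
    """Feedback-circuit ensemble: pulsatile traces returning to baseline."""
    rng = np.random.default_rng(seed)
    return [
        make_pulse_trace(seed=seed + i, amplitude=float(rng.uniform(100, 200)),
                         ou_sigma=10.0, trace_id=f"pulse_{i:03d}")
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Synthetic movie rendering


@dataclass
class MovieSpec:
    """Specification of a synthetic two-channel TIRF movie.

    Channel 0 carries DNA spots (488 nm convention), channel 1 the
    expression spots (647 nm); fiducial beads appear in both channels.
    Positions are 0-based pixel coordinates in (row, col) order with spot
    centers at pixel centers; ``drift`` is the per-frame lateral stage
    displacement in pixels applied to every object.
    """

    n_frames: int
    shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.143  # µm per px
    psf_sigma: float = 1.3  # px
    dna_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    dna_brightness: float = 200.0
    expression_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    expression_traces: list[IntensityTrace] = field(default_factory=list)
    bead_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    bead_brightness: float = 500.0
    drift: np.ndarray | None = None  # (n_frames, 2) px
    background: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dna_positions = np.atleast_2d(np.asarray(self.dna_positions, dtype=float))
        self.expression_positions = np.atleast_2d(
            np.asarray(self.expression_positions, dtype=float)
        )
        self.bead_positions = np.atleast_2d(np.asarray(self.bead_positions, dtype=float))
        for name in ("dna_positions", "expression_positions", "bead_positions"):
            arr = getattr(self, name)
            if arr.size == 0:
                setattr(self, name, arr.reshape(0, 2))
        if self.drift is None:
            self.drift = np.zeros((self.n_frames, 2))
        self.drift = np.asarray(self.drift, dtype=float)
        if self.drift.shape != (self.n_frames, 2):
            raise ValueError("drift must have shape (n_frames, 2)")
        if len(self.expression_traces) != len(self.expression_positions):
            raise ValueError("one IntensityTrace required per expression spot")
        nrow, ncol = self.shape
        for name in ("dna_positions", "expression_positions", "bead_positions"):
            arr = getattr(self, name)
            if arr.size and (
                (arr[:, 0] < 0).any()
                or (arr[:, 1] < 0).any()
                or (arr[:, 0] >= nrow).any()
                or (arr[:, 1] >= ncol).any()
            ):
                raise ValueError(f"{name} must lie within image bounds before drift")


def _add_psf(frame: np.ndarray, row: float, col: float, amplitude: float, sigma: float) -> None:
    """Accumulate a 2-D Gaussian PSF (peak ``amplitude``) into ``frame`` in place."""
    nrow, ncol = frame.shape
    half = int(math.ceil(4 * sigma))
    r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
    c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
    r0c, r1c = max(r0, 0), min(r1, nrow)
    c0c, c1c = max(c0, 0), min(c1, ncol)
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None]
    cc = np.arange(c0c, c1c)[None, :]
    frame[r0c:r1c, c0c:c1c] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2)
    )


def render_movie(spec: MovieSpec) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Render the synthetic movie and its ground-truth table.

    Returns
    -------
    (stacks, truth)
        ``stacks`` maps channel index (0: DNA, 1: protein) to a float32
        array of shape ``(n_frames, nrow, ncol)``; ``truth`` lists every
        rendered spot per frame with columns
        ``spot_id, kind, channel, frame, t, x_px, y_px, intensity``
        (x = column, y = row, drift included).
    """
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.shape
    stacks = {
        0: np.zeros((spec.n_frames, nrow, ncol), dtype=np.float64),
        1: np.zeros((spec.n_frames, nrow, ncol), dtype=np.float64),
    }
    records: list[dict] = []

    def render_spot(kind, idx, channels, pos, amplitude_of) -> None:
        spot_id = f"{kind}_{idx}"
        for f in range(spec.n_frames):
            amp = amplitude_of(f)
            row = pos[0] + spec.drift[f, 0]
            col = pos[1] + spec.drift[f, 1]
            if not (0 <= row < nrow and 0 <= col < ncol):
                warnings.warn(
                    f"{spot_id} drifted outside the image at frame {f}; clipped",
                    stacklevel=3,
                )
            for ch in channels:
                if amp != 0:
                    _add_psf(stacks[ch][f], row, col, amp, spec.psf_sigma)
                records.append(
                    dict(
                        spot_id=spot_id,
                        kind=kind,
                        channel=ch,
                        frame=f,
                        t=f * 4.0,
                        x_px=col,
                        y_px=row,
                        intensity=amp,
                    )
                )

    for i, pos in enumerate(spec.bead_positions):
        render_spot("bead", i, (0, 1), pos, lambda f: spec.bead_brightness)
    for i, pos in enumerate(spec.dna_positions):
        render_spot("dna", i, (0,), pos, lambda f: spec.dna_brightness)
    for i, (pos, trace) in enumerate(zip(spec.expression_positions, spec.expression_traces)):
        if len(trace) < spec.n_frames:
            raise ValueError("expression trace shorter than the movie")
        render_spot("expression", i, (1,), pos, lambda f, tr=trace: float(tr.intensity[f]))

    for ch in (0, 1):
        stacks[ch] += spec.background
        if spec.noise_sigma > 0:
            stacks[ch] += rng.normal(0.0, spec.noise_sigma, size=stacks[ch].shape)
        stacks[ch] = stacks[ch].astype(np.float32)

    columns = ["spot_id", "kind", "channel", "frame", "t", "x_px", "y_px", "intensity"]
    truth = pd.DataFrame(records, columns=columns)
    return stacks, truth
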