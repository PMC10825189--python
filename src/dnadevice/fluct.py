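"""Fluctuation analysis of expression-spot intensity traces.

The central quantity is the normalized autocorrelation function (ACF)

    G(tau) = <dI(t) dI(t+tau)> / <I(t)>^2,   dI = I - <I>,

whose inverse amplitude G(0)^-1 = mu^2/sigma^2 reports the initiation
statistics and whose correlation time tau_C reports how long produced
proteins remain visible.  For uncorrelated single-protein production without
bleaching the ACF is triangular,

    G(tau) = (T - tau) / (k_tx T^2) * H[T - tau],

with transcription-translation initiation rate k_tx and residence time T,
so G(0)^-1 = k_tx T.  With dominant photobleaching the decay becomes
exponential and tau_C is bounded by the mean bleaching time; correlation
times beyond that bound are the signature of transcriptional bursting.

`FluctuationModel` packages the per-spot ACF -> median ACF -> mono-exponential
fit chain as a statsmodels-style model; `LogisticLengthModel` fits the
spot-count (or detection-probability) versus gene-extension-length curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simkit import IntensityTrace

__all__ = [
    "ACFResult",
    "LogisticFit",
    "compute_acf",
    "median_acf",
    "fit_monoexponential",
    "ideal_acf",
    "linear_drift",
    "fit_logistic_counts",
    "spot_accounting",
    "FluctuationModel",
    "FluctuationResults",
    "LogisticLengthModel",
]

DEFAULT_FIT_WINDOW = (1e-9, 600.0)  # lags from 1 frame up to 10 min


@dataclass
class ACFResult:
    """Autocorrelation curve of one trace (or a pointwise ensemble median).

    ``g[k]`` is G at delay ``tau[k]``; ``tau[0] = 0`` and
    ``g[0] = sigma^2/mu^2`` exactly (same estimator as the moments).  The
    fitted inverse amplitude and correlation time are filled in by
    :func:`fit_monoexponential`.
    """

    tau: np.ndarray  # s
    g: np.ndarray
    mean: float  # mu, a.u.
    std: float  # sigma, a.u.
    g0_inverse: float | None = None  # fitted 1/G0
    tau_c: float | None = None  # fitted correlation time, s
    fit_window: tuple[float, float] | None = None

    @property
    def g0(self) -> float:
        return float(self.g[0])


def compute_acf(trace: IntensityTrace, max_lag: float | None = None) -> ACFResult:
    """Normalized autocorrelation of one intensity trace.

    Uses the per-lag pair-count estimator: the lag-k covariance sum is
    divided by the number of overlapping pairs (N - k), and the global trace
    mean is subtracted.  By construction G(0) = sigma^2/mu^2 with the same
    (1/N) variance estimator.

    Parameters
    ----------
    trace
        Uniformly sampled trace of length >= 4.
    max_lag
        Largest delay (seconds) to evaluate; defaults to half the trace.
    """
    x = trace.intensity
    n = len(x)
    if n < 4:
        raise ValueError("trace must have at least 4 samples")
    dt = trace.dt
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # population (1/N) estimator, matches G(0)
    if sigma == 0:
        raise ValueError("zero variance: constant trace has no fluctuations")
    if mu == 0:
        raise ValueError("zero mean: G(tau) normalization undefined")
    if max_lag is None:
        max_lag = (n // 2) * dt
    kmax = min(int(np.floor(max_lag / dt)), n - 1)
    d = x - mu
    g = np.empty(kmax + 1)
    for k in range(kmax + 1):
        g[k] = np.dot(d[: n - k], d[k:]) / (n - k)
    g /= mu**2
    tau = np.arange(kmax + 1) * dt
    return ACFResult(tau=tau, g=g, mean=mu, std=sigma)


def median_acf(acfs: Sequence[ACFResult]) -> ACFResult:
    """Pointwise median ACF over an ensemble of expression spots."""
    if len(acfs) == 0:
        raise ValueError("need at least one ACF")
    tau0 = acfs[0].tau
    for a in acfs[1:]:
        if len(a.tau) != len(tau0) or not np.allclose(a.tau, tau0):
            raise ValueError("ACFs must share a common delay grid")
    g = np.median(np.stack([a.g for a in acfs]), axis=0)
    return ACFResult(
        tau=tau0.copy(),
        g=g,
        mean=float(np.median([a.mean for a in acfs])),
        std=float(np.median([a.std for a in acfs])),
    )


def fit_monoexponential(
    acf: ACFResult, fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW
) -> ACFResult:
    """Fit G(tau) = G0 exp(-tau/tau_C) over the given delay window.

    The default window runs from one frame up to 10 minutes: beyond that the
    estimator is dominated by finite-sampling effects (small negative
    values).  Returns a copy of ``acf`` with ``g0_inverse`` and ``tau_c``
    set.  Raises ``RuntimeError`` on non-convergence instead of returning a
    silent fallback.
    """
    lo, hi = fit_window
    mask = (acf.tau >= lo) & (acf.tau <= hi)
    if mask.sum() < 4:
        raise ValueError("need at least 4 ACF points inside the fit window")
    tau, g = acf.tau[mask], acf.g[mask]

    def model(t, g0, tc):
        return g0 * np.exp(-t / tc)

    g0_init = max(float(g[0]), 1e-12)
    # crude 1/e crossing for the timescale start value
    below = np.nonzero(g < g0_init / np.e)[0]
    tc_init = float(tau[below[0]]) if len(below) else float(tau[-1]) / 2
    tc_init = max(tc_init, float(tau[1] - tau[0]))
    try:
        popt, _ = curve_fit(
            model, tau, g, p0=(g0_init, tc_init),
            bounds=((0, 0), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"mono-exponential ACF fit did not converge: {err}")
    g0, tc = popt
    return ACFResult(
        tau=acf.tau, g=acf.g, mean=acf.mean, std=acf.std,
        g0_inverse=float(1.0 / g0), tau_c=float(tc), fit_window=fit_window,
    )


def ideal_acf(k_tx: float, T: float, tau: np.ndarray | float) -> np.ndarray | float:
    """Triangular ACF of uncorrelated single-protein production, no bleaching.

    G(tau) = (T - tau)/(k_tx T^2) for tau < T and 0 beyond; G(0) = 1/(k_tx T).
    """
    if k_tx <= 0 or T <= 0:
        raise ValueError("k_tx and T must be positive")
    tau_arr = np.asarray(tau, dtype=float)
    g = np.where(tau_arr < T, (T - tau_arr) / (k_tx * T**2), 0.0)
    return g if np.ndim(tau) else float(g)


def linear_drift(trace: IntensityTrace) -> tuple[float, float]:
    """Ordinary least-squares fit I(t) = D*t + b; returns (D, b)."""
    if len(trace) < 2:
        raise ValueError("need at least 2 points for a linear fit")
    D, b = np.polyfit(trace.t, trace.intensity, 1)
    return float(D), float(b)


@dataclass
class LogisticFit:
    """4-parameter logistic fit of spot counts versus extension length."""

    midpoint: float  # L0, nt
    plateau: float
    baseline: float
    steepness: float  # nt; positive = counts increase with length
    midpoint_se: float = float("nan")

    def predict(self, length: np.ndarray | float) -> np.ndarray | float:
        L = np.asarray(length, dtype=float)
        out = self.baseline + (self.plateau - self.baseline) / (
            1.0 + np.exp(-(L - self.midpoint) / self.steepness)
        )
        return out if np.ndim(length) else float(out)


def _logistic(L, baseline, plateau, midpoint, steepness):
    return baseline + (plateau - baseline) / (1.0 + np.exp(-(L - midpoint) / steepness))


def fit_logistic_counts(
    lengths: Sequence[float], counts: Sequence[float]
) -> LogisticFit:
    """Fit a 4-parameter logistic to spot counts (or detection probability)
    versus C-terminal extension length; the midpoint L0 is the length at
    which counts reach half of the plateau-baseline range.

    Raises ``RuntimeError`` if the fit fails or converges to a
    wrong-signed (decreasing) curve.
    """
    L = np.asarray(lengths, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(L) < 4:
        raise ValueError("need at least 4 (length, count) pairs")
    span = float(L.max() - L.min())
    p0 = (float(y.min()), float(y.max()), float(np.median(L)), span / 8)
    try:
        popt, pcov = curve_fit(
            _logistic, L, y, p0=p0,
            bounds=((-np.inf, -np.inf, L.min(), 1e-6), (np.inf, np.inf, L.max(), np.inf)),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"logistic fit did not converge: {err}")
    baseline, plateau, midpoint, steepness = popt
    if plateau < baseline:
        raise RuntimeError("logistic fit converged to a decreasing curve")
    se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    return LogisticFit(
        midpoint=float(midpoint), plateau=float(plateau),
        baseline=float(baseline), steepness=float(steepness), midpoint_se=se,
    )


def spot_accounting(
    count_shortest: float, count_longest: float, frac_colocalized: float | None = None
) -> tuple[float, float | None]:
    """Bookkeeping of expression spots against non-specific adsorption.

    Spots seen with the shortest extension are attributed to non-specifically
    adsorbed dye; subtracting them from the longest-extension count gives the
    fraction of genuine nascent-protein spots.  Subtracting further the
    fraction directly co-localized with visible DNA gives the fraction
    attributed to unidentified (non-fluorescent) DNA.
    """
    if count_shortest < 0 or count_longest <= 0:
        raise ValueError("counts must be >= 0 with count_longest > 0")
    specific = (count_longest - count_shortest) / count_longest
    if specific < 0:
        raise ValueError("more spots at the shortest extension than the longest")
    if frac_colocalized is None:
        return float(specific), None
    unidentified = specific - frac_colocalized
    if unidentified < 0:
        raise ValueError("co-localized fraction exceeds the specific fraction")
    return float(specific), float(unidentified)


# ---------------------------------------------------------------------------
# Model / Results interface


class FluctuationModel:
    """Ensemble fluctuation model for a set of expression-spot traces.

    Computes the per-spot ACF, the pointwise median ACF of the ensemble, and
    fits a mono-exponential decay over the delay window to obtain the inverse
    amplitude G(0)^-1 and correlation time tau_C.

    Parameters
    ----------
    traces
        Expression-spot intensity traces on a common frame period.
    max_lag
        Largest ACF delay in seconds (default 600 s).
    """

    def __init__(self, traces: Sequence[IntensityTrace], max_lag: float = 600.0):
        if len(traces) == 0:
            raise ValueError("need at least one trace")
        self.traces = list(traces)
        self.max_lag = float(max_lag)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "FluctuationModel":
        """Build from a long-format trace table with columns
        ``trace_id, t, intensity``."""
        from .io import traces_from_table

        return cls(traces_from_table(table), **kwargs)

    @classmethod
    def from_simulation(
        cls, config, n_traces: int, mode: str = "random", **kwargs
    ) -> "FluctuationModel":
        """Simulate an ensemble with :mod:`dnadevice.simkit` and wrap it."""
        from .simkit import simulate_ensemble

        return cls(simulate_ensemble(config, n_traces, mode=mode), **kwargs)

    def fit(
        self, fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
        n_boot: int = 0, seed: int = 0,
    ) -> "FluctuationResults":
        """Fit the ensemble; optional bootstrap over spots for SEs."""
        acfs = [compute_acf(tr, self.max_lag) for tr in self.traces]
        med = median_acf(acfs)
        fitted = fit_monoexponential(med, fit_window)
        tau_c_se = g0inv_se = float("nan")
        if n_boot > 0 and len(acfs) > 1:
            rng = np.random.default_rng(seed)
            tcs, g0s = [], []
            for _ in range(n_boot):
                idx = rng.integers(0, len(acfs), size=len(acfs))
                try:
                    bf = fit_monoexponential(median_acf([acfs[i] for i in idx]), fit_window)
                except (RuntimeError, ValueError):
                    continue
                tcs.append(bf.tau_c)
                g0s.append(bf.g0_inverse)
            if len(tcs) >= 2:
                tau_c_se = float(np.std(tcs, ddof=1))
                g0inv_se = float(np.std(g0s, ddof=1))
        return FluctuationResults(self, acfs, fitted, tau_c_se, g0inv_se)


@dataclass
class FluctuationResults:
    """Fitted ensemble ACF: estimates, bootstrap SEs, and diagnostics."""

    model: FluctuationModel
    spot_acfs: list[ACFResult]
    median: ACFResult
    tau_c_se: float
    g0_inverse_se: float

    @property
    def tau_c(self) -> float:
        return self.median.tau_c

    @property
    def g0_inverse(self) -> float:
        return self.median.g0_inverse

    @property
    def n_spots(self) -> int:
        return len(self.spot_acfs)

    def summary(self) -> str:
        lines = [
            "Ensemble fluctuation analysis (median ACF, mono-exponential fit)",
            "-" * 64,
            f"spots                     {self.n_spots}",
            f"ACF delay window (s)      {self.median.fit_window}",
            f"G(0) (median ACF)         {self.median.g0:.4g}",
            f"G(0)^-1 (fit)             {self.g0_inverse:.4g}"
            + (f" +/- {self.g0_inverse_se:.2g}" if np.isfinite(self.g0_inverse_se) else ""),
            f"tau_C (fit, s)            {self.tau_c:.4g}"
            + (f" +/- {self.tau_c_se:.2g}" if np.isfinite(self.tau_c_se) else ""),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Median ACF curve as a tidy table (tau_s, g)."""
        return pd.DataFrame({"tau_s": self.median.tau, "g": self.median.g})

    def plot(self, ax=None):
        """Median ACF with the fitted mono-exponential overlay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.median.tau, self.median.g, "o", ms=3, label="median ACF")
        lo, hi = self.median.fit_window
        tt = np.linspace(lo, hi, 200)
        ax.plot(tt, (1.0 / self.g0_inverse) * np.exp(-tt / self.tau_c),
                "-", label=f"fit: tau_C={self.tau_c:.0f} s")
        ax.set_xlabel("delay tau (s)")
        ax.set_ylabel("G(tau)")
        ax.legend()
        return ax


class LogisticLengthModel:
    """Spot count (or detection probability) versus gene-extension length.

    ``fit()`` returns the :class:`LogisticFit`; the midpoint L0 estimates
    the extension length at which nascent proteins just have time to fold
    and bind dye before release, i.e. L0 ~ v * (t_fold + t_dye).
    """

    def __init__(self, lengths: Sequence[float], counts: Sequence[float]):
        self.lengths = np.asarray(lengths, dtype=float)
        self.counts = np.asarray(counts, dtype=float)

    @classmethod
    def from_detection_sweep(
        cls, base_config, lengths: Sequence[float], n_reps: int = 10_000
    ) -> "LogisticLengthModel":
        """Generate detection probabilities with the mechanistic model at
        each extension length and wrap them for logistic fitting."""
        from .simkit import detection_probability

        probs = []
        for i, L in enumerate(lengths):
            cfg = base_config.replace(
                gene_extension_length=float(L), seed=int(base_config.seed + i)
            )
            probs.append(detection_probability(cfg, n_reps))
        return cls(lengths, probs)

    def fit(self) -> LogisticFit:
        return fit_logistic_counts(self.lengths, self.counts)
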