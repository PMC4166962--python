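"""First- and second-order spike-train statistics.

The spike train is treated as a sum of delta functions x(t) = sum_i
delta(t - t_i).  Its power spectrum is estimated as the average over
non-overlapping rectangular windows of |x~(f)|^2 / T, where x~ is the
finite-window Fourier transform of the binned train (bin value =
count/dt).  With times in ms and the window converted to seconds, S(f)
carries units of Hz and approaches the firing rate nu at high frequency;
the zero-frequency bin (which carries the nu^2 T mean-rate term) is
removed rather than mean-subtracting the signal.

For a renewal process the spectrum follows from the ISI density alone:

    S(f) = nu * (1 - |rho~(f)|^2) / |1 - rho~(f)|^2,

with rho~ the Fourier transform of the ISI density, evaluated here as the
empirical characteristic function of an interval sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "ISIStats",
    "PowerSpectrum",
    "InsufficientDataError",
    "isi_statistics",
    "spike_spectrum",
    "renewal_spectrum",
]

#: below this many pooled lag pairs a serial correlation estimate is flagged
LOW_CONFIDENCE_PAIRS = 100


class InsufficientDataError(ValueError):
    """Fewer spikes than the requested statistic needs."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) within an observation window [0, duration]."""

    times: np.ndarray
    duration: float
    trial_id: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike times must form a 1-d array")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration + 1e-9:
                raise ValueError("spike times must lie within [0, duration]")
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class ISIStats:
    """Pooled interspike-interval statistics of one generation or run.

    ``rho`` holds serial correlation coefficients for lags 1..K, estimated
    per trial (intervals never span trial boundaries) and pooled with
    interval-pair-count weighting; ``rho_low_confidence`` flags lags with
    fewer than ``LOW_CONFIDENCE_PAIRS`` pooled pairs.
    """

    rate: float
    cv: float
    rho: np.ndarray
    isi_sample: np.ndarray
    n_intervals: int
    rho_pairs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.rate < 0 or self.cv < 0:
            raise ValueError("rate and cv must be non-negative")
        rho = np.asarray(self.rho, dtype=float)
        if rho.size and np.any(np.abs(rho) > 1 + 1e-9):
            raise ValueError("serial correlation coefficients must lie in [-1, 1]")
        object.__setattr__(self, "rho", rho)

    @property
    def rho_low_confidence(self) -> np.ndarray:
        return self.rho_pairs < LOW_CONFIDENCE_PAIRS


@dataclass(frozen=True)
class PowerSpectrum:
    """Frequency grid (Hz) and spectral values with estimation metadata.

    ``values`` are in Hz for spike trains and mV^2/Hz for current traces;
    the f=0 bin is excluded.  ``flags`` optionally marks bins where an
    analytic limit replaced an ill-conditioned estimate.
    """

    freq: np.ndarray
    values: np.ndarray
    delta_f: float
    n_windows: int = 0
    window_length: float | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if freq.shape != values.shape or freq.ndim != 1:
            raise ValueError("freq and values must be matching 1-d arrays")
        if freq.size:
            if freq[0] <= 0 or np.any(np.diff(freq) <= 0):
                raise ValueError("freq must be strictly increasing and exclude 0")
            if np.any(values < -1e-12):
                raise ValueError("spectral values must be non-negative")
        if self.window_length is not None:
            expected = 1000.0 / self.window_length
            if abs(self.delta_f - expected) > 1e-6 * expected:
                raise ValueError(
                    f"delta_f={self.delta_f} inconsistent with window_length="
                    f"{self.window_length} ms (expected {expected} Hz)"
                )
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "values", np.maximum(values, 0.0))

    def band(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        """Restrict to the frequency band [f_lo, f_hi]."""
        m = (self.freq >= f_lo) & (self.freq <= f_hi)
        return PowerSpectrum(
            self.freq[m], self.values[m], self.delta_f, self.n_windows,
            self.window_length, None if self.flags is None else self.flags[m],
        )


def isi_statistics(trains: list[SpikeTrain], max_lag: int = 5) -> ISIStats:
    """Rate, CV and serial correlations from pooled per-trial ISIs.

    Intervals are pooled within trials only, so no interval spans a trial
    boundary.  The rate is 1/<I> converted to Hz; the CV is the pooled
    interval standard deviation over the mean.  Serial correlations at each
    feasible lag are computed per trial with the sample-mean-centered
    covariance estimator and pooled with pair-count weights.
    """
    per_trial = [t.intervals() for t in trains if t.n_spikes >= 2]
    if not per_trial:
        raise InsufficientDataError("need at least 2 spikes in at least one train")
    pooled = np.concatenate(per_trial)
    mean = pooled.mean()
    sd = pooled.std(ddof=1) if pooled.size > 1 else 0.0
    cv = sd / mean
    rate = 1000.0 / mean

    max_feasible = max(x.size - 1 for x in per_trial)
    lags = range(1, min(max_lag, max_feasible) + 1)
    rho, pairs = [], []
    for k in lags:
        num = den = 0.0
        n_pairs = 0
        for x in per_trial:
            if x.size <= k:
                continue
            xc = x - x.mean()
            c_k = np.dot(xc[:-k], xc[k:]) / (x.size - k)
            c_0 = np.dot(xc, xc) / (x.size - 1) if x.size > 1 else 0.0
            w = x.size - k
            num += w * (c_k / c_0 if c_0 > 0 else 0.0)
            den += w
            n_pairs += w
        rho.append(num / den if den else 0.0)
        pairs.append(n_pairs)
    return ISIStats(
        rate=rate,
        cv=cv,
        rho=np.clip(np.array(rho), -1.0, 1.0),
        isi_sample=pooled,
        n_intervals=pooled.size,
        rho_pairs=np.array(pairs, dtype=int),
    )


def spike_spectrum(
    trains: list[SpikeTrain],
    window_length: float = 1638.4,
    dt: float = 0.1,
) -> PowerSpectrum:
    """Averaged periodogram of binned spike trains (rectangular windows).

    Each trial is split into non-overlapping windows of ``window_length``
    ms; empty windows contribute zero power.  The high-frequency tail of
    the estimate converges to the firing rate.
    """
    n_bin = int(round(window_length / dt))
    if n_bin < 2:
        raise ValueError("window_length must span at least 2 steps")
    window_length = n_bin * dt
    t_win_s = window_length / 1000.0

    segments = []
    for train in trains:
        n_win = int(np.floor(train.duration / window_length + 1e-9))
        if n_win == 0:
            continue
        span = n_win * n_bin
        steps = np.floor(train.times / dt).astype(np.int64)
        steps = steps[steps < span]
        counts = np.bincount(steps, minlength=span).astype(float)
        segments.append(counts.reshape(n_win, n_bin))
    if not segments:
        raise ValueError("window_length exceeds the duration of every train")
    counts = np.concatenate(segments, axis=0)
    spec = np.fft.rfft(counts, axis=1)
    power = (spec.real**2 + spec.imag**2) / t_win_s
    values = power.mean(axis=0)[1:]  # drop the f=0 (mean-rate) bin
    delta_f = 1000.0 / window_length
    freq = delta_f * np.arange(1, values.size + 1)
    return PowerSpectrum(
        freq=freq,
        values=values,
        delta_f=delta_f,
        n_windows=counts.shape[0],
        window_length=window_length,
    )


def _char_function(isi_sample: np.ndarray, freq: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Empirical characteristic function mean(exp(2*pi*i*f*I)) on a Hz grid."""
    t_s = isi_sample / 1000.0
    out = np.empty(freq.size, dtype=complex)
    for lo in range(0, freq.size, chunk):
        f = freq[lo : lo + chunk]
        out[lo : lo + chunk] = np.exp(2j * np.pi * np.outer(f, t_s)).mean(axis=1)
    return out


def renewal_spectrum(
    isi_density,
    rate: float,
    freq: np.ndarray,
    tol: float = 1e-6,
    max_sample: int = 50_000,
) -> PowerSpectrum:
    """Power spectrum of a renewal process from its ISI law.

    ``isi_density`` is either an array of sampled intervals (ms) — the
    characteristic function is then the mean of complex exponentials over
    the sample, with no histogram smoothing — or a callable density rho(I)
    per ms, integrated on a fine grid.  Bins where |1 - rho~| falls below
    ``tol`` (f -> 0 as CV -> 0) are replaced by the analytic limit
    nu * CV^2 and flagged.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    freq = np.asarray(freq, dtype=float)
    if callable(isi_density):
        mean_ms = 1000.0 / rate
        t = np.linspace(0.0, 50.0 * mean_ms, 200_001)
        rho_t = np.asarray([isi_density(x) for x in t]) if np.ndim(
            isi_density(t[:2])
        ) == 0 else isi_density(t)
        rho_t = np.maximum(np.asarray(rho_t, dtype=float), 0.0)
        norm = np.trapezoid(rho_t, t)
        if not 0.98 < norm < 1.02:
            raise ValueError(f"ISI density integrates to {norm:.4f}, not 1")
        rho_t /= norm
        phases = np.exp(2j * np.pi * np.outer(freq, t / 1000.0))
        char = np.trapezoid(phases * rho_t, t, axis=1)
        m1 = np.trapezoid(t * rho_t, t)
        m2 = np.trapezoid(t**2 * rho_t, t)
        cv2 = (m2 - m1**2) / m1**2
    else:
        sample = np.asarray(isi_density, dtype=float)
        if sample.size == 0 or np.any(sample < 0):
            raise ValueError("ISI sample must be non-empty and non-negative")
        if sample.size > max_sample:
            sample = sample[:: int(np.ceil(sample.size / max_sample))]
        char = _char_function(sample, freq)
        cv2 = sample.var(ddof=1) / sample.mean() ** 2

    denom = np.abs(1.0 - char) ** 2
    bad = denom < tol**2
    with np.errstate(divide="ignore", invalid="ignore"):
        values = rate * (1.0 - np.abs(char) ** 2) / denom
    values[bad] = rate * cv2
    values = np.maximum(values, 0.0)
    delta_f = float(np.median(np.diff(freq))) if freq.size > 1 else 1.0
    return PowerSpectrum(
        freq=freq, values=values, delta_f=delta_f, n_windows=0,
        window_length=None, flags=bad,
    )
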