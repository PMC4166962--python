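"""Stationary Gaussian current with a prescribed power spectrum.

The Gaussian approximation replaces the summed local spike-train input by
a colored Gaussian current eta(t) with

    <eta>     = RI_ext + C_E J (1 - g gamma) nu tau,
    S_eta(f)  = (C_E J^2 + C_I g^2 J^2) tau^2 S_x(f),

where S_x is the spike-train power spectrum (Hz, two-sided density) of the
previous generation and tau is in seconds, giving S_eta in mV^2/Hz.

Synthesis draws, in each frequency bin, two independent zero-mean Gaussian
numbers for the real and imaginary parts of the spectrum such that the
ensemble-averaged periodogram of the output equals the target exactly; the
inverse FFT then yields the real, stationary time series.  Bin 0 carries
only the mean and the Nyquist bin is made real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif_core import CurrentTrace
from .rate_map import SynapseConfig
from .spike_stats import PowerSpectrum

__all__ = ["SpectrumTarget", "gaussian_series", "build_gaussian_surrogate"]


@dataclass(frozen=True)
class SpectrumTarget:
    """Target spectrum (mV^2/Hz) and mean (mV) on the synthesis FFT grid.

    The grid covers bins k = 1 .. n_samples//2 with spacing
    delta_f = 1/(n_samples * dt), dt in ms hence delta_f in kHz converted
    to Hz below.
    """

    freq: np.ndarray
    values: np.ndarray
    mean: float
    n_samples: int
    dt: float

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if freq.shape != values.shape or freq.ndim != 1:
            raise ValueError("freq and values must be matching 1-d arrays")
        if np.any(values < 0):
            raise ValueError("target spectral values must be non-negative")
        if self.n_samples % 2 != 0:
            raise ValueError("n_samples must be even")
        if freq.size != self.n_samples // 2:
            raise ValueError(
                f"target must cover the {self.n_samples // 2}-bin synthesis grid, "
                f"got {freq.size} bins"
            )
        delta_f = 1000.0 / (self.n_samples * self.dt)
        expected = delta_f * np.arange(1, self.n_samples // 2 + 1)
        if not np.allclose(freq, expected, rtol=1e-9, atol=1e-9):
            raise ValueError("target grid does not match the synthesis FFT grid")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "values", values)

    @property
    def delta_f(self) -> float:
        return 1000.0 / (self.n_samples * self.dt)

    @property
    def total_power(self) -> float:
        """Integral of the two-sided spectrum over the full band (mV^2)."""
        return 2.0 * float(np.sum(self.values)) * self.delta_f


def gaussian_series(
    target: SpectrumTarget,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> CurrentTrace:
    """Synthesize one realization of the Gaussian current (mV).

    Per interior bin the complex spectral amplitude has independent real
    and imaginary Gaussian components whose variance is chosen so that the
    periodogram estimator dt |FFT|^2 / N reproduces the target; the
    Nyquist bin is real with twice that variance.
    """
    n = target.n_samples
    dt_s = target.dt / 1000.0
    # variance per real/imag component so that <|G_k|^2> = S_k * N / dt_s
    sigma = np.sqrt(target.values * n / (2.0 * dt_s))
    spec = np.zeros(n // 2 + 1, dtype=complex)
    spec[1:-1] = rng.normal(scale=sigma[:-1]) + 1j * rng.normal(scale=sigma[:-1])
    spec[-1] = rng.normal(scale=np.sqrt(2.0) * sigma[-1])
    spec[0] = target.mean * n
    values = np.fft.irfft(spec, n=n)
    return CurrentTrace(values=values, dt=target.dt, t_start=t_start)


def build_gaussian_surrogate(
    prev_spectrum: PowerSpectrum,
    prev_rate: float,
    syn: SynapseConfig,
    external_mean: float,
    tau_m: float,
    n_samples: int,
    dt: float,
) -> SpectrumTarget:
    """Target spectrum and mean for the next generation's Gaussian input.

    The measured spectrum is linearly interpolated onto the synthesis grid;
    beyond the measured band it is extrapolated as the high-frequency
    plateau (spike spectra approach the rate nu there), below the first
    measured bin as the first measured value.
    """
    if prev_rate <= 0:
        raise ValueError("previous-generation rate must be positive")
    if prev_spectrum.freq.size < 2:
        raise ValueError("previous spectrum has too few bins to interpolate")
    delta_f = 1000.0 / (n_samples * dt)
    freq = delta_f * np.arange(1, n_samples // 2 + 1)
    if freq[-1] > prev_spectrum.freq[-1] * 2.0 + 1e-9:
        raise ValueError(
            "synthesis grid extends far beyond the measured band "
            f"({freq[-1]:.1f} Hz vs {prev_spectrum.freq[-1]:.1f} Hz)"
        )
    s_x = np.interp(
        freq, prev_spectrum.freq, prev_spectrum.values,
        left=prev_spectrum.values[0], right=prev_rate,
    )
    tau_s = tau_m / 1000.0
    values = syn.amplitude_factor * tau_s**2 * s_x
    mean = external_mean + syn.J * (syn.C_E - syn.g * syn.C_I) * prev_rate * tau_s
    return SpectrumTarget(freq=freq, values=values, mean=mean,
                          n_samples=n_samples, dt=dt)
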