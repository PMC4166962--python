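"""Generation loop for the self-consistent spike-train statistics.

A single LIF neuron is simulated over repeated trials.  Generation 1 is
driven by a constant external mean plus C_E + C_I independent Poisson
trains at a chosen rate (the "zeroth generation").  Every later generation
receives surrogate input built from the previous generation's measured
output statistics, under one of two approximations:

``gaussian``
    a stationary Gaussian current whose spectrum is proportional to the
    previous spike-train power spectrum (mean from the rate);

``renewal``
    a superposition of C_E + C_I independent equilibrium renewal trains
    resampling the previous ISI distribution, delivered as signed delta
    pulses.

The loop stops when the spectra of consecutive generations agree (relative
integrated squared difference below tolerance twice in a row and the rate
settled), when the rate trajectory diverges (growing oscillations — the
instability of the underlying rate map), or at the generation cap.  No
synaptic delay appears in the scheme: the surrogate input is stationary,
so a delay would not change any statistic of the driven neuron.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len

from .lif_core import NeuronParams, integrate_batch
from .rate_map import SynapseConfig
from .spike_stats import (PowerSpectrum, SpikeTrain, isi_statistics,
                          spike_spectrum)
from .surrogate_gaussian import build_gaussian_surrogate, gaussian_series
from .surrogate_renewal import RenewalSampler, sample_renewal_trains

__all__ = [
    "IterationConfig",
    "GenerationRecord",
    "DegenerateInputError",
    "run_generation_zero",
    "run_iteration",
    "spectral_distance",
    "child_rng",
]


class DegenerateInputError(RuntimeError):
    """A generation produced no output spikes in any trial."""


def child_rng(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Independent generator derived from a master seed and a component name."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence((seed, key, index)))


@dataclass(frozen=True)
class IterationConfig:
    """Run control for the generation loop.

    ``trial_duration`` includes a ``warmup`` interval that is discarded
    from all statistics; the remainder should hold an integer number of
    spectral estimation windows of ``window_length`` ms.
    """

    scheme: str = "gaussian"
    syn: SynapseConfig = field(default_factory=SynapseConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    init_rate: float = 71.0
    trials_per_generation: int = 20
    trial_duration: float = 10030.4
    warmup: float = 200.0
    window_length: float = 1638.4
    max_generations: int = 15
    min_generations: int = 2
    convergence_tol: float = 0.01
    rate_tol: float = 1.0
    rate_bounds: tuple = (1.0, 450.0)
    max_lag: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("gaussian", "renewal"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.trials_per_generation < 1:
            raise ValueError("trials_per_generation must be >= 1")
        if self.max_generations < 2:
            raise ValueError("max_generations must be >= 2")
        if not 2 <= self.min_generations <= self.max_generations:
            raise ValueError("min_generations must lie in "
                             "[2, max_generations]")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be positive")
        if self.trial_duration - self.warmup < self.window_length:
            raise ValueError("trial_duration minus warmup must hold at least "
                             "one spectral window")

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.neuron.dt))


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation snapshot logged by the iteration driver."""

    index: int
    rate: float
    cv: float
    rho: np.ndarray
    spectrum: PowerSpectrum
    isi_sample: np.ndarray
    distance_to_previous: float
    seed_key: tuple


def spectral_distance(a: PowerSpectrum, b: PowerSpectrum,
                      band: tuple = (0.0, 500.0)) -> float:
    """Relative integrated squared difference of two spectra on a band.

    Int (S_a - S_b)^2 df / Int S_b^2 df, with S_a linearly interpolated
    onto b's frequency grid restricted to the common band.
    """
    lo = max(band[0], a.freq[0], b.freq[0])
    hi = min(band[1], a.freq[-1], b.freq[-1])
    mask = (b.freq >= lo) & (b.freq <= hi)
    if not mask.any():
        raise ValueError(
            f"spectra share no frequency band within [{band[0]}, {band[1]}] Hz")
    f = b.freq[mask]
    sb = b.values[mask]
    sa = np.interp(f, a.freq, a.values)
    num = np.trapezoid((sa - sb) ** 2, f)
    den = np.trapezoid(sb**2, f)
    if den == 0:
        raise ValueError("reference spectrum has zero power on the band")
    return float(num / den)


def _measure(config: IterationConfig, spike_times: list[np.ndarray],
             index: int, distance: float, seed_key: tuple) -> GenerationRecord:
    trains = []
    usable = config.trial_duration - config.warmup
    for i, times in enumerate(spike_times):
        kept = times[times > config.warmup] - config.warmup
        trains.append(SpikeTrain(times=kept, duration=usable, trial_id=i))
    if sum(t.n_spikes for t in trains) == 0:
        raise DegenerateInputError(
            f"generation {index}: no output spikes in any trial")
    stats = isi_statistics(trains, max_lag=config.max_lag)
    spectrum = spike_spectrum(trains, window_length=config.window_length,
                              dt=config.neuron.dt)
    return GenerationRecord(
        index=index, rate=stats.rate, cv=stats.cv, rho=stats.rho,
        spectrum=spectrum, isi_sample=stats.isi_sample,
        distance_to_previous=distance, seed_key=seed_key,
    )


def run_generation_zero(config: IterationConfig) -> GenerationRecord:
    """First generation: LIF driven by Poisson trains at ``init_rate``.

    The C_E excitatory (+J) and C_I inhibitory (-gJ) Poisson streams are
    delivered through their per-step summed jumps (exactly equivalent to
    event delivery on the Euler grid); the constant external mean adds to
    the current.  ``init_rate = 0`` leaves only the deterministic constant
    drive.
    """
    if config.init_rate < 0:
        raise ValueError("init_rate must be non-negative")
    syn, neuron = config.syn, config.neuron
    rng = child_rng(config.seed, "generation", 1)
    n_steps = config.n_steps
    n_trials = config.trials_per_generation
    jumps = None
    if config.init_rate > 0:
        dt_s = neuron.dt / 1000.0
        lam_e = syn.C_E * config.init_rate * dt_s
        lam_i = syn.C_I * config.init_rate * dt_s
        jumps = syn.J * rng.poisson(lam_e, (n_trials, n_steps)).astype(float)
        if syn.C_I > 0:
            jumps -= syn.g * syn.J * rng.poisson(lam_i, (n_trials, n_steps))
    v0 = rng.uniform(0.0, neuron.v_threshold, n_trials)
    spike_times = integrate_batch(neuron, syn.external_mean, jumps, v0,
                                  n_steps=n_steps)
    return _measure(config, spike_times, index=1, distance=np.nan,
                    seed_key=(config.seed, "generation", 1))


def _next_generation(config: IterationConfig, prev: GenerationRecord,
                     index: int) -> GenerationRecord:
    syn, neuron = config.syn, config.neuron
    rng = child_rng(config.seed, "generation", index)
    n_steps = config.n_steps
    n_trials = config.trials_per_generation
    v0 = rng.uniform(0.0, neuron.v_threshold, n_trials)

    if config.scheme == "gaussian":
        n_fft = next_fast_len(n_steps, real=True)
        if n_fft % 2:
            n_fft = next_fast_len(n_fft + 1, real=True)
        target = build_gaussian_surrogate(
            prev.spectrum, prev.rate, syn, syn.external_mean,
            neuron.tau_m, n_fft, neuron.dt,
        )
        drives = np.empty((n_trials, n_steps))
        for i in range(n_trials):
            drives[i] = gaussian_series(target, rng).values[:n_steps]
        spike_times = integrate_batch(neuron, drives, None, v0, n_steps=n_steps)
    else:
        sampler = RenewalSampler.from_sample(prev.isi_sample)
        jumps = np.zeros((n_trials, n_steps))
        dt = neuron.dt
        T = config.trial_duration
        for i in range(n_trials):
            exc = sample_renewal_trains(sampler, syn.C_E, T, rng)
            inh = sample_renewal_trains(sampler, syn.C_I, T, rng)
            for trains, amp in ((exc, syn.J), (inh, -syn.g * syn.J)):
                for train in trains:
                    idx = np.floor(train.times / dt).astype(np.int64)
                    idx = idx[idx < n_steps]
                    np.add.at(jumps[i], idx, amp)
        spike_times = integrate_batch(neuron, syn.external_mean, jumps, v0,
                                      n_steps=n_steps)

    record = _measure(config, spike_times, index=index, distance=np.nan,
                      seed_key=(config.seed, "generation", index))
    distance = spectral_distance(record.spectrum, prev.spectrum)
    return GenerationRecord(
        index=record.index, rate=record.rate, cv=record.cv, rho=record.rho,
        spectrum=record.spectrum, isi_sample=record.isi_sample,
        distance_to_previous=distance, seed_key=record.seed_key,
    )


def _growing_oscillation(rates: list[float], min_amp: float = 5.0) -> bool:
    """Alternating-sign rate differences with growing magnitude (3 in a row)."""
    if len(rates) < 4:
        return False
    d = np.diff(rates[-4:])
    alternating = d[0] * d[1] < 0 and d[1] * d[2] < 0
    growing = abs(d[2]) > abs(d[1]) > abs(d[0])
    return alternating and growing and abs(d[2]) > min_amp


def run_iteration(config: IterationConfig) -> tuple[list[GenerationRecord], str]:
    """Run the generation loop until convergence, instability, or the cap.

    Returns the per-generation records and a status string: ``converged``
    (spectral distance below tolerance twice in a row with a settled
    rate), ``unstable`` (rate left the admissible band or its oscillation
    grows over consecutive generations), or ``max_generations``.
    """
    records = [run_generation_zero(config)]
    status = "max_generations"
    consecutive = 0
    lo, hi = config.rate_bounds
    for index in range(2, config.max_generations + 1):
        try:
            record = _next_generation(config, records[-1], index)
        except DegenerateInputError:
            status = "unstable"
            break
        rate_change = abs(record.rate - records[-1].rate)
        records.append(record)
        if not (lo <= record.rate <= hi):
            status = "unstable"
            break
        if _growing_oscillation([r.rate for r in records]):
            status = "unstable"
            break
        if (record.distance_to_previous < config.convergence_tol
                and rate_change < config.rate_tol):
            consecutive += 1
        else:
            consecutive = 0
        if consecutive >= 2 and index >= config.min_generations:
            status = "converged"
            break
    return records, status
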