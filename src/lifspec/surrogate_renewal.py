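"""Equilibrium renewal spike trains with an empirically measured ISI law.

Surrogate input trains are renewal processes whose interval distribution
is the pooled ISI sample of the previous generation.  Interval generation
resamples the empirical sample with replacement — no density smoothing, so
the measured law is preserved exactly.  Two equilibration methods make the
trains stationary on the observation window:

``forward_recurrence`` (default)
    The first spike is a sample of the forward-recurrence time, whose
    density is rho_FR(t1) = nu * Int_t1^inf rho(t') dt'.  This is sampled
    exactly by length-biased interval selection (probability proportional
    to the interval) followed by a uniform position within the chosen
    interval.

``burnin``
    A synchronizing spike is placed at -T_0 with T_0 ~ 1/(nu CV^2) and
    only spikes inside [0, T] are kept; T_0 is capped at a configurable
    multiple of the mean ISI (with a warning) to avoid overflow as CV -> 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lif_core import EventStream
from .spike_stats import SpikeTrain

__all__ = ["RenewalSampler", "sample_renewal_train", "sample_renewal_trains",
           "superpose_trains"]


@dataclass(frozen=True)
class RenewalSampler:
    """Empirical ISI law plus the equilibration method for stationarity."""

    isi_sample: np.ndarray
    rate: float
    cv: float
    method: str = "forward_recurrence"
    t0_cap_multiple: float = 50.0

    def __post_init__(self) -> None:
        sample = np.asarray(self.isi_sample, dtype=float)
        if sample.size == 0 or np.any(sample <= 0):
            raise ValueError("ISI sample must be non-empty with positive intervals")
        if self.method not in ("forward_recurrence", "burnin"):
            raise ValueError(f"unknown equilibration method {self.method!r}")
        implied = 1000.0 / sample.mean()
        if abs(implied - self.rate) > 0.05 * implied:
            raise ValueError(
                f"rate {self.rate:.3f} Hz inconsistent with sample mean "
                f"({implied:.3f} Hz)"
            )
        object.__setattr__(self, "isi_sample", sample)

    @classmethod
    def from_sample(cls, isi_sample: np.ndarray, method: str = "forward_recurrence",
                    **kwargs) -> "RenewalSampler":
        sample = np.asarray(isi_sample, dtype=float)
        rate = 1000.0 / sample.mean()
        cv = sample.std(ddof=1) / sample.mean() if sample.size > 1 else 0.0
        return cls(isi_sample=sample, rate=rate, cv=cv, method=method, **kwargs)

    @property
    def mean_isi(self) -> float:
        return float(self.isi_sample.mean())

    def burnin_t0(self) -> float:
        """Equilibration period T_0 ~ 1/(nu CV^2) in ms, capped for small CV."""
        cap = self.t0_cap_multiple * self.mean_isi
        if self.cv <= 0:
            warnings.warn("CV = 0: burn-in period capped at "
                          f"{self.t0_cap_multiple} mean ISIs", stacklevel=2)
            return cap
        t0 = 1000.0 / (self.rate * self.cv**2)
        if t0 > cap:
            warnings.warn(
                f"burn-in T_0 = {t0:.0f} ms capped at {cap:.0f} ms "
                f"({self.t0_cap_multiple} mean ISIs)", stacklevel=2)
            return cap
        return t0


def _forward_recurrence_times(sampler: RenewalSampler, size: int,
                              rng: np.random.Generator) -> np.ndarray:
    sample = sampler.isi_sample
    p = sample / sample.sum()
    chosen = rng.choice(sample, size=size, p=p)  # length-biased selection
    return chosen * rng.random(size)


def sample_renewal_train(
    sampler: RenewalSampler, T: float, rng: np.random.Generator, trial_id: int = 0
) -> SpikeTrain:
    """Draw one equilibrium renewal spike train on [0, T]."""
    return sample_renewal_trains(sampler, 1, T, rng, first_trial_id=trial_id)[0]


def sample_renewal_trains(
    sampler: RenewalSampler,
    n_trains: int,
    T: float,
    rng: np.random.Generator,
    first_trial_id: int = 0,
) -> list[SpikeTrain]:
    """Draw many independent equilibrium renewal trains on [0, T] at once.

    All trains are generated from matrix draws of resampled intervals,
    topping up the rare rows whose cumulative sum falls short of T.
    """
    if T <= 0:
        raise ValueError("window length T must be positive")
    sample = sampler.isi_sample
    mean = sampler.mean_isi

    if sampler.method == "forward_recurrence":
        origin = _forward_recurrence_times(sampler, n_trains, rng)
    else:
        origin = np.full(n_trains, -sampler.burnin_t0())

    span = T - origin.min()
    m = int(span / mean * 1.25 + 10.0 * np.sqrt(span / mean + 1.0)) + 2
    isi = rng.choice(sample, size=(n_trains, m))
    times = origin[:, None] + np.concatenate(
        [np.zeros((n_trains, 1)), np.cumsum(isi, axis=1)], axis=1
    )
    trains: list[SpikeTrain] = []
    for i in range(n_trains):
        t = times[i]
        while t[-1] < T:  # top up rows that fell short
            extra = rng.choice(sample, size=max(16, int((T - t[-1]) / mean * 2) + 8))
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
        if sampler.method == "forward_recurrence":
            kept = t[t <= T]
        else:
            kept = t[(t >= 0) & (t <= T)]
        trains.append(SpikeTrain(times=kept, duration=T,
                                 trial_id=first_trial_id + i))
    return trains


def superpose_trains(
    excitatory: list[SpikeTrain],
    inhibitory: list[SpikeTrain],
    J: float,
    g: float,
) -> EventStream:
    """Merge C_E excitatory (+J) and C_I inhibitory (-gJ) trains, time-sorted."""
    times_list, amp_list = [], []
    for train in excitatory:
        times_list.append(train.times)
        amp_list.append(np.full(train.n_spikes, J))
    for train in inhibitory:
        times_list.append(train.times)
        amp_list.append(np.full(train.n_spikes, -g * J))
    if not times_list:
        return EventStream.empty()
    times = np.concatenate(times_list)
    amps = np.concatenate(amp_list)
    order = np.argsort(times, kind="stable")
    return EventStream(times=times[order], amplitudes=amps[order])
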