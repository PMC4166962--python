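"""Leaky integrate-and-fire dynamics under current and delta-pulse input.

Between spikes the membrane voltage obeys

    tau_m * dv/dt = -v + RI(t),

integrated with a plain forward-Euler scheme on a fixed grid of step ``dt``:
``v <- v + (dt/tau_m) * (RI - v)``.  A presynaptic delta pulse of area
``tau_m * J`` in ``RI`` adds its amplitude ``J`` to the voltage
instantaneously; equivalently, a binned current pulse of height
``J * tau_m / dt`` lasting one step produces the same jump.  Whenever the
voltage reaches the threshold a spike is recorded at the end of the step,
the voltage is clamped at the reset value for an absolute refractory period
``tau_ref`` (during which incoming events are discarded), and integration
resumes from the reset voltage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "CurrentTrace",
    "EventStream",
    "NumericalBlowupError",
    "integrate_lif",
    "integrate_batch",
    "apply_event",
    "bin_events",
]


class NumericalBlowupError(RuntimeError):
    """Voltage became non-finite during integration."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane and discretization constants of a single LIF neuron.

    Parameters
    ----------
    tau_m
        Membrane time constant (ms).
    v_threshold
        Firing threshold (mV).
    v_reset
        Reset voltage after the refractory period (mV).
    tau_ref
        Absolute refractory period (ms); rounded to an integer multiple of
        ``dt`` at construction (a warning records any adjustment).
    dt
        Euler time step (ms).
    """

    tau_m: float = 20.0
    v_threshold: float = 20.0
    v_reset: float = 10.0
    tau_ref: float = 2.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.dt < self.tau_m:
            raise ValueError(f"dt={self.dt} must be smaller than tau_m={self.tau_m}")
        if not self.v_reset < self.v_threshold:
            raise ValueError(
                f"v_reset={self.v_reset} must lie below v_threshold={self.v_threshold}"
            )
        if self.tau_ref < 0:
            raise ValueError(f"tau_ref must be non-negative, got {self.tau_ref}")
        rounded = round(self.tau_ref / self.dt) * self.dt
        if abs(rounded - self.tau_ref) > 1e-9 * max(1.0, self.dt):
            warnings.warn(
                f"tau_ref={self.tau_ref} ms rounded to {rounded} ms "
                f"(integer multiple of dt={self.dt} ms)",
                stacklevel=2,
            )
            object.__setattr__(self, "tau_ref", rounded)

    @property
    def n_ref(self) -> int:
        """Refractory period in Euler steps."""
        return int(round(self.tau_ref / self.dt))


@dataclass(frozen=True)
class CurrentTrace:
    """Sampled input current ``RI(t)`` (mV) on the Euler grid."""

    values: np.ndarray
    dt: float = 0.1
    t_start: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("CurrentTrace.values must be a non-empty 1-d array")
        if not np.all(np.isfinite(values)):
            raise ValueError("CurrentTrace.values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def duration(self) -> float:
        return self.values.size * self.dt


@dataclass(frozen=True)
class EventStream:
    """Signed instantaneous voltage jumps at arbitrary times.

    ``times`` are event times in ms (sorted ascending); ``amplitudes`` are
    the corresponding voltage jumps in mV (finite and nonzero).
    """

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if times.shape != amps.shape or times.ndim != 1:
            raise ValueError("times and amplitudes must be matching 1-d arrays")
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("event times must be sorted ascending")
        if amps.size and (not np.all(np.isfinite(amps)) or np.any(amps == 0.0)):
            raise ValueError("event amplitudes must be finite and nonzero")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitudes", amps)

    @classmethod
    def empty(cls) -> "EventStream":
        return cls(np.empty(0), np.empty(0))

    def __len__(self) -> int:
        return self.times.size


def apply_event(v: float, amplitude: float) -> float:
    """Apply one delta-pulse event: the voltage jumps by exactly its amplitude.

    The threshold check happens after application, inside the integration
    step in which the event falls.
    """
    return v + amplitude


def bin_events(events: EventStream, n_steps: int, dt: float, t_start: float = 0.0) -> np.ndarray:
    """Sum event amplitudes into per-step voltage jumps.

    An event at time t belongs to step ``floor((t - t_start)/dt)``; events
    falling exactly on a grid point are assigned to the step they begin.
    """
    jumps = np.zeros(n_steps)
    if len(events) == 0:
        return jumps
    idx = np.floor((events.times - t_start) / dt).astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n_steps):
        raise ValueError(
            "events fall outside the simulation window "
            f"[{t_start}, {t_start + n_steps * dt}) ms"
        )
    np.add.at(jumps, idx, events.amplitudes)
    return jumps


def integrate_batch(
    params: NeuronParams,
    drive,
    jumps: np.ndarray | None,
    v0: np.ndarray,
    t_start: float = 0.0,
    n_steps: int | None = None,
    check_every: int = 4096,
    record_voltage: bool = False,
):
    """Integrate many independent trials in lockstep; returns spike times per trial.

    ``drive`` is either a scalar constant current (mV) or an array of shape
    ``(n_trials, n_steps)``; ``jumps`` is ``None`` or an array of per-step
    summed event amplitudes with the same shape.  Spike times are reported
    at the end of the step in which threshold is reached.  With
    ``record_voltage`` the end-of-step voltage of the first trial is
    returned alongside the spike times.
    """
    v0 = np.atleast_1d(np.asarray(v0, dtype=float))
    n_trials = v0.size
    drive_is_scalar = np.isscalar(drive) or np.ndim(drive) == 0
    if not drive_is_scalar:
        drive = np.asarray(drive, dtype=float)
        if drive.ndim != 2 or drive.shape[0] != n_trials:
            raise ValueError("drive must be scalar or (n_trials, n_steps)")
        if n_steps is None:
            n_steps = drive.shape[1]
        elif drive.shape[1] != n_steps:
            raise ValueError(
                f"drive covers {drive.shape[1]} steps but {n_steps} were requested"
            )
    if n_steps is None:
        raise ValueError("n_steps is required with a scalar drive")
    if jumps is not None and jumps.shape != (n_trials, n_steps):
        raise ValueError("jumps must have shape (n_trials, n_steps)")
    if np.any(v0 >= params.v_threshold):
        raise ValueError("initial voltage must lie below threshold")

    a = params.dt / params.tau_m
    v_thr = params.v_threshold
    v_res = params.v_reset
    n_ref = params.n_ref

    v = v0.copy()
    ref = np.zeros(n_trials, dtype=np.int64)
    spk_steps: list[int] = []
    spk_trials: list[np.ndarray] = []
    v_rec = np.empty(n_steps) if record_voltage else None

    for j in range(n_steps):
        refract = ref > 0
        ri = drive if drive_is_scalar else drive[:, j]
        v_up = v + a * (ri - v)
        if jumps is not None:
            v_up = v_up + jumps[:, j]
        v = np.where(refract, v_res, v_up)
        if refract.any():
            ref[refract] -= 1
        crossed = (~refract) & (v >= v_thr)
        if crossed.any():
            idx = np.nonzero(crossed)[0]
            spk_steps.append(j)
            spk_trials.append(idx)
            v[idx] = v_res
            ref[idx] = n_ref
        if v_rec is not None:
            v_rec[j] = v[0]
        if (j + 1) % check_every == 0 and not np.all(np.isfinite(v)):
            raise NumericalBlowupError(f"non-finite voltage at step {j}")
    if not np.all(np.isfinite(v)):
        raise NumericalBlowupError(f"non-finite voltage at step {n_steps - 1}")

    # regroup (step, trial) pairs into per-trial ascending spike-time arrays
    out: list[np.ndarray] = [np.empty(0) for _ in range(n_trials)]
    if spk_steps:
        lens = np.array([t.size for t in spk_trials])
        steps = np.repeat(np.array(spk_steps, dtype=np.int64), lens)
        trials = np.concatenate(spk_trials)
        order = np.argsort(trials, kind="stable")
        steps = steps[order]
        counts = np.bincount(trials, minlength=n_trials)
        splits = np.cumsum(counts)[:-1]
        times = t_start + (steps + 1) * params.dt
        out = [np.asarray(part) for part in np.split(times, splits)]
    if record_voltage:
        return out, v_rec
    return out


def integrate_lif(
    params: NeuronParams,
    drive: CurrentTrace,
    events: EventStream | None = None,
    v0: float | None = None,
    rng: np.random.Generator | None = None,
    trial_id: int = 0,
):
    """Integrate one LIF trial under a current trace plus optional events.

    Returns a :class:`~lifspec.spike_stats.SpikeTrain` whose times are
    relative to ``drive.t_start`` and strictly increase with gaps of at
    least ``tau_ref``.  If ``v0`` is omitted it is drawn uniformly on
    ``[0, v_threshold)`` to shorten initial transients.
    """
    from .spike_stats import SpikeTrain

    if abs(drive.dt - params.dt) > 1e-12:
        raise ValueError(
            f"drive sampled at {drive.dt} ms but neuron uses dt={params.dt} ms"
        )
    n_steps = drive.values.size
    if v0 is None:
        v0 = (rng or np.random.default_rng()).uniform(0.0, params.v_threshold)
    jumps = None
    if events is not None and len(events) > 0:
        jumps = bin_events(events, n_steps, params.dt, drive.t_start)[None, :]
    times = integrate_batch(
        params,
        drive.values[None, :],
        jumps,
        np.array([v0]),
        t_start=0.0,
    )[0]
    return SpikeTrain(times=times, duration=n_steps * params.dt, trial_id=trial_id)
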