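"""Sparse recurrent network of excitatory and inhibitory LIF neurons.

The classic sparse random network: N_E excitatory and N_I = gamma N_E
inhibitory neurons, each receiving input from exactly C_E excitatory and
C_I = gamma C_E inhibitory presynaptic partners drawn uniformly at random
(no self-connections, no duplicate partners within a class).  A spike of
neuron j at time t delivers an instantaneous voltage jump +J (excitatory)
or -gJ (inhibitory) to all postsynaptic targets at t + delay.  The
external drive is either a constant current RI_ext or C_E independent
Poisson trains of matching mean per neuron.

The update loop is a synchronous Euler scheme with a circular delay
buffer; spike delivery is aggregated per time step (all contributions of
neurons that spiked ``delay`` earlier are gathered through a CSR adjacency
and summed with one weighted bincount), which is exactly equivalent to
per-event delivery on the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lif_core import NeuronParams, NumericalBlowupError
from .rate_map import SynapseConfig
from .spike_stats import ISIStats, PowerSpectrum, SpikeTrain, isi_statistics, spike_spectrum

__all__ = ["NetworkConfig", "Connectivity", "NetworkResult",
           "build_connectivity", "simulate_network"]


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterization of one network simulation."""

    N_E: int = 10_000
    gamma: float = 0.25
    syn: SynapseConfig = field(default_factory=SynapseConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    delay: float = 1.5
    duration: float = 10_500.0
    transient: float = 500.0
    n_record: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_E < 1:
            raise ValueError("N_E must be positive")
        n_total = self.n_total
        if self.syn.C_E >= self.N_E or self.syn.C_I >= self.N_I:
            raise ValueError(
                f"in-degrees (C_E={self.syn.C_E}, C_I={self.syn.C_I}) must be "
                f"smaller than the populations (N_E={self.N_E}, N_I={self.N_I})"
            )
        if self.syn.C_E / self.N_E > 0.1:
            warnings.warn(
                f"C_E/N_E = {self.syn.C_E / self.N_E:.2f} > 0.1: the network is "
                "not sparse and shared-input correlations matter", stacklevel=2)
        steps = self.delay / self.neuron.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"delay={self.delay} ms must be an integer multiple of "
                f"dt={self.neuron.dt} ms")
        if self.n_record > n_total:
            raise ValueError("n_record exceeds the network size")
        if self.duration <= self.transient:
            raise ValueError("duration must exceed the transient")

    @property
    def N_I(self) -> int:
        return int(round(self.gamma * self.N_E))

    @property
    def n_total(self) -> int:
        return self.N_E + self.N_I

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.neuron.dt))


@dataclass
class Connectivity:
    """Presynaptic partner lists: exactly C_E excitatory and C_I inhibitory
    partners per neuron, no self-connections, no duplicates within a class.

    Neurons are indexed 0..N_E-1 (excitatory) and N_E..N_E+N_I-1
    (inhibitory); ``pre_exc``/``pre_inh`` have shapes (N, C_E) and (N, C_I).
    """

    pre_exc: np.ndarray
    pre_inh: np.ndarray
    N_E: int

    def out_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Postsynaptic targets grouped by source: (indptr, targets)."""
        n = self.pre_exc.shape[0]
        src = np.concatenate([self.pre_exc.ravel(),
                              (self.pre_inh + self.N_E).ravel()])
        tgt = np.concatenate([
            np.repeat(np.arange(n, dtype=np.int32), self.pre_exc.shape[1]),
            np.repeat(np.arange(n, dtype=np.int32), self.pre_inh.shape[1]),
        ])
        order = np.argsort(src, kind="stable")
        targets = tgt[order]
        counts = np.bincount(src, minlength=n)
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        return indptr, targets


def _sample_partners(rng: np.random.Generator, n_pop: int, k: int,
                     exclude: int | None) -> np.ndarray:
    """k distinct uniform picks from range(n_pop), optionally excluding one."""
    if exclude is None:
        return rng.choice(n_pop, size=k, replace=False).astype(np.int32)
    picks = rng.choice(n_pop - 1, size=k, replace=False).astype(np.int32)
    picks[picks >= exclude] += 1
    return picks


def build_connectivity(config: NetworkConfig,
                       rng: np.random.Generator | None = None) -> Connectivity:
    """Fixed in-degree random connectivity (uniform, without replacement)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0)))
    n = config.n_total
    c_e, c_i = config.syn.C_E, config.syn.C_I
    pre_exc = np.empty((n, c_e), dtype=np.int32)
    pre_inh = np.empty((n, c_i), dtype=np.int32)
    for i in range(n):
        pre_exc[i] = _sample_partners(rng, config.N_E, c_e,
                                      i if i < config.N_E else None)
        inh_self = i - config.N_E if i >= config.N_E else None
        pre_inh[i] = _sample_partners(rng, config.N_I, c_i, inh_self)
    return Connectivity(pre_exc=pre_exc, pre_inh=pre_inh, N_E=config.N_E)


def _make_spike_kernel():
    """Compiled synchronous-update loop (constant external drive).

    Semantically identical to :func:`_run_numpy_loop`: same delivery
    aggregation, refractory clamping and end-of-step spike registration.
    """
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @njit(cache=False, fastmath=False)
    def kernel(indptr, targets, weight, v0, ext_const, a, v_thr, v_res,
               n_ref, n_steps, delay_steps, transient_steps, cap):
        n = v0.shape[0]
        v = v0.copy()
        ref = np.zeros(n, np.int32)
        incr = np.zeros(n)
        buf = np.empty((delay_steps, n), np.int32)
        buf_cnt = np.zeros(delay_steps, np.int64)
        spk_neuron = np.empty(cap, np.int32)
        spk_step = np.empty(cap, np.int32)
        m = 0
        jump_sum = 0.0
        overflow = False
        for j in range(n_steps):
            slot = j % delay_steps
            cnt = buf_cnt[slot]
            post = j >= transient_steps
            for k in range(cnt):
                src = buf[slot, k]
                w = weight[src]
                for e in range(indptr[src], indptr[src + 1]):
                    incr[targets[e]] += w
                if post:
                    jump_sum += w * (indptr[src + 1] - indptr[src])
            nspk = 0
            for i in range(n):
                if ref[i] > 0:
                    v[i] = v_res
                    ref[i] -= 1
                else:
                    vi = v[i] + a * (ext_const - v[i]) + incr[i]
                    if vi >= v_thr:
                        if m < cap:
                            spk_neuron[m] = i
                            spk_step[m] = j
                            m += 1
                        else:
                            overflow = True
                        buf[slot, nspk] = i
                        nspk += 1
                        v[i] = v_res
                        ref[i] = n_ref
                    else:
                        v[i] = vi
                incr[i] = 0.0
            buf_cnt[slot] = nspk
        return spk_neuron[:m], spk_step[:m], jump_sum, v, overflow

    return kernel


_spike_kernel = _make_spike_kernel()


def _run_numpy_loop(config, rng, indptr, targets, weight, v, ref, buffer,
                    poisson_ext, lam_ext, ext_const, a, n_steps, delay_steps,
                    transient_steps):
    """Vectorized fallback loop; also serves the Poisson-external mode."""
    neuron, syn = config.neuron, config.syn
    n = config.n_total
    v_thr, v_res, n_ref = neuron.v_threshold, neuron.v_reset, neuron.n_ref
    spikers_per_step: list[np.ndarray] = []
    step_of: list[int] = []
    jump_sum = 0.0

    for j in range(n_steps):
        slot = j % delay_steps
        arrived = buffer[slot]
        incr = None
        if arrived.size:
            starts = indptr[arrived]
            lens = (indptr[arrived + 1] - starts).astype(np.int64)
            total = int(lens.sum())
            if total:
                offs = np.repeat(starts - np.concatenate(
                    ([0], np.cumsum(lens)[:-1])), lens)
                tg = targets[offs + np.arange(total)]
                w = np.repeat(weight[arrived], lens)
                incr = np.bincount(tg, weights=w, minlength=n)

        refract = ref > 0
        v_up = v + a * (ext_const - v)
        if poisson_ext:
            v_up += syn.J * rng.poisson(lam_ext, n)
        if incr is not None:
            v_up += incr
            if j >= transient_steps:
                # arriving local current, before any refractory discard
                jump_sum += incr.sum()
        v = np.where(refract, v_res, v_up)
        ref[refract] -= 1

        crossed = (~refract) & (v >= v_thr)
        spikers = np.nonzero(crossed)[0]
        if spikers.size:
            v[spikers] = v_res
            ref[spikers] = n_ref
            spikers_per_step.append(spikers)
            step_of.append(j)
        buffer[slot] = spikers
        if (j + 1) % 4096 == 0 and not np.all(np.isfinite(v)):
            raise NumericalBlowupError(
                f"non-finite voltage at t = {(j + 1) * neuron.dt:.1f} ms")
    if not np.all(np.isfinite(v)):
        raise NumericalBlowupError("non-finite voltage at end of run")

    if spikers_per_step:
        lens = np.array([s.size for s in spikers_per_step])
        all_neurons = np.concatenate(spikers_per_step)
        all_steps = np.repeat(np.array(step_of, dtype=np.int64), lens)
    else:
        all_neurons = np.empty(0, dtype=np.int64)
        all_steps = np.empty(0, dtype=np.int64)
    return all_neurons, all_steps, jump_sum


@dataclass
class NetworkResult:
    """Recorded spike trains plus population-averaged summary statistics."""

    trains: list[SpikeTrain]
    rate: float
    cv: float
    isi: ISIStats
    rate_exc: float
    rate_inh: float
    mean_local_input: float
    recorded: np.ndarray
    spectrum: PowerSpectrum | None = None
    rho: np.ndarray | None = None


def simulate_network(
    config: NetworkConfig,
    connectivity: Connectivity | None = None,
    compute_spectrum: bool = False,
    window_length: float = 1638.4,
    max_lag: int = 5,
) -> NetworkResult:
    """Run the network and pool single-neuron statistics over a recorded subset.

    Statistics pool the post-transient spikes of ``n_record`` neurons
    sampled proportionally from both populations (excitatory and
    inhibitory cells are statistically equivalent here, which the summary
    exposes through the per-population rates).  ``mean_local_input``
    converts the post-transient arriving synaptic jumps into the
    time-averaged local current tau * (sum of jumps)/(N T), which vanishes
    for balanced parameters g * gamma = 1.
    """
    if connectivity is None:
        connectivity = build_connectivity(config)
    neuron, syn = config.neuron, config.syn
    n = config.n_total
    n_steps = int(round(config.duration / neuron.dt))
    delay_steps = max(config.delay_steps, 1)
    a = neuron.dt / neuron.tau_m
    v_thr, v_res, n_ref = neuron.v_threshold, neuron.v_reset, neuron.n_ref

    indptr, targets = connectivity.out_csr()
    weight = np.where(np.arange(n) < config.N_E, syn.J, -syn.g * syn.J)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x51)))
    v = rng.uniform(0.0, v_thr, n)
    ref = np.zeros(n, dtype=np.int32)
    buffer: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * delay_steps

    poisson_ext = syn.external_mode == "poisson"
    lam_ext = syn.C_E * syn.nu_ext(neuron.tau_m) * neuron.dt / 1000.0
    ext_const = 0.0 if poisson_ext else syn.external_mean

    transient_steps = int(round(config.transient / neuron.dt))
    if _spike_kernel is not None and not poisson_ext:
        cap = int(n * config.duration / 1000.0 * 120.0) + 1000
        for _ in range(4):
            all_neurons, all_steps, jump_sum, v, overflow = _spike_kernel(
                indptr, targets.astype(np.int32), weight, v, ext_const, a,
                v_thr, v_res, n_ref, n_steps, delay_steps, transient_steps,
                cap,
            )
            if not overflow:
                break
            cap *= 4
        else:
            raise RuntimeError("spike storage overflow: rate beyond 480 Hz?")
        all_neurons = all_neurons.astype(np.int64)
        all_steps = all_steps.astype(np.int64)
        if not np.all(np.isfinite(v)):
            raise NumericalBlowupError("non-finite voltage at end of run")
    else:
        all_neurons, all_steps, jump_sum = _run_numpy_loop(
            config, rng, indptr, targets, weight, v, ref, buffer,
            poisson_ext, lam_ext, ext_const, a, n_steps, delay_steps,
            transient_steps,
        )
    all_times = (all_steps + 1) * neuron.dt

    post_steps = all_steps[all_steps >= transient_steps]
    if n_ref > 0 and post_steps.size:
        per_step = np.bincount(post_steps - transient_steps)
        saturated = (per_step > 0.9 * n / n_ref).sum()
        if saturated > 0.05 * (n_steps - transient_steps):
            warnings.warn(
                "population rate approached the refractory bound 1/tau_ref; "
                "the network is outside the asynchronous irregular regime",
                stacklevel=2)

    t_use = config.duration - config.transient
    post = all_times > config.transient
    counts_post = np.bincount(all_neurons[post], minlength=n)
    rate_exc = 1000.0 * counts_post[: config.N_E].mean() / t_use
    rate_inh = (1000.0 * counts_post[config.N_E:].mean() / t_use
                if config.N_I else np.nan)

    n_rec_e = int(round(config.n_record * config.N_E / n))
    rec = np.concatenate([
        rng.choice(config.N_E, size=n_rec_e, replace=False),
        config.N_E + rng.choice(config.N_I, size=config.n_record - n_rec_e,
                                replace=False),
    ])
    rec_mask = np.zeros(n, dtype=bool)
    rec_mask[rec] = True
    keep = rec_mask[all_neurons] & post
    sel_neurons = all_neurons[keep]
    sel_times = all_times[keep] - config.transient
    order = np.argsort(sel_neurons, kind="stable")
    sel_neurons, sel_times = sel_neurons[order], sel_times[order]
    sorted_rec = np.sort(rec)
    trains = []
    split_times = np.split(sel_times, np.searchsorted(sel_neurons, sorted_rec[1:]))
    for neuron_id, times in zip(sorted_rec, split_times):
        trains.append(SpikeTrain(times=times, duration=t_use,
                                 trial_id=int(neuron_id)))

    rate = 1000.0 * counts_post[sorted_rec].mean() / t_use
    isi = isi_statistics(trains, max_lag=max_lag)
    mean_local = neuron.tau_m * jump_sum / (n * t_use)
    spectrum = (spike_spectrum(trains, window_length=window_length,
                               dt=neuron.dt) if compute_spectrum else None)
    return NetworkResult(
        trains=trains, rate=rate, cv=isi.cv, isi=isi, rate_exc=rate_exc,
        rate_inh=rate_inh, mean_local_input=mean_local, recorded=sorted_rec,
        spectrum=spectrum, rho=isi.rho,
    )
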