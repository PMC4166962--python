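"""Diffusion-approximation firing-rate map, fixed points and stability.

Replacing the summed synaptic shot noise at input rate nu_in by white
Gaussian noise with matched mean and intensity,

    mu = C_E J tau [nu_ext + (1 - gamma g) nu_in]          (mV)
    D  = C_E J^2 tau (1 + gamma g^2) nu_in / 2             (mV^2)

the stationary firing rate of the white-noise driven LIF follows the
first-passage-time (Siegert) formula

    nu_out = ( tau_ref + tau sqrt(pi) * Int_{z_lo}^{z_hi} e^{z^2} erfc(z) dz )^-1

with z_lo = (mu - v_T)/sqrt(2D), z_hi = (mu - v_R)/sqrt(2D).  A constant
external drive enters only the mean, never the noise intensity.  The
self-consistent network rate is the fixed point nu_out(nu) = nu of this
scalar map; the fixed point is stable iff |d nu_out / d nu_in| < 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erfcx, erfi

from .lif_core import NeuronParams

__all__ = [
    "SynapseConfig",
    "RateMapResult",
    "drift_and_noise",
    "siegert_rate",
    "find_fixed_point",
]

#: below this z the e^{z^2} factor in the integrand exceeds float range,
#: which only happens deep in the subthreshold/low-noise regime where the
#: firing rate is indistinguishable from zero
_Z_OVERFLOW = -26.0


@dataclass(frozen=True)
class SynapseConfig:
    """In-degrees, synaptic amplitudes and external drive of one neuron.

    ``C_I`` defaults to ``round(gamma * C_E)``.  ``external_mean`` is the
    constant-equivalent external current RI_ext in mV; in ``poisson`` mode
    the same mean is delivered as C_E independent excitatory Poisson trains
    of amplitude J.  The local input is balanced when ``g * gamma == 1``.
    """

    C_E: int = 1000
    gamma: float = 0.25
    J: float = 0.1
    g: float = 4.0
    external_mean: float = 30.0
    external_mode: str = "constant"
    C_I: int | None = None

    def __post_init__(self) -> None:
        if self.C_I is None:
            object.__setattr__(self, "C_I", int(round(self.gamma * self.C_E)))
        if self.C_E < 0 or self.C_I < 0:
            raise ValueError("in-degrees must be non-negative")
        if not self.J > 0:
            raise ValueError(f"J must be positive, got {self.J}")
        if self.g < 0:
            raise ValueError(f"g must be non-negative, got {self.g}")
        if self.external_mode not in ("constant", "poisson"):
            raise ValueError(f"unknown external_mode {self.external_mode!r}")

    @property
    def balanced(self) -> bool:
        return abs(self.g * self.gamma - 1.0) < 1e-12

    @property
    def amplitude_factor(self) -> float:
        """C_E J^2 + C_I g^2 J^2 (mV^2), the surrogate-noise amplitude."""
        return self.J**2 * (self.C_E + self.g**2 * self.C_I)

    def nu_ext(self, tau_m: float) -> float:
        """External Poisson rate (Hz) whose mean drive equals external_mean."""
        return 1000.0 * self.external_mean / (self.C_E * self.J * tau_m)


@dataclass(frozen=True)
class RateMapResult:
    """Fixed point of the rate map with stability classification."""

    nu_star: float
    slope: float
    stable: bool
    trace: np.ndarray  # (n, 2) array of (nu_in, nu_out) samples
    found: bool = True
    all_roots: tuple = ()


def drift_and_noise(
    nu_in: float, syn: SynapseConfig, neuron: NeuronParams
) -> tuple[float, float]:
    """Mean mu (mV) and white-noise intensity D (mV^2) at input rate nu_in (Hz).

    Written with the exact integer in-degrees: mu = external_mean +
    J tau (C_E - g C_I) nu_in and D = J^2 tau (C_E + g^2 C_I) nu_in / 2,
    which reduce to the gamma-form when C_I = gamma C_E.
    """
    if nu_in < 0:
        raise ValueError("nu_in must be non-negative")
    tau_s = neuron.tau_m / 1000.0
    mu = syn.external_mean + syn.J * tau_s * (syn.C_E - syn.g * syn.C_I) * nu_in
    d = 0.5 * syn.J**2 * tau_s * (syn.C_E + syn.g**2 * syn.C_I) * nu_in
    return mu, d


def _deterministic_rate(mu: float, neuron: NeuronParams) -> float:
    if mu <= neuron.v_threshold:
        return 0.0
    period = neuron.tau_ref + neuron.tau_m * math.log(
        (mu - neuron.v_reset) / (mu - neuron.v_threshold)
    )
    return 1000.0 / period


def siegert_rate(mu: float, D: float, neuron: NeuronParams) -> float:
    """Stationary rate (Hz) of the white-noise driven LIF.

    The integrand e^{z^2} erfc(z) is evaluated through the scaled
    complementary error function for z >= 0 and through the split
    2 e^{z^2} - erfcx(-z) for z < 0, with the 2 e^{z^2} part integrated in
    closed form via the imaginary error function; this avoids the naive
    overflow near the suprathreshold/low-noise regime.
    """
    if D < 0:
        raise ValueError("noise intensity D must be non-negative")
    if D == 0.0:
        return _deterministic_rate(mu, neuron)
    s = math.sqrt(2.0 * D)
    z_lo = (mu - neuron.v_threshold) / s
    z_hi = (mu - neuron.v_reset) / s
    if z_lo < _Z_OVERFLOW:
        return 0.0

    integral = 0.0
    if z_hi > 0.0:
        a = max(z_lo, 0.0)
        val, err = quad(erfcx, a, z_hi, limit=200)
        if not np.isfinite(val) or err > 1e-6 * (abs(val) + 1.0):
            raise RuntimeError(
                f"quadrature failed for mu={mu}, D={D}: value={val}, err={err}"
            )
        integral += val
    if z_lo < 0.0:
        b = min(z_hi, 0.0)
        gauss = math.sqrt(math.pi) * (erfi(b) - erfi(z_lo))
        corr, _ = quad(lambda z: erfcx(-z), z_lo, b, limit=200)
        integral += gauss - corr
    period = neuron.tau_ref + neuron.tau_m * math.sqrt(math.pi) * integral
    return 1000.0 / period


def find_fixed_point(
    syn: SynapseConfig,
    neuron: NeuronParams,
    n_scan: int = 201,
    slope_step: float = 0.5,
    operating_rate: float | None = None,
) -> RateMapResult:
    """Locate self-consistent rates nu_out(nu) = nu and classify stability.

    The map is scanned on [0, 1/tau_ref]; every bracketed root is refined
    by Brent's method and the slope at each root estimated by a central
    difference of step ``slope_step`` Hz.  If several fixed points exist
    the one nearest ``operating_rate`` (or the largest, by default) is
    reported as primary; all are returned in ``all_roots``.
    """
    nu_max = 1000.0 / neuron.tau_ref if neuron.tau_ref > 0 else 1000.0
    grid = np.linspace(0.0, nu_max, n_scan)

    def nu_out(nu_in: float) -> float:
        return siegert_rate(*drift_and_noise(nu_in, syn, neuron), neuron)

    outs = np.array([nu_out(nu) for nu in grid])
    trace = np.column_stack([grid, outs])
    resid = outs - grid

    roots = []
    for i in range(n_scan - 1):
        if resid[i] == 0.0:
            roots.append(grid[i])
        elif resid[i] * resid[i + 1] < 0:
            roots.append(brentq(lambda nu: nu_out(nu) - nu, grid[i], grid[i + 1],
                                xtol=1e-6))
    if not roots:
        warnings.warn("no self-consistent rate bracketed on [0, 1/tau_ref]",
                      stacklevel=2)
        return RateMapResult(np.nan, np.nan, False, trace, found=False)

    results = []
    for r in roots:
        lo = max(r - slope_step, 0.0)
        hi = r + slope_step
        slope = (nu_out(hi) - nu_out(lo)) / (hi - lo)
        results.append((r, slope, abs(slope) < 1.0))
    if operating_rate is not None:
        primary = min(results, key=lambda t: abs(t[0] - operating_rate))
    else:
        primary = max(results, key=lambda t: t[0])
    return RateMapResult(
        nu_star=primary[0],
        slope=primary[1],
        stable=primary[2],
        trace=trace,
        found=True,
        all_roots=tuple(results),
    )
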