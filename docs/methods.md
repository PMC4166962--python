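# Methods

## The self-consistency problem

A neuron embedded in a homogeneous recurrent network receives input that is a
superposition of many spike trains whose second-order statistics equal those of
its own output. Replacing the input by Poisson trains (the diffusion
approximation) gets the firing rate about right but misrepresents the temporal
correlations: the output of a leaky integrate-and-fire (LIF) neuron is far from
Poisson, so the assumption of Poissonian input is internally inconsistent.
This package determines the *self-consistent* spike-train power spectrum by
iterating a single neuron over generations: generation *n* is driven by
surrogate stochastic input constructed from the measured output statistics of
generation *n−1*, until the spectrum stops changing.

## Single-neuron model

The membrane obeys `tau_m dv/dt = −v + RI(t)` with threshold `v_T`, reset
`v_R`, and absolute refractory period `tau_ref`, integrated by plain forward
Euler on a fixed grid `dt`. Defaults (all configurable): `tau_m = 20 ms`,
`v_T = 20 mV`, `v_R = 10 mV` (0 mV as the common alternative),
`tau_ref = 2 ms`, `dt = 0.1 ms`.

Numerical conventions that matter for reproducibility:

- A presynaptic delta pulse of area `tau_m·J` in `RI` jumps the voltage by
  exactly `J`; equivalently a one-step current pulse of height `J·tau_m/dt`.
  The two drive representations produce identical spike trains (tested).
- A spike is recorded at the end of the Euler step in which `v ≥ v_T`
  (no sub-step interpolation; `v == v_T` counts as a spike).
- During refractoriness the voltage is clamped at `v_R` and incoming events
  are discarded. The model is silent on this point; clamping is the common
  convention for absolute refractoriness and makes the deterministic-drive
  period `tau_ref + tau_m·ln((mu−v_R)/(mu−v_T))` exact up to `dt`. The
  alternative (buffering events) would matter most at high rates; the choice
  is isolated in one code path should sensitivity checks be wanted.
- Initial voltages are drawn uniformly on `[0, v_T)` and a warm-up interval
  (default 200 ms for single-neuron trials, 500 ms for networks) is discarded
  from all statistics.

## Spike-train statistics

Intervals are pooled within trials only; the rate is the inverse pooled mean
interval, the CV the pooled standard deviation over the mean. Serial
correlation coefficients `rho_k` are computed per trial with the
sample-mean-centered covariance estimator and pooled with pair-count weights;
lags with fewer than 100 pooled pairs are flagged low-confidence.

The power spectrum treats the train as a sum of delta functions binned at
`dt` (at most one spike per bin, guaranteed by refractoriness). Each trial is
split into non-overlapping rectangular windows of `2^14·dt = 1638.4 ms`
(`Δf ≈ 0.61 Hz`, enough to resolve spectral peaks at 30–200 Hz); per window
`S(f) = |x̃(f)|²/T`, averaged over all windows and trials. No taper is
applied. The `f = 0` bin, which carries the `ν²T` mean-rate term, is dropped
rather than mean-subtracting the signal, so `S(f→∞) = ν` (the flat Poisson
value) holds by convention. Spectra are two-sided densities: a Poisson train
gives `S(f) = ν` and the band integral over `[−1/2dt, 1/2dt]` equals the
binned-signal variance.

For a renewal process the spectrum follows from the ISI density alone:
`S(f) = ν(1−|ρ̃|²)/|1−ρ̃|²` with `ρ̃(f)` the Fourier transform of the ISI
density, evaluated as the empirical characteristic function of the interval
sample (no histogram smoothing, hence no bin-width choice). Where
`|1−ρ̃| < 1e−6` (the `f→0` limit of a very regular process) the analytic
limit `ν·CV²` replaces the ill-conditioned quotient and the bin is flagged.

## Surrogate input: two approximations

**Gaussian.** The summed local input is replaced by a stationary Gaussian
current with mean `⟨η⟩ = RI_ext + C_E J(1−gγ)ν·tau_m` and spectrum
`S_η(f) = (C_E J² + C_I g² J²)·tau_m²·S_x(f)` (`tau_m` in seconds, `S_η` in
mV²/Hz), where `S_x` is the previous generation's spike spectrum. Synthesis
draws two independent zero-mean Gaussians per frequency bin, scaled so the
ensemble-averaged periodogram equals the target exactly; bin 0 carries only
the mean and the Nyquist bin is real. The measured spectrum is linearly
interpolated onto the synthesis grid; beyond the measured band the
high-frequency plateau `ν` is used (spike spectra converge to the rate). With
these conventions the white-noise limit reproduces the diffusion
noise intensity exactly: `2D·tau_m = (C_E J²+C_I g²J²)·tau_m²·ν` at the
plateau, i.e. `D = C_E J² tau_m (1+γg²) ν/2`.

**Renewal.** Each of the `C_E + C_I` input trains is an equilibrium renewal
process whose interval law resamples the previous generation's pooled ISI
sample with replacement (the measured law is preserved exactly). Equilibrium
is achieved either by a forward-recurrence first spike — sampled exactly by
length-biased interval selection plus a uniform position, the default because
it needs no burn-in — or by a synchronizing spike at `−T_0` with
`T_0 ≈ 1/(ν·CV²)`, capped at 50 mean intervals (the estimate applies for
CV < 1 and diverges as CV → 0). Both methods yield statistically
indistinguishable superposition spectra (tested). The superposition carries
amplitudes `+J` and `−gJ`. The renewal approximation is exact only if the
output is renewal; when interval correlations `rho_1 ≠ 0` persist, input and
output spectra differ — this gap is reported by the iteration records, not
hidden.

## Rate map and stability

The scalar map from input to output rate uses the first-passage-time (Siegert)
formula for the white-noise-driven LIF with
`mu = C_E J tau[ν_ext + (1−γg)ν]` and `D = C_E J² tau(1+γg²)ν/2`; a constant
external drive enters only `mu`. The integrand `e^{z²}erfc(z)` is evaluated
with the scaled complementary error function for `z ≥ 0` and, for `z < 0`,
split as `2e^{z²} − erfcx(−z)` with the exponential part integrated in closed
form via the imaginary error function; below `z ≈ −26` the quotient overflows
double precision and the rate is indistinguishable from zero, so zero is
returned. `D = 0` falls back to the deterministic period. Fixed points are
bracketed on `[0, 1/tau_ref]` (201-point scan, Brent refinement); stability is
`|dν_out/dν_in| < 1` with a central-difference slope (step 0.5 Hz). With the
standard balanced parameters the stable root is ≈ 71 Hz; at `g = 5` the root
persists but `|slope| ≈ 1.45 > 1` (unstable), while `C_E = 100, J = 1 mV,
g = 5` gives a negative slope of magnitude < 1 (stable again — fewer, stronger
synapses raise the noise floor).

## Generation loop

Generation 1 is driven by a constant external mean plus `C_E + C_I`
independent Poisson trains (delivered through per-step summed jumps, exactly
equivalent to event delivery on the grid). Convergence requires the relative
integrated squared spectral difference
`∫(S_n−S_{n−1})² df / ∫S_{n−1}² df` on 0–500 Hz to stay below 0.01 for two
consecutive generations *and* the rate to move by less than 1 Hz. The
distance metric has an estimator-noise floor of about `2/n_windows`; the
default averaging depth (100 trials × 6 windows of 10 s trials) puts the
floor at ~0.003, safely below the threshold, whereas strongly reduced
averaging can leave a run hovering at its noise floor with statistics that
are plainly stationary — such runs end with status `max_generations`.
Instability is declared when the generation rate leaves `[1, 450] Hz` or when
three consecutive rate differences alternate in sign with strictly growing
magnitude (final swing > 5 Hz, above estimator noise). No synaptic delay
appears in the scheme: the surrogate input is stationary, so a delay would
change nothing.

## Recurrent network

The validation network is the classic sparse random model: `N_E` excitatory
and `N_I = γN_E` inhibitory LIF neurons, each with exactly `C_E` excitatory
and `C_I = γC_E` inhibitory presynaptic partners drawn uniformly without
replacement, excluding self-connections and duplicates (the reference model
class is silent on multi-contacts; excluding them is standard, and at
`C_E/N_E ≤ 0.1` the difference is negligible). Spikes are delivered after a
delay `D` (default 1.5 ms) through a circular buffer; per-step aggregation of
all arriving jumps is exactly equivalent to per-event delivery. External
drive is the constant `RI_ext = 30 mV` (equivalently `ν_ext/ν_thr = 1.5`) or
`C_E` independent Poisson trains of the same mean. Default validation size is
`N_E = 10^4` with 1000 recorded neurons sampled proportionally from both
populations — spectra are size-invariant from this scale up, which is what
makes the scaled runs representative — and the first 500 ms are discarded.

The summary reports the time-averaged *arriving* local current
`tau·(Σ jumps)/(N·T)`. This is the quantity that vanishes under balance
(`gγ = 1`); the *applied* current (after refractory discards) is biased
slightly positive because post-volley inhibition preferentially arrives
during refractoriness — a real property of the discrete model worth knowing
when checking balance.

The inner loop exists twice with identical semantics: a numba-compiled kernel
(used for constant external drive when numba is importable) and a vectorized
numpy loop (Poisson external mode and fallback). The two paths produce
bit-identical spike trains on the same inputs.

## Problem sizes used in the shipped checks

Deterministic quantities (rate map, stability) are exact to solver tolerance.
Stochastic checks use: 20–48 trials × 10 s per generation for the iterative
schemes (pooled ISI counts ≥ 10^4, CV standard error well below 0.01);
`N_E = 10^4`, 10 s of recording from 1000 neurons for the network runs. These
sizes keep every published comparison within its stated tolerance (rates
±10 %, CVs ±0.05) while remaining single-CPU friendly; doubling any of them
changes the reported statistics by less than the quoted uncertainty.

## Known limitations

- The schemes describe an infinitely sparse network: all input trains are
  independent. Shared-input correlations at `C_E/N_E > 0.1` are outside the
  model (the simulator warns).
- Synchronous regimes (`g < 3`, strong excitation) are out of scope; the
  asynchronous-irregular regime `g ∈ [3.5, 5]` is the domain of validity.
- The renewal scheme cannot represent interval correlations by construction;
  its systematic deviation in the strongly correlated regimes is expected
  and reported.
- The Gaussian scheme assumes many small-amplitude inputs; at `J = 1 mV`
  with `C_E = 100` it degrades and the renewal scheme is the better choice.
- No conductance-based synapses, synaptic filtering, firing-rate
  heterogeneity, or cross-spectra between neurons.
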