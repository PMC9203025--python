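# Methods

## Models

### Conductance-based LIF neuron

The membrane potential follows

    tau dv/dt = -(v - E_L) - g_GABA (v - E_GABA) - g_Glu (v - E_Glu) + I_noise(t),

with a spike emitted at v = E_thr and an instantaneous reset to E_reset (no
refractory period). Conductances are normalized by the leak conductance and
dimensionless; `I_noise = sigma*sqrt(tau)*zeta(t)` with unit-variance Gaussian
white noise. Defaults: tau = 20 ms, E_L = -80, E_thr = -60, E_reset = -70,
E_Glu = 0 mV. With constant conductances the dynamics reduce to relaxation
towards the effective reversal E_eff with conductance g_eff = 1 + g_GABA +
g_Glu and time constant tau/g_eff, giving the closed-form rate
nu = g_eff / (tau ln[(E_eff - E_reset)/(E_eff - E_thr)]) when E_eff > E_thr.
Internally rates are in ms^-1 (the natural unit of the equations); every
public interface reports Hz.

GABA acts twice: it shortens the effective time constant (always
rate-raising) and moves E_eff towards E_GABA. Their competition yields the
regime taxonomy implemented in `lif_analytics`: INHIBITORY, NON_MONOTONIC
(interior maximum of rate vs g_GABA; occurs only for
(E_reset+E_thr)/2 < E_GABA < E_thr), EXCITATORY (E_GABA above threshold),
and, at sub-threshold glutamatergic drive, SILENT vs GABA_ACTIVATED.

Two measure-zero ties need a deterministic rule for grid labelling:
E_GABA = E_thr is labelled EXCITATORY, an initial slope within 1e-9 of zero
INHIBITORY, and at sub-threshold drive E_GABA = E_thr is grouped with SILENT
(GABA can then never lift E_eff above threshold).

One asymptotic subtlety: the critical reversal separating inhibitory from
non-monotonic behaviour converges, for strong glutamatergic drive, towards
(E_reset + E_thr)/2 only in the idealization E_eff -> infinity. Because
E_eff saturates at E_Glu = 0 mV, the exact limit with the default constants
is E_thr - 4.743 mV rather than E_thr - 5 mV; `critical_EGABA` returns the
exact value.

### Firing rate under noise

The stationary rate under white-noise input is the mean first-passage-time
(Ricciardi) expression, an integral of e^{x^2}(1 + erf x) between
(E_reset - E_eff)/sigma_eff and (E_thr - E_eff)/sigma_eff with
sigma_eff = sigma/sqrt(g_eff). Numerically the integrand is erfcx(-x), the
scaled complementary error function, which is stable on the whole axis; the
integral is evaluated by adaptive quadrature (absolute tolerance 1e-12,
relative 1e-10, split at x = 0 when the interval straddles it). When the
upper bound exceeds 26 the rate underflows double precision (< 1e-290) and
is returned as exactly 0. The zero-noise limit dispatches to the closed
form.

Two noise models are supported. Constant: sigma is a free amplitude in mV.
Conductance-dependent: the diffusion approximation of Poisson synaptic
bombardment gives sigma^2(v) = sum_s a_s g_s (v - E_s)^2 over the two
synapse types, evaluated at v = E_eff (the standard substitution that makes
the noise additive); a_Glu = a_GABA = a by default. The high-noise closed
form nu = sigma*sqrt(g_eff)/(tau*sqrt(pi)*(E_thr - E_reset)) — increasing
in g_GABA as sqrt(1 + g_GABA) — is exposed separately; it is the limit in
which the integration bounds shrink to zero, and becomes accurate to a few
percent only for sigma of several hundred mV at small conductances.

The boundary between inhibitory and non-monotonic regimes under noise is
the zero of the initial slope d(nu)/d(g_GABA)|_{g_GABA=0}, computed by a
central difference with step 1e-4 (the rate formula is analytic in g_GABA,
so the stencil may cross zero) and bisected over [E_reset, E_thr] to
0.01 mV. Noise only lowers this boundary, so the bracket is safe; an
absent sign change raises.

### EIF-Kir neuron

The robustness model adds an exponential spike-generating current
Delta_T exp((v - V_T)/Delta_T) and an inward-rectifier potassium current
-g_K/(1 + exp((v - V_P)/K)) (v - E_K) to the LIF equation (Delta_T = 2 mV,
V_T = -60 mV, g_K = 5, K = 16 mV, V_P = E_K = -80 mV; the Kir current is
written with the hyperpolarizing sign of a potassium current, conductance
halving at V_P). There is no hard threshold: the voltage diverges through
the exponential term and is reset from a numeric ceiling V_cut = -30 mV,
beyond which the spike time is insensitive to the cutoff (< dt). The reset
potential is taken from the LIF set (-70 mV). Injected currents in pA are
converted with g_L = 5 nS. A step from below V_T jumping past V_cut + 20 mV
flags an unresolvable upswing (dt too large); overshoot above V_cut after a
resolved upswing is intrinsic to explicit integration of the exponential
term and harmless, since the state is reset.

In this model the non-monotonic band hugs the *effective* spike threshold,
which lies slightly above V_T for Delta_T = 2: interior maxima of the
rate-vs-g_GABA curve appear for E_GABA from a few tenths of a mV below V_T
upward and grow large above it, and the band moves to higher E_GABA as
Delta_T grows — the same mechanism, with the soft threshold replacing the
hard one.

## Simulation

All simulators use Euler–Maruyama in ms units with the white-noise increment
sigma*sqrt(dt/tau)*N(0,1) per step; defaults dt = 0.05 ms (LIF, network) and
0.01 ms (EIF-Kir, stiff exponential). Spikes register at the first step at
or above threshold, without interpolation; halving dt changes rates by
well under 1%. Where simulated rates are compared quantitatively with the
first-passage theory, the comparison accounts for the half-order
discretization bias of discrete threshold observation by evaluating the
theory at a threshold raised by zeta(1/2)/sqrt(2)*sigma*sqrt(dt/tau)
(~0.58*sigma*sqrt(dt/tau)); with this shift, theory and 200 s simulations
agree to better than 0.1% across dt = 0.0025–0.01 ms.

Deterministic tonic rates are measured from inter-spike intervals
((n-1)/(t_last - t_first)), which resolves rate differences far below the
1/duration quantization of spike counting.

## Synthetic inputs

The generators mirror the stated input statistics exactly and are pure
functions of (spec, seed):

- Cortical drive: one independent Poisson stream per neuron at 1000 Hz,
  filtered by a first-order exponential kernel with 5.6 ms decay; per-bin
  Poisson counts with the exact discrete decay update (statistically
  identical to event lists at these rates and far cheaper). Stationary mean
  a*r*tau and variance a^2*r*tau/2 follow Campbell's theorem and are
  verified against it.
- GABA synapses: difference-of-exponentials conductance kernel
  g0 (e^{-t/tau1} - e^{-t/tau2}), tau1 = 20 ms decay, tau2 = 1.5 ms rise,
  implemented as two exponentially decaying state variables incremented by
  g0 on each presynaptic spike (exact discrete update, O(1) per neuron per
  step). g0 is identified with the connection-strength matrix entry, which
  is what makes the mean total conductance from population j equal
  G_ij P_ij N_j nu_j (tau1 - tau2). The kernel peaks at
  tau1*tau2/(tau1-tau2)*ln(tau1/tau2) = 4.20 ms and integrates to
  18.5*g0 ms.
- Connectivity: independent Bernoulli edges with block probabilities P[i,j]
  (row = target population), strength G[i,j] per present edge, no
  self-connections, no transmission delays (none are part of the model;
  conduction within the ~0.01 mm^3 volume is sub-dt).

## Striatal network

N = 1000 LIF neurons: 20 FSIs (GABA reversal -80 mV), 490 dSPNs and 490
iSPNs (shared depolarized reversal, default E_thr - 1 = -61 mV; every GABA
synapse onto a neuron uses the postsynaptic cell's reversal). Initial
voltages are independent uniform draws on [E_L, E_thr] to avoid spurious
synchrony; the first 100 ms are discarded from every statistic.

Per-population drive amplitudes are calibrated to target mean rates
(defaults 10/1/1 Hz). Because SPNs do not project to FSIs, the FSI amplitude
is calibrated first by bisection on the 20-neuron FSI subnetwork; the two
SPN amplitudes are then bisected jointly against shared full-network
evaluation runs (10 s each after the transient), which the weak dSPN/iSPN
coupling permits; tolerance 5% of target. FSI-rate manipulations re-calibrate
the FSI drive only (a minimal model of optogenetic gain modulation that
preserves FSI spike statistics), with the SPN drive frozen at baseline.
Calibrated amplitudes are population-level, self-averaging quantities and
are reused across connectivity realizations in multi-realization sweeps.

Membrane-potential statistics pool all SPNs, sampled every 1 ms after the
transient, excluding samples within 1 ms of a spike on either side (removes
threshold-approach and reset artifacts from the sub-threshold
distribution); the Gaussian fit is maximum likelihood, i.e. the sample mean
and SD. The heterogeneity analysis correlates per-SPN rate changes between
two FSI conditions (Pearson, with Spearman reported alongside) against the
FSI in-degree of the shared connectivity realization.

## What the generators do and do not emulate

The synthetic inputs reproduce the stated stimulus ensemble exactly:
independent stationary Poisson drive, binary weights, block-Bernoulli
connectivity. Real cortical input is correlated, non-stationary and has
broad weight distributions; striatum contains further interneuron classes
and lateral SPN glutamate is absent by construction. Passing tests therefore
validate the implementation of this model class, not transferability to in
vivo data. Two quantitative consequences are documented in the acceptance
analysis: with homogeneous per-population drive the only quenched disorder
is connectivity in-degree, so the per-SPN rate-distribution widths are an
order of magnitude narrower than the figures printed for the original
network (whose protocol for those widths is ambiguous), and the iSPN
population — receiving ~40% less FSI input than dSPNs — peaks at a higher
FSI rate, so it is not yet inhibited at 25 Hz relative to the 10 Hz
baseline. The finite-duration attenuation of the rate-change/in-degree
correlation is handled by measuring over 200 s condition runs.

## Problem sizes and numerical defaults

Default problem sizes used by the test suite and the acceptance script:
10 s calibration evaluations, a 10 s membrane-potential run, 100–200 s
condition runs, 20 s sweep runs across 5 connectivity realizations, 200 s
single-neuron Monte-Carlo checks. Phase diagrams default to E_GABA in
[-80, -50] mV step 0.1 and g_Glu in [0, 2] step 0.01 for the closed-form
model; noisy diagrams (one quadrature per point) default to coarser grids
and skip per-point curve summaries unless requested. Maximization of the
rate-vs-g_GABA curve uses a 512-point log-spaced grid over [0, 2*g_silence]
(or [0, 50] when GABA cannot silence) refined by bounded scalar
minimization to 1e-6 in g. Random number streams are derived from a single
master seed (kept below 2^31) with fixed salts per component.

## Known limitations

- No refractory period, adaptation, synaptic delays or kinetics beyond the
  stated kernels; white noise only in the theory (no coloured-noise
  corrections).
- Euler–Maruyama is half-order for first-passage problems; quantitative
  theory/simulation comparisons must use the threshold-shift correction
  described above.
- The calibration assumes monotone rate-vs-amplitude transfer, which holds
  at these operating points but need not for strongly recurrent variants.
- `strength_ratio` is reported as +inf where the neuron is silent without
  GABA; ratio heatmaps should mask those points.
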