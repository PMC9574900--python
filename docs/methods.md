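# Methods

## The model

`ctnet` simulates a network of corticothalamic mean-field units. Each unit
couples four neural populations — cortical excitatory (e) and inhibitory
(i), thalamic reticular (r) and relay (s). Population `a` integrates its
presynaptic input through a second-order dendritic filter

    (1/(alpha_d*beta_d)) V_a'' + (1/alpha_d + 1/beta_d) V_a' + V_a
        = sum_b nu_ab * phi_b(t - tau_ab),

converts membrane potential to firing rate through the saturating sigmoid
`Q(V) = Q_max / (1 + exp(-(V - theta)/sigma'))`, and — for the cortical
excitatory population only — propagates the rate through damped axonal
dynamics `(1/gamma_e^2) phi_e'' + (2/gamma_e) phi_e' + phi_e = Q_e`. The
other populations are electrotonically compact (`phi_b = Q_b`). The
corticothalamic loop delay `t0` is split as `t0/2` on the descending
(e -> r, e -> s) and ascending (s -> e, s -> i) legs; this loop is what
produces the alpha-band (8–13 Hz) resonance. The relay population receives
an external drive `phi_n = noise_mean + noise_std * white noise`, the only
stochastic term.

Couplings `nu_ab` (V*s) follow the random-intracortical-connectivity
assumption: both cortical populations receive statistically identical
input, so `nu_ie = nu_ee`, `nu_ii = nu_ei`, `nu_is = nu_es`. Couplings with
an inhibitory source (`nu_ei`, `nu_ii`, `nu_sr`) are non-positive.

Long-range structure enters through a weighted, symmetric, zero-diagonal
connectome over 78 cortical regions (the cortical parcels of the AAL
atlas). Region j's excitatory population receives
`global_coupling * sum_k rownorm(W)[j,k] * phi_e_k` in addition to its
local input. Row-normalization makes the uniform network mode equivalent
to an isolated unit with an extra excitatory self-gain equal to
`global_coupling`.

## Integration

A stochastic Heun scheme with fixed step `dt = 1e-4 s` integrates the
delay system; phi_e and phi_s histories live in ring buffers (the loop
delay spans 400 steps). Noise is additive on the relay drive with the same
draw used in predictor and corrector, the standard treatment for additive
noise. Per-region noise streams are Philox generators spawned from one
master seed, so identical configurations and seeds reproduce bit-identical
trajectories. The integrator starts at the spatially uniform fixed point
(solved by reducing the four steady-state equations to a scalar problem in
phi_e*, with the monotone thalamic and inhibitory sub-blocks solved by
bracketed root finding) and discards a 2 s transient. A divergence guard
(|V| > 1 V or |phi_e| > 10 Q_max, far beyond physiological range) aborts
with the step and region identified.

The field is recorded at 2500 Hz (every 4th step) and decimated with
anti-alias filtering to 250 Hz before any metric is computed; 250 Hz was
chosen over alternatives because it is an integer divisor of the record
rate and comfortably above the 30 Hz analysis ceiling.

## The linear oracle

All stability and calibration decisions rest on an independent linearized
analysis, not on the integrator. About the fixed point, the dendritic
operator becomes `L^-1(w) = (1 + iw/alpha_d)(1 + iw/beta_d)`, the axonal
operator `(1 + iw/gamma_e)^2`, and each delayed leg contributes
`exp(-iw t0/2)`. Solving the resulting 4x4 linear system gives the
noise-to-phi_e transfer function and hence a closed-form power spectral
density (`linear_spectrum`); the number of unstable modes is the winding
number of the characteristic function `det(M)/L^-4` along the frequency
axis (a Nyquist argument; `rhp_winding_number`). Because an analytic
resonance can be narrower than the Welch resolution, comparisons against
simulated spectra convolve the prediction with the Hann window's spectral
power kernel first (`welch_expected_psd`).

## The default operating point

The published corticothalamic alpha points place the cortex at a firing
rate where the sigmoid slope is steep; we found every such point to be
structurally fragile: the low-activity fixed point sits within ~1e-4 V*s
of a saddle-node in the excitatory gain, so adding the long-range network
gain either removed the fixed point or destabilized non-uniform network
modes, and the noisy network escaped to a saturated high-firing attractor.
The default parameter set was therefore calibrated by a constrained
search over the coupling space (sigma' allowed in 3.3–6.6 mV), accepting a
point only if

1. the low-activity fixed point persists up to three times the network
   gain (saddle-node margin),
2. the baseline is linearly stable for every network mode (winding number
   zero for effective ee-gain perturbations across +/-2x the network
   gain),
3. the linear spectrum peaks in 8–13 Hz,
4. the excitatory reduction path (both cortical excitatory couplings
   scaled to 0.875) remains stable and loses alpha power,
5. the inhibitory reduction path (cortical inhibitory couplings scaled
   toward 0.851) crosses the alpha Hopf instability late in the 50-step
   schedule — the mechanism that saturates the response and produces the
   late plateau, and
6. forward simulations at the working noise level reproduce the
   directions (excitatory down, inhibitory and combined up, inhibitory
   dominant) with bounded supercritical behavior.

The calibrated defaults are `sigma' = 3.65 mV`, `nu_ee = 0.92e-3`,
`nu_ei = -2.57e-3`, `nu_es = 1.22e-3`, `nu_re = 0.38e-3`,
`nu_rs = 0.33e-3`, `nu_se = 1.96e-3`, `nu_sr = -1.22e-3`,
`nu_sn = 1.26e-3` (V*s), `noise_mean = 7.4 s^-1`, with `Q_max = 250 s^-1`,
`theta = 15 mV`, `alpha_d = 50 s^-1`, `beta_d = 200 s^-1`,
`gamma_e = 100 s^-1`, `t0 = 80 ms` retained from the standard alpha
regime. At this point the baseline peak sits near 10 Hz and the inhibitory
path crosses the instability at a coupling scale of about 0.87 (roughly
iteration 42 of 50).

The noise amplitude matters qualitatively, not just quantitatively: at
large amplitude the network wanders far enough from the fixed point that
sigmoid rectification shifts the effective operating point and can invert
the response directions, while at very small amplitude the baseline power
is so low that the supercritical plateau dwarfs it and the excitatory
phase-locking response loses its sign. The default `noise_std` is placed
inside the window where forward simulations agree with the linearized
directions.

The default long-range gain is `global_coupling = 5e-5 V*s`: large enough
for measurable baseline phase locking, small enough that the induced
dimensionless gain perturbation stays inside the unit's stability
envelope.

## The reduction experiment

A run reduces couplings linearly over `n_iterations = 50` steps:
`s_X(i) = 1 - endpoint_X * i/n`, with end-points 0.125 (excitatory) and
0.149 (inhibitory) — the measured layer-VI density reductions in
normal-appearing MS gray matter; the demyelinated-cortex values
(0.185/0.293) ship as a config preset. The default policy scales only the
intracortical couplings (`nu_ee`, `nu_ie` by s_E; `nu_ei`, `nu_ii` by
s_I), because the histology measured cortical synapses; a named
alternative additionally scales the long-range gain by s_E. Spatially the
reduction is uniform by default; a graded mode accepts a per-region
profile whose maximum is 1 so the most-affected region reaches the
end-point exactly.

Outcomes per iteration: alpha power (mean over regions of the 8–13 Hz
trapezoid-integrated Welch PSD; 4 s Hann windows, 50% overlap) and mean
PLV (zero-phase 4th-order Butterworth band-pass, analytic phase, 1 s edge
trim, off-diagonal mean), plus percent changes versus iteration 0. Noise
realizations are fresh per iteration (seeds derived from the master seed
and the iteration index); a frozen mode reuses the baseline realization to
isolate pure coupling effects. Desk-scale runs retain iterations
0, 5, ..., 50 with 10 s of retained signal per iteration; these problem
sizes are the package's reference configuration for the reduction
experiment.

## Histology stage

ROI-level densities (counts/mm^2) are averaged within subject x tissue
type x marker x layer, then modeled with linear mixed-effects fits:
fixed effects tissue type (NC reference), layer and tissue-type x layer
interaction for synapse markers, covariates age, sex and post-mortem
delay; random intercept per subject. Estimation is REML via statsmodels
with the response standardized and covariates mean-centered internally
(raw-scale fits are ill-conditioned: densities ~1e5 against 0/1 dummies).
The interaction is tested with a Wald chi-square divided by its degrees
of freedom against an F reference with between-within denominator df
(subjects minus fixed-effect columns); the same t reference serves the
pairwise contrasts, a conventional small-sample approximation in the
absence of a Satterthwaite implementation. When the interaction p < 0.05,
per-layer follow-up models yield NAGM-NC, DEMYEL-NC and DEMYEL-NAGM
contrasts; percent differences come from covariate-adjusted group means
(direct by construction, since covariates are centered). No multiplicity
correction is applied, matching raw reported p-values. A singular or
non-convergent fit raises an explicit diagnostic naming the suspect
variance component rather than returning estimates.

## Synthetic data

The connectome generator emulates tractography regularities: uniform
random 3D positions, connection probability proportional to
`exp(-d/lambda)` calibrated by bisection to the requested edge density,
log-normal weights attenuated by the same distance rule, deterministic
bridging of any disconnected components, and max-normalization. It does
not reproduce hemispheric symmetry, community structure or true fiber
lengths, so network-level results should be read as generic-topology
behavior, not subject-specific prediction.

The histology generator draws log-normal densities:
`log density = log(baseline * multiplier) + subject effect + ROI noise`,
with layer-VI multiplier presets 0.875/0.851 (NAGM) and 0.815/0.707
(demyelinated) and all other cells null; 9 NC and 33 MS subjects with two
ROIs each are assigned tissue types so that subject-level counts after
averaging are 9 NC / 29 NAGM / 13 DEMYEL. Covariates are sampled per
group with post-mortem delay shorter in MS, mirroring the reported
demographics; the generator gives covariates no effect on density, so
adjusted contrasts are unbiased for the multipliers. Between-subject and
within-subject log-scale standard deviations default to 0.15 and 0.10 —
placeholders chosen for realistic dispersion, not empirical estimates.
The transient layer-I excitatory increase is available as an off-by-
default preset because it did not survive the neuronal-density covariate
control. What passing the round-trip shows is that the statistical stage
recovers known effects under the study's nesting; it cannot validate the
magnitudes of real biological variance components.

## Numerical choices and degenerate inputs

- Fixed-point search: 201-point scan of the scalar reduction with brentq
  refinement; the lowest-activity branch is returned; residual tolerance
  1e-9 V.
- Welch band integration: trapezoid over grid points inside [8, 13] Hz.
- PLV requires at least 5 cycles at the band's low edge after edge
  trimming; (near-)constant series raise a degenerate-signal error.
- Constant-density tables raise the singular-fit diagnostic instead of
  crashing; rank-deficient designs are rejected before fitting.
- Connectome reader symmetrizes asymmetries within relative 1e-8 by
  averaging and rejects anything larger.

## Known limitations

- The operating point is a calibrated stand-in for an unavailable
  published set; absolute percent changes at the end-points depend on the
  noise amplitude and should not be read as predictions.
- Inter-regional conduction delay defaults to 0 (pure mass coupling);
  a uniform nonzero delay is supported but untuned.
- The supercritical segment of the inhibitory path is a saturated limit
  cycle; its amplitude is set by the sigmoid, not by fitted physiology.
- Mixed-model p-values use between-within df, which is approximate for
  crossed designs with few doubly-measured subjects.
- At the 10 s-per-iteration desk scale the alpha-power estimate of the
  near-critical baseline carries substantial sampling noise (the peak is
  narrower than 1 Hz, so one iteration holds only a few independent
  envelope samples). Rank-based monotonicity statistics of single-seed
  excitatory curves are therefore noisy at this scale; the seed-averaged
  curve is the meaningful summary. A broader (more damped) baseline peak
  would stabilize the estimate but is incompatible with the inhibitory
  path crossing the alpha instability by the measured end-point, which is
  what produces the saturation plateau.
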