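# ctnet

Corticothalamic network modeling of excitatory and inhibitory synaptic
loss, with the nested mixed-model density analysis that motivates it.

In multiple sclerosis (MS), post-mortem cortex shows reduced densities of
both excitatory (vGLUT/PSD95) and inhibitory (vGAT/gephyrin) synapses in
cortical layer VI — about −12.5% and −14.9% in normal-appearing gray
matter relative to non-neurological controls. `ctnet` is for
computational neuroscientists who want to ask what such losses do to
large-scale brain dynamics: it simulates a network of corticothalamic
mean-field units over a structural connectome, reduces the cortical
synaptic couplings step-wise to those measured end-points, and quantifies
the outcome as alpha-band (8–13 Hz) spectral power and phase-locking-value
(PLV) connectivity. A separate module reproduces the statistical stage
that produces such end-points from nested histology tables (linear
mixed-effects contrasts of densities across tissue types and layers,
controlled for age, sex and post-mortem delay).

## The model

Each of 78 cortical regions (AAL cortical parcellation) is a
corticothalamic unit with cortical excitatory (e) and inhibitory (i) and
thalamic reticular (r) and relay (s) populations. Population voltages obey
second-order dendritic dynamics driven by delayed presynaptic rates,

    D_a V_a(t) = sum_b nu_ab * phi_b(t - tau_ab),
    D_a = (1/(alpha*beta)) d^2/dt^2 + (1/alpha + 1/beta) d/dt + 1,

with the sigmoid rate function `Q(V) = Q_max / (1 + exp(-(V-theta)/sigma'))`,
damped axonal propagation for the cortical excitatory field phi_e, a
corticothalamic loop delay t0 split equally over the descending and
ascending legs (the alpha resonance is the loop mode near 1/t0), and white
noise driving the relay nucleus. Regions communicate through their
excitatory populations: region j receives
`g * sum_k W_jk * phi_e_k` with W the row-normalized structural
connectome. A reduction experiment scales (nu_ee, nu_ie) by s_E and
(nu_ei, nu_ii) by s_I linearly over 50 iterations toward the measured
end-points (s_E -> 0.875, s_I -> 0.851) in three conditions — excitatory,
inhibitory, combined — and records alpha power and mean PLV per iteration.

A linearized transfer-function oracle (closed-form PSD and a Nyquist
winding-number stability test) verifies the integrator independently;
see `docs/methods.md` for the model account, parameter table and the
calibration of the default operating point.

Because neither the study's tractography matrix nor its raw density
measurements are publicly deposited, the package ships generators for
both: a distance-rule log-normal connectome sampler and a nested
log-normal histology sampler that emulates the study design (9 control,
29 normal-appearing, 13 demyelinated subject-level measurements; layers
I, II, III, VI; two synapse and three neuron markers; realistic covariate
distributions).

## Worked example

```python
import ctnet

params = ctnet.CorticothalamicParams()          # calibrated alpha regime
conn = ctnet.generate_connectome(
    ctnet.ConnectomeSimConfig(seed=42)
).replace(global_coupling=5e-5)

schedule = ctnet.ReductionSchedule(condition="inhibitory")
result = ctnet.run_experiment(
    params, conn, schedule, seed=1, iterations=[0, 25, 50]
)
print(result.to_frame().round(3).to_string(index=False))
```

```
 condition  iteration  alpha_power  mean_plv  pct_power  pct_plv
inhibitory          0       34.063     0.471      0.000    0.000
inhibitory         25       75.297     0.930    121.055   97.627
inhibitory         50       93.435     0.986    174.302  109.386
```

Reading the table: with inhibitory couplings reduced by 7.45% (iteration
25) alpha-band power has already doubled; at the measured −14.9%
end-point (iteration 50) the network has crossed the alpha instability —
power is up ~174% over baseline and the regions phase-lock almost
completely. The excitatory condition moves both outcomes the opposite
way, and the combined condition behaves like the inhibitory one:
disinhibition dominates.

The histology stage runs the other direction — from a density table to
end-points:

```python
table = ctnet.generate_histology(ctnet.HistologySimConfig(seed=7))
contrasts = ctnet.fit_density_model(table, "synapse")
```

Command-line equivalents: `synth-connectome`, `synth-histology`,
`simulate-experiment --condition inhibitory --connectome conn.tsv --out out/`,
`histology-stats --input table.csv --marker-class synapse --out out/`.

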