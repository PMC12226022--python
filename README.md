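# plastinet

Calcium-based long-term synaptic plasticity, simulated synapse by synapse, and
the network analyses that relate plastic change to connectivity structure —
on fully synthetic, seeded cortical-microcircuit data.

The package is aimed at computational neuroscientists who want to study, at
desk scale, how a biophysically grounded plasticity rule interacts with
network-level features: directed-simplex motifs and k-edge indegree,
functional cell assemblies detected from spike trains, spatial synapse
clusters on dendrites, spike-time reliability, and input–output distance
structure — together with the null models (pair-based STDP, K-dimensional
random walks, rate-matched neuron sets, degree-preserving control subgraphs)
needed to interpret them.

## The model

Each synapse carries a bounded efficacy ρ ∈ [0, 1] with bistable dynamics
around the unstable fixed point ρ\* = 0.5,

    τ dρ/dt = −ρ(1−ρ)(ρ\*−ρ) + γ_p (1−ρ) Θ(Ca\* − θ_p) − γ_d ρ Θ(Ca\* − θ_d),

driven by a leaky integrator Ca\* (τ\* = 278.318 ms) of spine calcium, which
in turn follows NMDA-receptor current (voltage-gated by the Jahr–Stevens
Mg²⁺ block) and per-postsynaptic-spike VDCC impulses:

    d[Ca]ᵢ/dt = (I*_NMDA + I_VDCC) · η/(2FX) − ([Ca]ᵢ − [Ca]ᵢ⁽⁰⁾)/τ_Ca.

The depression/potentiation thresholds θ_d < θ_p of every synapse are linear
functions (2×2 matrices, apical vs. basal dendrites) of the calcium peaks
c_pre and c_post that single pre- or postsynaptic spikes evoke there —
measured in silico by the package itself. Changes in ρ are converted by
low-pass filtering (τ_change = 100 s) into the release probability U_SE and
peak AMPA conductance. The local dendritic voltage is a reduced kernel model
(EPSPs, distance-attenuated back-propagating APs); see `docs/methods.md` for
every parameter, unit and design decision.

## Worked example

Measure a synapse's calcium fingerprints, derive its thresholds, and pair
pre- and postsynaptic spikes at ±10 ms (30 pairings at 10 Hz):

```python
import numpy as np
from plastinet import plasticity as pl

params, kernels = pl.PlasticityParams(), pl.DriverKernels()
syn = pl._reference_table(kinds=("basal",))          # one reference synapse
c_pre, c_post = pl.measure_c_pre_c_post(syn, kernels, params)
syn["c_pre"], syn["c_post"] = c_pre, c_post
syn["theta_d"], syn["theta_p"] = pl.derive_thresholds(
    c_pre, c_post, ["basal"], params)
syn["rho"] = 0.5

pre = 100.0 + 100.0 * np.arange(30)
for lag in (+10.0, -10.0):
    trains = {int(syn.pre[0]): pre, int(syn.post[0]): np.sort(pre + lag)}
    trace = pl.simulate(syn, trains, 8000.0, kernels, params)
    print(f"lag {lag:+.0f} ms: rho 0.5 -> {trace.rho[0, -1]:.3f}")
```

prints

```
lag +10 ms: rho 0.5 -> 0.344
lag -10 ms: rho 0.5 -> 0.004
```

A single presynaptic spike evokes c_pre ≈ 16.5 µM against c_post ≈ 0.017 µM
(a ~10³ ratio), giving this synapse θ_d ≈ 931 and θ_p ≈ 4898 µM·ms. Causal
pairing pushes Ca\* past the potentiation threshold during the volleys and
ends far above the anti-causal outcome (0.344 vs 0.004, the classic timing
asymmetry); both protocols pay a depression toll while Ca\* decays back
through the θ_d band after the last pairing, which is why even the causal
end state sits below the 0.5 start. With no spikes at all, ρ stays exactly
at its fixed point, and bisection of the drive-free dynamics locates the
separatrix at 0.500000.

## Pipeline and CLI

`plastinet run --config cfg.yaml --out rundir` executes
generate → simulate → analyze with per-stage seeds fanned out from one
master seed; re-running a config is bit-identical. Sub-commands
(`generate`, `simulate`, `assemblies`, `topology`, `clusters`, `metrics`,
`controls …`) operate on the plain-text artifacts (edge lists, two-column
spike files, TSV synapse tables, JSON schedules, HDF5 traces) so each stage
is re-loadable on its own. `plastinet topology edge-centrality` accepts any
edge list in `pre post` format, including external connectomes.

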