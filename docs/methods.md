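# Methods

`plastinet` implements, at desk scale, a calcium-based model of long-term
synaptic plasticity together with the network-analysis machinery needed to
relate plastic change to connectivity structure: directed-simplex topology,
functional cell-assembly detection, dendritic synapse-cluster statistics,
spike-train reliability and input–output distance analyses, plus the control
models (pair-based STDP, K-dimensional random walk, rate-matched neuron sets,
degree-preserving control subgraphs) used to put the plasticity model's
behaviour in context. All inputs are produced by seeded synthetic generators.

## The plasticity model

Each excitatory synapse carries a bounded efficacy ρ ∈ [0, 1] with bistable
dynamics around an unstable fixed point ρ\* = 0.5:

    τ dρ/dt = −ρ(1−ρ)(ρ\*−ρ) + γ_p (1−ρ) Θ(Ca\* − θ_p) − γ_d ρ Θ(Ca\* − θ_d)

with τ = 70 s, γ_d = 101.5, γ_p = 216.2 and Θ the Heaviside function. Spine
calcium obeys

    d[Ca]ᵢ/dt = (I\*_NMDA + I_VDCC) · η/(2FX) − ([Ca]ᵢ − [Ca]ᵢ⁽⁰⁾)/τ_Ca

with unbuffered fraction η = 0.04, Faraday constant F, spine volume X
(default 0.09 µm³) and clearance τ_Ca = 12 ms. The NMDA current is
I = g·m(V)·(V − E_NMDA) with E_NMDA = −3 mV and the Jahr–Stevens magnesium
block m(V) = 1/(1 + ([Mg²⁺]ₒ/θ)·e^(−κV)), θ = 2.552, κ = 0.072,
[Mg²⁺]ₒ = 1 mM. A leaky integrator Ca\* of the calcium excess
(τ\* = 278.318 ms) is compared against two synapse-specific thresholds
θ_d < θ_p, derived as 2×2 linear maps (apical or basal) of the peak calcium
transients c_pre and c_post that a single presynaptic or postsynaptic spike
evokes at that synapse. Changes in ρ are converted by low-pass filtering
(τ_change = 100 s) into the release probability U_SE and the peak AMPA
conductance ĝ_AMPA, which relax between depressed and potentiated endpoint
values; ĝ_NMDA is set from the final ρ when a run's end state is exported.

**Sign convention.** `nmda_calcium_current` returns the current as printed
above (negative = inward below reversal); the engine feeds `−I · η/(2FX)`
into the concentration equation so that an open channel at
depolarised-but-subreversal voltage produces calcium influx.

**Units.** Calcium is tracked in µM and Ca\* in µM·ms; time in ms (ρ, U_SE
and ĝ time constants are stated in seconds); voltage in mV, conductance in
nS, current in pA. The resting calcium default is 0.07 µM (70 nM). The
literature value printed alongside the model reads "70 pM", three orders of
magnitude below typical resting calcium; we treat this as a units slip,
default to 70 nM, and leave the printed value reachable through
configuration rather than silently correcting either way.

## The reduced voltage driver

The original model obtains the local dendritic voltage from morphologically
detailed compartmental simulations. Here V(t) is a per-synapse kernel model:

- presynaptic spikes (after a 1 ms synaptic delay) add a peak-normalised
  double-exponential EPSP (default 8 mV, rise 1 ms, decay 18 ms) and open a
  double-exponential NMDA conductance (rise 2 ms, decay 40 ms, peak ĝ_NMDA);
- postsynaptic spikes add a back-propagating-AP kernel (default 60 mV at the
  soma, rise 1 ms, decay 10 ms) whose amplitude attenuates with path distance
  as exp(−d/λ), λ = 200 µm, and inject a VDCC calcium impulse
  (0.02 µM per spike, attenuated the same way).

This keeps the two mechanisms the plasticity rule needs — NMDA calcium gated
by local depolarisation for presynaptic input, and BAP/VDCC signalling of
postsynaptic firing — while replacing cable physics with six explicit,
configurable kernels. Kernel defaults were chosen once for plausible
dendritic magnitudes and to satisfy the model's own structural requirements
(presynaptically evoked calcium peaks at least two orders of magnitude above
postsynaptically evoked ones; a causal pre→post pairing advantage). They are
calibration targets, not measured quantities.

With these defaults a single presynaptic spike evokes c_pre ≈ 16.5 µM versus
c_post ≈ 0.016 µM (ratio ≈ 10³, matching the reported three-orders-of-
magnitude separation).

## Threshold calibration

The fitted threshold matrices of the source model are not published. The
shipped defaults are produced by `calibrate_threshold_matrices`, which places
the thresholds on a reference synapse (apical at 100 µm, basal at 30 µm path
offset) so that:

1. a single presynaptic spike crosses neither threshold;
2. a single causal pre→post pair at 10 ms lag crosses θ_d;
3. ten causal pairs at 10 Hz cross θ_p;
4. ten anti-causal (post→pre) pairs at 10 Hz do **not** cross θ_p.

θ_d sits 30 % of the way from the single-pre Ca\* peak to the single-pair
peak; θ_p halfway between the anti-causal and causal volley peaks. Condition
(4) is our addition to the first three: without it the potentiation
threshold cannot separate causal from anti-causal volleys and the model loses
its spike-timing asymmetry. Each threshold is expressed as
α·(c_pre + c_post), i.e. the default matrices have equal entries per row;
they are configuration-first and any 2×2 matrices can be substituted. The
resulting frozen defaults give, on the basal reference synapse,
θ_d ≈ 931 µM·ms and θ_p ≈ 4898 µM·ms.

A consequence worth knowing: because every synapse shares the same kernels,
two presynaptic spikes within ~330 ms (the Ca\* decay window) sum to just
under the causal-pair level, so sustained presynaptic firing above ~1 Hz
eventually crosses θ_d and depresses. The end-to-end analyses therefore run
at sparse, in-vivo-like rates (0.1–0.5 Hz background), where uncorrelated
activity rarely crosses and plastic change discriminates co-firing from
firing rate. In the full-scale model this margin comes instead from the
per-synapse variability of c_pre and of the fitted thresholds.

## Integration scheme

Operator splitting at dt = 0.1 ms (default): the four voltage/conductance
kernels are exact single-pole filter pairs (spikes are binned to the grid);
calcium and Ca\* use exponential-Euler steps with trapezoidal drive; ρ uses
forward Euler, clamped to [0, 1]. The Heaviside terms are evaluated with
crossing-time interpolation: within a step the fraction of time Ca\* spent
above each threshold is computed by linear interpolation between the step's
endpoints, and the γ terms are weighted by that fraction. Plain post-step
evaluation quantises crossing durations to dt and cannot meet the integrator
convergence requirement (halving dt changes the final ρ of a pairing
protocol by < 10⁻⁴); with interpolation the observed dt-halving difference
is ≈ 8·10⁻⁶. U_SE and ĝ_AMPA are updated every step by the exact exponential
relaxation toward their ρ-dependent targets. With no spikes the state
(ρ ∈ {0, 1}, [Ca]ᵢ = rest, Ca\* = 0) is exactly stationary, by construction.

Non-plastic synapses carry negative sentinel thresholds; the engine treats
them as disabling both Heaviside terms and freezes ρ entirely.

The drive-free bistability analyses (`integrate_rho_free`, `find_separatrix`)
use forward Euler at dt = 10–50 ms, ample for the 70 s time constant of the
cubic; bisection to 10⁻⁶ locates the separatrix at ρ\* = 0.5. Note that the
approach rate to the stable fixed points is ρ\*(1)/τ = 1/(2τ), so a
trajectory started at 0.9 retains a residual 0.1·e^(−600/140) ≈ 1.9·10⁻³
after 600 s — "convergence to 1" at that horizon means to ≈ 0.998, not to
10⁻³.

## Synthetic data

The generators emulate the study conditions the analyses expect, not a
biophysically complete circuit:

- **Network**: nodes in a cylindrical column (radius 250 µm, depth 1.5 mm)
  with six layer strata (fractions configurable, default uniform) and an
  arbitrary user-supplied connection-probability function of the node
  attribute pair; every ordered pair is sampled independently.
- **Synapses**: per-connection counts follow a shifted negative binomial
  truncated to [1, 20], moment-matched to 4.1 ± 2.3 synapses per connection.
  (A shifted geometric — the one-parameter special case — cannot reach an SD
  of 2.3 at mean 4.1; the extra dispersion parameter is the minimal fix.)
  Branches are abstract straight segments (10 per neuron, 200 µm), so
  along-branch distance equals Euclidean distance; apical/basal is a
  per-branch Bernoulli with a post-layer-dependent probability (default 0.3
  apical).
- **Stimulus patterns**: fibers with uniform 2-D flat-map locations are
  grouped into bundles by seeded k-means (default 100 bundles); four disjoint
  base patterns A–D of ⌊0.12·n_bundles⌋ bundles each, E–G pairwise unions,
  H–I triple unions, J the union of all four. H and I share 2 of their 3
  bases — exactly 66 % at bundle level; at fiber level the share fluctuates
  a few percent with the k-means bundle sizes.
- **Stimulus spike trains**: per presentation, fibers of the active pattern
  draw from an inhomogeneous Poisson profile with a 10 ms linear rise to the
  maximal rate (17.5 Hz) and exponential adaptation (τ = 50 ms) over the
  100 ms window; presentations are balanced permutation blocks at 500 ms
  inter-stimulus onset intervals. A nonspecific fiber group is active at
  every presentation at half the maximal rate. The original study used an
  adapting Markov renewal process; the parametric profile preserves its peak
  rate and adaptation with three interpretable parameters.
- **Planted activity**: co-firing neuron groups assigned to
  (pattern, latency-window) slots with Poisson volleys, over a Poisson
  background — ground truth for assembly-recovery scoring.
- **Initial states**: every synapse starts at a fixed point, ρ ∈ {0, 1},
  Bernoulli per (pre-layer, post-layer) pathway probability, with U_SE and
  ĝ_AMPA at the corresponding endpoints. The extracellular-calcium effect on
  release probability is a single configurable scale factor on U_SE.

What the generators do **not** emulate: morphology (no SWC, no tortuosity),
depth-dependent fiber innervation profiles, inhibition, short-term
(Tsodyks–Markram) release dynamics during simulation, and the full circuit's
heterogeneous synaptic physiology. Passing tests show the analysis machinery
is correct and the model behaves as specified on controlled inputs — not
that the desk-scale numbers transfer to a full-scale cortical simulation.

## Analyses

- **Assemblies**: 20 ms bins; significant bins exceed the mean population
  rate plus the 95th percentile of the standard deviations of 100 controls in
  which each neuron's binned train is circularly shifted by an independent
  uniform offset (the natural reading of "shifted by any amount"; it
  preserves rates and ISI structure). Significant-bin activation vectors
  (raw spike counts, not binarised) are clustered with Ward linkage on
  1 − cosine distance; the cluster count minimises the Davies-Bouldin index
  (standard Euclidean definition, computed on the activation vectors; the
  metric mismatch with the cosine clustering is deliberate and documented)
  over k = 5..20, ties toward smaller k. Neurons join a cluster when their
  correlation with its binary activation series beats the 95th percentile of
  1000 circular-shift controls of their own train (computed for all shifts at
  once via FFT cross-correlation); a cluster is an assembly only if its
  members' mean pairwise correlation beats the dataset-wide mean. Sequence
  reliability is the mean pairwise Hamming similarity over a pattern's
  repetitions; group differences use the Kruskal–Wallis test. The 95th
  percentile membership rule carries an intrinsic ≈5 % false-positive rate
  per neuron and cluster; recovery scores on planted data reflect it.
- **Topology**: directed k-simplices are counted by vertex-ordered DFS with
  successive out-neighbourhood intersections; a directed simplex is an
  ordered tuple, so reciprocal edges (allowed; self-loops rejected) can
  contribute several simplices on one node set — the brute-force oracles
  count the same way. k-edge indegree of (u, v) is the k-simplex count of
  the subgraph induced on the common in-neighbours of u and v, which equals
  counting (k+2)-simplices whose last edge is (u, v); the equality is tested.
  Probability-of-change curves use integer bins for metric values ≤ 2 and
  logarithmic bins above, suppressing bins with < 50 edges.
- **Synapse clusters**: a synapse qualifies with ≥ 9 same-branch neighbours
  within 10 µm; qualifying synapses within 10 µm merge transitively, so
  clusters span more than 20 µm when windows chain. Significance compares
  the cluster's nearest-neighbour distances with an exponential null whose
  rate is fitted to all same-branch nearest-neighbour distances of the
  neuron: under the null the sum of n such distances is Gamma(n, 1/λ) and
  the p-value is its lower tail (zero distances are jittered by a configurable
  epsilon and logged). The synaptic clustering coefficient (SCC) — defined in
  a companion study we do not reproduce exactly — is implemented as the
  z-score, against 1000 seeded same-size random synapse subsets of the same
  neuron, of the mean nearest-neighbour distance among the assembly synapses,
  sign-flipped so larger means more clustered. Target neurons maximise the
  product of their ranks in assembly-indegree and SCC. Michelson contrasts
  ((P(out|cat) − P(out))/(P(out|cat) + P(out))) are reported per category,
  NaN for empty categories and 0 when both probabilities vanish; change
  amplitude uses a two-way ANOVA (statsmodels, type-II).
- **Response metrics**: spike-time reliability bins at 1 ms, smooths with a
  10 ms Gaussian, mean-centres, and averages cosine similarities over
  repetition pairs (empty-train pairs contribute 0, logged). Input distances
  between patterns are exact earth-mover's distances between their fiber
  location clouds (uniform weights, Euclidean ground metric, HiGHS linear
  program up to 500 points per cloud, Sinkhorn above, logged); output
  distances compare mean-ρ vectors over the shared connection set
  (Euclidean, changed-flag Hamming, or 1-D EMD of the value distributions).
  Input–output association uses Pearson correlation of the condensed
  triangles with a Mantel-style permutation p-value (10⁴ label permutations
  by default; the source analysis does not state its test). The Euclidean
  output distance spans all shared connections, not only ever-changing ones.
- **Controls**: the pair-based STDP rule defaults to all-to-all pairing
  (the classic form; nearest-neighbour available), with unbounded weights —
  it serves only as a change-magnitude control. The random-walk control
  moves all K coordinates by ±ε per step (norm exactly ε√K) and is compared
  with the diffusive l√N law. Rate-matched controls sample without
  replacement by decile stratification of the assembly's rate distribution,
  excluding members unless a stratum cannot be filled (then flagged and
  logged). Control subgraphs redraw the same number of edges among the
  changing subgraph's nodes, preserving 0- and 1-simplex counts exactly.

## Reproducibility and problem sizes

Every generator and shuffle takes an explicit seed; the pipeline fans a
master seed out per stage through `numpy.random.SeedSequence(master).spawn`,
so a rerun with the same configuration is bit-identical. The test-suite and
the acceptance script run everything at desk scale — networks of 50–300
neurons, a few thousand synapses, tens of seconds of simulated time,
oracle graphs of ≤ 12 nodes — sizes chosen so the full suite completes in
minutes on one CPU while every statistical check retains adequate power.
The headline circuit-scale findings of the source study (e.g. the global
fraction of changing synapses, or the magnitude of the input–output distance
correlation) depend on the 200k-neuron morphological circuit and are treated
as direction checks only at this scale.

## Known limitations

- Homogeneous kernels make c_pre, and hence the thresholds, nearly identical
  across synapses; the sparse-rate caveat above follows from this.
- The reduced driver has no dendritic nonlinearities beyond the Mg²⁺ block,
  no NMDA-spike or plateau events, and E_NMDA = −3 mV (as printed) caps the
  calcium driving force at strong depolarisation.
- Short-term plasticity is not simulated; U_SE is carried as a plasticity
  output only, since the synthetic spike trains have no release-dynamics
  consumer.
- Assembly detection quality degrades gracefully but measurably when the
  Davies-Bouldin scan over-splits clusters; analyses that need a
  per-planted-group readout should map detected assemblies to groups by best
  Jaccard, as the recovery tests do.
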