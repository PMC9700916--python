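# Methods

This note records the models implemented in grnlink, the parameters that
matter, and the design decisions taken where more than one reasonable
choice existed. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Dynamical model

All dynamics follow `dg_i/dt = f_i(g) − λ g_i` on non-negative
concentrations, with a shared degradation rate λ (default 1 per time
unit). Genes designated as *clamped* (input signals such as a morphogen
gradient) follow externally imposed trajectories and are neither
synthesised nor degraded; they enter every other gene's synthesis term as
ordinary inputs.

### Hill ground truth

The mechanistic synthesis term is a sum of activating Hill terms times a
product of inhibitory Hill factors,

    f_i = ( Σ_j b_ij g_j^n / (K_ij^n + g_j^n) ) · Π_l K_il^n / (K_il^n + g_l^n),

with Hill coefficient n = 2 throughout. Consequences worth noting:

- a gene with no activators has `f_i = 0` (the empty sum) and simply
  decays. Input-signal genes are modelled by clamping, not by basal
  synthesis. Because of this, the random-network generator never assigns
  an inhibitor as the sole regulator of a target — such a link would be
  mathematically invisible in the dynamics and unrecoverable by any
  inference method;
- `0 ≤ f_i ≤ Σ b` over incoming activations (saturation bound).

**Integration** is forward Euler with internal step `dt_int = 0.01` time
units, sub-sampled onto the requested output grid. Euler can overshoot
into negative concentrations on stiff parameter draws, so the state is
clipped at zero after every step. The decay error against the closed form
`e^{−λt}` is O(dt), verified by the step-halving test.

### Adaptation and the enumeration screen

Adaptation of an output gene to an input step is summarised by two
numbers measured on a trajectory: **sensitivity**, the peak absolute
excursion from the pre-stimulus baseline, and **adaptation error**, the
absolute offset between the fully adapted level (end of horizon, with a
settling check: drift over the final 10% of the horizon below 1e-3,
otherwise flagged) and the baseline.

The enumeration screen asks whether a *topology* can adapt: all b and K
are drawn i.i.d. from the unit-rate exponential `p(x) = e^{−x}`, the
clamped input is held at 0.5 for 10 time units (pre-equilibration) and
stepped to 1.5 for 30, and a parameter set passes when sensitivity
≥ 0.2 × |step| and adaptation error ≤ 0.1 × sensitivity. A topology is
called successful at ≥ 2 passes out of 100,000 draws. The thresholds and
the step protocol are configuration parameters (`AdaptationScreen`); the
defaults were chosen once on the grounds that unit-mean exponential
parameters put K and b at order 1, so an order-1 input step probes the
responsive range of the kinetics. The screen is vectorised across
parameter sets (one Euler loop over ~4,000 steps on arrays of 100,000
draws), which keeps the full run in the minutes range on one CPU.

### A caveat about the printed reference circuits

The two bundled six-link reference circuits (`table1_ifl`, `table2_ifl`)
ship with fixed reference parameter sets. Under the product-form kinetics
above, a protocol scan (baselines and steps over [0, 8]², long horizons)
shows both circuits respond *monotonically* to any sustained input step —
the intermediate gene either saturates its input term or operates far
below its half-saturation constant, so the negative arm never pulls the
output back down. Their displayed "response then recovery" behaviour is
the response to a *transient* stimulus (applied, then removed), and that
is how the fixture generator exercises them. For experiments that need
genuine sustained-step adaptation (pruning to a functional motif), the
package ships `adapting_ifl`: the minimal incoherent feed-forward loop
equipped with a representative parameter set drawn from the unit-rate
exponential and retained by the adaptation screen (rounded to three
decimals). Its output peaks at ≈ 0.46 for a 0.5 → 1.5 input step and
returns to within 0.5% of the peak of its baseline.

## The learned synthesis term

`f` is a fully connected network with four layers: input of width
n_genes, two ReLU hidden layers (default 64/64 — the layer count is part
of the model, the widths are a free capacity choice), and a sigmoid
output of width n_genes, so every component of `f` lies in (0,1).

**Normalization.** Each gene is min-max scaled to [0,1] over the pooled
training series; the scaler is stored on the model so raw data can be
mapped in and out.

**Training** is one-step teacher forcing: predict
`ĝ(t+dt) = g(t) + (f(g(t)) − λ g(t))·dt` and minimise
`√Σ‖ĝ(t+dt) − g(t+dt)‖²` over all consecutive pairs of all series (pairs
never span series boundaries). Clamped genes — globally clamped inputs
and genes held fixed during a perturbation block — are fed as inputs but
excluded from the loss. The optimiser is full-batch Adam (default
learning rate 1e-3, 2,000 epochs), entirely in numpy: the networks are
small, and manual backprop keeps training bit-reproducible per seed. If
the loss ever turns non-finite, training aborts at the last finite
checkpoint. The recorded per-epoch loss refers to the parameters entering
that epoch, so the loss and the gradient always describe the same
parameters.

**Step size and representability.** The training step `dt` is taken from
the data grid. With λ·dt = 1 (unit degradation, unit sampling — the
classical choice) the update collapses to `ĝ(t+1) = f(g(t))`, and the
target always lies inside the sigmoid's range. On finer grids the
implied target `f = (g_next − g)/dt + λg` can exceed 1 during the fastest
transients of a step response; with the default fixture grid (dt = 0.25)
this affects at most the first sample after a step and is visible as a
small irreducible one-step error there. Coarser grids avoid that cap but
make the learned `f` a one-step *flow map* rather than an instantaneous
rate, which has one consequence for attribution (next section).

## Link knockout readout

The signed effect of regulator i on target j is
`Δ_ij = f_j(..., g_i, ...) − f_j(..., μ·g_i, ...)`, averaged over all
observed timepoints of all series (the arithmetic mean is the default
aggregation; max-|Δ| is available). μ = 0 is a full knockout; μ = 1
reproduces the wild type exactly. Network calls: edge weight = |mean Δ|,
sign = sign of the mean; binarisation either by top-k or by a relative
null band (weights below 5% of the model's largest weight are called
absent — a three-way Act/Null/Inh call needs an explicit null band, and a
per-model relative threshold keeps it scale-free). Self-edges are
retained as self-regulation calls; clamped genes are never targets.

**Self-persistence on coarse grids.** Because training data come from the
continuous flow, a model trained at λ·dt near 1 carries `e^{−λ·dt}` of
each gene's own level into its next-step prediction; the plain knockout
formula reads that memory as self-activation. An optional correction
(`self_correction=True`) subtracts the closed-form persistence
`[λ + (e^{−λ·dt} − 1)/dt] · (1−μ) · mean(g_j)` from diagonal deltas; it
is exact for genes whose synthesis does not depend on themselves and
vanishes as dt → 0. It is off by default — the default is the plain
discounting formula — and recommended whenever λ·dt is of order 1.

**Mutant trajectories** iterate the one-step update with the knocked
link's input discounted only inside the target's synthesis evaluation,
every step. The learned map folds within-step dynamics of the *intact*
circuit into `f`, so mutant rollouts carry a small systematic gap (beyond
fit error) relative to finely integrated mechanistic mutants; the tests
bound it at 0.2 normalized units on the reference fixture. A mutant that
drives a gene far outside its training range (e.g. deleting the only
brake on a strongly self-activating gene) leaves the sigmoid-bounded
model unable to follow the mechanistic excursion — the *direction* of the
effect remains correct, the magnitude saturates.

## Pruning to a minimal functional motif

`prune_network` starts from the network inferred by knockout and
repeatedly: (1) tentatively knocks out each surviving edge (μ = 0 in the
model's input mask), (2) scores the step-response function (sensitivity,
adaptation error) of each mutant, (3) permanently removes the edge whose
removal changes the pair least (L1 change normalized by the initial
sensitivity; ties broken lexicographically by regulator then target
index), and (4) retrains with that input forced off for a reduced budget
(default 500 epochs, i.e. 25% of the initial). It stops before a removal
that would drop sensitivity below (1 − 0.3) of the initial value or push
adaptation error above the initial error + 0.15 × initial sensitivity —
the point where the network has too few links to perform the function.
If the starting network does not perform the function at all
(sensitivity < 0.05 normalized, or error > 0.5 × sensitivity), pruning
raises instead of silently "preserving" a function that is not there.
Both tolerances are parameters; the defaults are loose enough to ignore
fit noise and tight enough that deleting any arm of a working
feed-forward loop trips them.

## Repeated-training majority vote

Training is stochastic in its initialisation, so edge calls are tabulated
over n independent seeds (default 40) as (activated / absent / inhibited)
counts per ordered gene pair; the majority network takes the plurality
call, with ambiguous ties resolving to absent.

## Evaluation conventions

The candidate universe is every ordered (TF, gene) pair excluding
self-edges (the community convention for in-silico benchmarks, whose gold
standards exclude autoregulation); NN-derived self-edge calls are dropped
before benchmark scoring. Confusion metrics (TPR, FPR, MCC, ACC, F1) come
from the 2×2 table over candidate pairs after top-k binarisation (ties at
the cutoff broken by weight, then regulator, then target); MCC is defined
as 0 when a marginal is zero. AUROC uses the trapezoidal, tie-aware
(Mann–Whitney) convention and AUPR the step-wise precision–recall
integral; candidate pairs missing from a prediction are appended with
weight 0, and a gold standard with no positives raises. Note the
step-wise AUPR of an uninformative ranking fluctuates *around* the
positive rate — its expectation carries a small positive bias, and single
instances can land below the baseline; it is not a pointwise lower
bound. Network density is `edges / (genes × TFs)`, reported to 4
decimals.

## Synthetic data

The generator produces everything the pipeline consumes, so no external
benchmark download is needed. What it emulates, and what it does not:

- **Preset circuits** (`table1_ifl`, `table2_ifl`, `adapting_ifl`): the
  clamped input sits at 0.5, steps up by an amplitude drawn uniform(0.5,
  1) for the first half of the horizon, then returns (applied-then-removed
  perturbations); optional Gaussian white noise of configurable standard
  deviation is added to the input trace at sample resolution (clipped at
  zero). Defaults: 4 series × 121 points at dt = 0.25 over 30 time units.
- **Random sparse networks**: signed Erdős–Rényi-style topologies over the
  TF × gene candidate pairs with an exact edge count set by the target
  density, 25% inhibitory edges (subject to the no-lone-inhibitor rule),
  and unit-exponential Hill parameters; the gold standard equals the
  topology by construction. Benchmark-shaped runs use 100 genes at
  density ≈ 0.02 with 10 perturbation protocols × 21 points at dt = 1.
- **Perturbation blocks**: a perturbation holds a random gene subset at
  uniform(0.5, 1.5) levels for the first half of the horizon, then
  releases it. Each protocol is emitted as two series blocks — hold and
  release — with the held genes marked clamped during the hold: an
  externally held gene follows no dynamics of its own, so its held
  samples are valid model *inputs* but invalid prediction *targets*
  (pooling them as targets teaches a spurious "this gene holds its level"
  map). Every series consumes an independent child seed, and noise
  variates are drawn in a fixed order even at noise 0, so a seed pins the
  perturbations at any noise level.

What passing tests on these fixtures do **not** show: robustness to
measurement noise on all genes (only the input trace is noised),
unobserved regulators, non-uniform sampling, or kinetics outside the
product-form Hill family. Real expression data violate all four.

## Problem sizes and determinism

The test suite and the acceptance script were sized for a single CPU:
100,000-draw screens (vectorised), 3-gene fixtures with 2,000-epoch
trainings, ten-seed recovery panels, and three 100-gene benchmark
instances at 800 epochs. Every stochastic step takes an explicit seed
(numpy Generator); training, generation and the screen are reproducible
bit-for-bit per seed.

## Known limitations

- The learned `f` is only trustworthy on the envelope of states visited
  by the training series; cross-sections and knockouts extrapolate
  smoothly but without guarantees outside it.
- Edges whose regulator barely moves in the data (or whose Hill term is
  orders of magnitude below its siblings) are at the detection limit;
  their signs are not stable across seeds, and the null band exists
  precisely to call such edges absent rather than guess.
- Pruning explores greedily (single-edge removals); a motif reachable
  only by removing two edges at once would be missed.
- The degradation rate is assumed known and shared (λ = 1); estimating
  per-gene degradation is out of scope.
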