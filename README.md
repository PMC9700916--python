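# grnlink

Gene regulatory network (GRN) reconstruction from time-series expression
data, built around a learned differential equation: a small fully connected
neural network stands in for the gene synthesis rate, and the regulatory
logic is read back out of the trained network by in-silico link knockout.

## Who this is for

Systems biologists and methods developers who have time-course expression
data (GeneNetWeaver/DREAM-style TSV, or anything on a uniform grid) and want

- a signed, weighted regulatory network inferred without assuming a
  parametric regulation function,
- a way to verify that an inferred topology can still perform a biological
  function (here: adaptation) when transplanted into a mechanistic
  Hill-function ODE model, and
- DREAM-style benchmarking (confusion metrics at top-k, AUROC/AUPR) against
  gold-standard edge lists.

## The model

Expression dynamics are modelled as

    dg_i/dt = f_i(g_1, ..., g_n) - λ g_i

with degradation rate λ = 1. Two interchangeable forms of the synthesis
term `f` are implemented:

**Hill kinetics (mechanistic ground truth).** Activation
`h+ = b g^n / (K^n + g^n)` and inhibition `h- = K^n / (K^n + g^n)` combine
as `f_i = (Σ_j h+_ij) · (Π_l h-_il)` with Hill coefficient n = 2. A
vectorised enumeration screen samples all (b, K) from the unit-rate
exponential `p(x) = e^(-x)` and counts parameter sets under which a
topology adapts to an input step — a topology is called *successful* when
at least 2 of 100,000 draws pass.

**Learned synthesis (the inference engine).** A four-layer perceptron
(input, two ReLU hidden layers, sigmoid output, so `f ∈ (0,1)`) is trained
by one-step-ahead Euler prediction, `ĝ(t+dt) = g(t) + (f(g(t)) − λ g(t))·dt`,
minimising `√Σ_t ‖ĝ(t+dt) − g(t+dt)‖²` over all consecutive sample pairs.

Edges are then attributed by link knockout (never by reading weights):

    Δ_ij = f_j(g_1, ..., g_i, ...) − f_j(g_1, ..., μ·g_i, ...)

averaged over observed states, with discount μ = 0 for a full knockout.
`Δ > 0` means regulator i activates target j, `Δ < 0` means inhibition.
On top of this sit mutant trajectory simulation, iterative pruning to a
minimal functional motif, and majority voting over repeated trainings.

## Worked example

Simulate the three-gene reference circuit (gene 1 is a clamped input
signal), train the network on the time courses, and read out the edges:

```python
import grnlink as gl

circuit = gl.make_preset_circuit("table1_ifl")
config = gl.GeneratorConfig(seed=100, preset="table1_ifl")
series = gl.generate_timeseries(circuit, config)

model, report, scaled = gl.fit_dynamics(series, epochs=2000, rng_seed=0)
print(f"final training loss: {report.final_loss:.4f}")

network = gl.infer_network(model, scaled, top_k=6)
for i, j, w, s in network.ranked_edges():
    kind = "activates" if s > 0 else "represses"
    print(f"{network.gene_names[i]} {kind} {network.gene_names[j]}  (|delta| = {w:.3f})")

met = gl.score_adaptation(series[0], "g3", stimulus_time=0.0)
print(f"step response of g3: peak {met.sensitivity:.3f}, residual offset {met.adaptation_error:.4f}")
```

Output:

```
final training loss: 0.8863
g1 activates g3  (|delta| = 0.451)
g3 represses g2  (|delta| = 0.259)
g1 activates g2  (|delta| = 0.255)
g2 activates g2  (|delta| = 0.067)
g3 represses g3  (|delta| = 0.045)
g2 represses g3  (|delta| = 0.022)
step response of g3: peak 0.162, residual offset 0.0000
```

The five strongest calls match the circuit exactly. The weakest one,
`g2 → g3`, is in truth a (very weak) activation: under the printed circuit
parameters g2 stays below 4% of its half-saturation constant, so that
link's Hill term never exceeds 2·10⁻³ and its knockout delta sits at the
detection limit — across seeds its sign occasionally flips, which is the
expected behaviour for a dynamically near-invisible link. The step
response line shows the output gene returning to its pre-stimulus level
after the transient input is removed (residual offset ≈ 0).

The same pipeline is available from the shell:

```bash
grnlink generate --preset table1_ifl --seed 100 --out ts.tsv
grnlink train --data ts.tsv --clamped 0 --seed 0 --out model.json
grnlink infer --model model.json --data ts.tsv --clamped 0 \
    --out network.tsv --pred-out predictions.tsv
grnlink evaluate --gold gold.tsv --pred predictions.tsv --top-k 250
```

## Layout

- `grnlink.hill` — Hill-function ODE models, Euler integration, parameter
  sampling, adaptation scoring, the enumeration screen
- `grnlink.nn` — the synthesis-rate network, training, rollouts,
  cross-sections, and a Hill oracle wrapper
- `grnlink.knockout` — knockout deltas, network inference, mutant
  simulation, pruning, majority voting
- `grnlink.evaluation` — gold standards, confusion metrics, AUROC/AUPR,
  densities
- `grnlink.synthetic` — preset circuits and random sparse benchmark
  generators
- `grnlink.io` / `grnlink.cli` — file formats and the `grnlink` command

See `docs/methods.md` for the modelling choices and their rationale.
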