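"""Network readout by in-silico link knockout.

Once a synthesis model f(g) has been learned, the signed effect of regulator
i on target j is attributed without ever reading network weights: evaluate
f_j at observed states with g_i intact and with g_i discounted to mu*g_i
(mu = 0 is a full knockout),

    Delta_ij = f_j(g_1, ..., g_i, ...) - f_j(g_1, ..., mu*g_i, ...),

and average over the observed timepoints. A positive mean Delta means removing
the input lowers synthesis (activation), a negative one means inhibition.
The module also simulates mutant trajectories with a link permanently
discounted, prunes a redundant network down to a minimal functional motif,
and aggregates repeated trainings by majority vote.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .hill import AdaptationMetrics
from .nn import SynthesisModel, train
from .timeseries import ExpressionTimeSeries

__all__ = [
    "KnockoutDelta",
    "RegulatoryNetwork",
    "VoteTable",
    "FunctionSpec",
    "PruningError",
    "link_knockout_delta",
    "knockout_deltas",
    "infer_network",
    "simulate_mutant",
    "adaptation_of_model",
    "prune_network",
    "repeated_vote",
]


class PruningError(RuntimeError):
    """Raised when the starting network does not perform the target function."""


# ---------------------------------------------------------------------------
# Deltas
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KnockoutDelta:
    """Mean knockout effect sizes Delta[i, j] (regulator i, target j)."""

    gene_names: list[str]
    delta: np.ndarray
    mu: float
    n_states: int
    aggregation: str = "mean"


def _as_states(states) -> np.ndarray:
    if isinstance(states, ExpressionTimeSeries):
        return states.values.T
    X = np.asarray(states, dtype=float)
    return X[None, :] if X.ndim == 1 else X


def link_knockout_delta(
    model, states, i: int, j: int, mu: float = 0.0, self_correction: bool = False
) -> float:
    """Mean signed effect of discounting regulator ``i`` on target ``j``.

    With ``self_correction`` enabled, self-deltas (i == j) of models fit to
    flow data on a coarse grid are corrected for the degradation persistence
    baked into their one-step map (see ``SynthesisModel.self_persistence``),
    so a self-edge call reflects self-regulation rather than the gene
    remembering its own level. The default is the plain discounting formula.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("discount mu must lie in [0, 1]")
    X = _as_states(states)
    if X.shape[0] == 0:
        raise ValueError("no evaluation states given")
    if j in getattr(model, "clamped_genes", frozenset()):
        raise ValueError("target gene is clamped; its synthesis is not modelled")
    f1 = model.synthesis(X)[:, j]
    Xk = X.copy()
    Xk[:, i] *= mu
    f2 = model.synthesis(Xk)[:, j]
    delta = float(np.mean(f1 - f2))
    if self_correction and i == j:
        persistence = float(getattr(model, "self_persistence", 0.0))
        delta -= persistence * (1.0 - mu) * float(X[:, j].mean())
    return delta


def knockout_deltas(
    model,
    states,
    mu: float = 0.0,
    aggregation: str = "mean",
    self_correction: bool = False,
) -> KnockoutDelta:
    """Full regulator x target knockout matrix (one forward pass per regulator)."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("discount mu must lie in [0, 1]")
    if aggregation not in ("mean", "max"):
        raise ValueError("aggregation must be 'mean' or 'max'")
    X = _as_states(states)
    if X.shape[0] == 0:
        raise ValueError("no evaluation states given")
    G = model.n_genes
    f1 = model.synthesis(X)
    delta = np.zeros((G, G))
    for i in range(G):
        Xk = X.copy()
        Xk[:, i] *= mu
        d = f1 - model.synthesis(Xk)  # effect of discounting input i, per target
        if aggregation == "mean":
            delta[i] = d.mean(axis=0)
        else:
            k = np.argmax(np.abs(d), axis=0)
            delta[i] = d[k, np.arange(G)]
    if self_correction and aggregation == "mean":
        # correct self-deltas for the degradation memory of one-step flow maps
        persistence = float(getattr(model, "self_persistence", 0.0))
        delta[np.arange(G), np.arange(G)] -= persistence * (1.0 - mu) * X.mean(axis=0)
    for j in getattr(model, "clamped_genes", frozenset()):
        delta[:, j] = 0.0  # clamped genes have no modelled synthesis
    return KnockoutDelta(list(model.gene_names), delta, float(mu), X.shape[0], aggregation)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegulatoryNetwork:
    """Signed, weighted directed network over genes.

    ``signs[i, j]`` in {+1, 0, -1} and ``weights[i, j] >= 0`` score the edge
    regulator i -> target j; sign 0 iff the edge was not called.
    """

    gene_names: list[str]
    signs: np.ndarray
    weights: np.ndarray
    provenance: str = "NN-knockout"

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.signs))

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in np.argwhere(self.signs != 0)}

    def ranked_edges(self) -> list[tuple[int, int, float, int]]:
        """Called edges as (regulator, target, weight, sign), best first.

        Ties broken by (regulator, target) indices for determinism.
        """
        edges = [
            (int(i), int(j), float(self.weights[i, j]), int(self.signs[i, j]))
            for i, j in np.argwhere(self.signs != 0)
        ]
        return sorted(edges, key=lambda e: (-e[2], e[0], e[1]))

    def ranked_candidates(self, targets: Sequence[int]) -> list[tuple[int, int, float, int]]:
        """All candidate pairs into ``targets`` ranked by weight (for AUROC)."""
        edges = [
            (i, j, float(self.weights[i, j]), int(np.sign(self.weights[i, j])))
            for i in range(self.n_genes)
            for j in targets
        ]
        return sorted(edges, key=lambda e: (-e[2], e[0], e[1]))


def infer_network(
    model,
    series: ExpressionTimeSeries | Sequence[ExpressionTimeSeries],
    mu: float = 0.0,
    top_k: int | None = None,
    null_frac: float = 0.05,
    aggregation: str = "mean",
    self_correction: bool = False,
    provenance: str = "NN-knockout",
) -> RegulatoryNetwork:
    """Signed network from knockout deltas over all observed timepoints.

    Edge weight = |mean Delta_ij|, sign = sign of the mean. Edges are either
    binarized by ``top_k`` (keep the k largest weights) or by a relative null
    band: weights below ``null_frac`` of the model's largest weight are
    called absent. Self-edges are retained (self-activation/inhibition);
    clamped genes are never targets.
    """
    if isinstance(series, ExpressionTimeSeries):
        series = [series]
    X = np.concatenate([ts.values.T for ts in series], axis=0)
    kd = knockout_deltas(
        model, X, mu=mu, aggregation=aggregation, self_correction=self_correction
    )
    weights = np.abs(kd.delta)
    signs = np.sign(kd.delta).astype(int)
    if top_k is not None:
        flat = [
            (float(weights[i, j]), i, j)
            for i, j in np.argwhere(weights > 0)
        ]
        flat.sort(key=lambda e: (-e[0], e[1], e[2]))
        keep = np.zeros_like(weights, dtype=bool)
        for w, i, j in flat[: int(top_k)]:
            keep[i, j] = True
        signs[~keep] = 0
    else:
        wmax = weights.max()
        signs[weights < null_frac * wmax] = 0
    return RegulatoryNetwork(list(model.gene_names), signs, weights, provenance)


# ---------------------------------------------------------------------------
# Mutant simulation
# ---------------------------------------------------------------------------

def _edge_mask(G: int, edges, mu: float, base: np.ndarray | None = None) -> np.ndarray:
    M = np.ones((G, G)) if base is None else np.asarray(base, dtype=float).copy()
    if edges and isinstance(edges[0], int):
        edges = [edges]
    for i, j in edges:
        M[i, j] = mu
    return M


def simulate_mutant(
    model,
    knocked_edge: tuple[int, int],
    mu: float,
    initial_state: np.ndarray,
    t_end: float,
    inputs: dict[int, np.ndarray] | None = None,
) -> ExpressionTimeSeries:
    """Rollout with one link permanently discounted.

    Only in the computation of f_target is the regulator's level replaced by
    ``mu`` times its value, every step; all other synthesis terms see the
    intact state. ``mu = 1`` reproduces the wild type exactly.
    """
    from .nn import rollout

    if not 0.0 <= mu <= 1.0:
        raise ValueError("discount mu must lie in [0, 1]")
    G = model.n_genes
    base = getattr(model, "input_mask", None)
    mutant = model.with_mask(_edge_mask(G, [knocked_edge], mu, base))
    n_steps = int(round(t_end / model.dt))
    return rollout(mutant, initial_state, n_steps, inputs=inputs)


# ---------------------------------------------------------------------------
# Functional pruning
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FunctionSpec:
    """Step-stimulus protocol defining the target function (normalized units).

    The clamped ``input_gene`` is held at ``baseline`` for ``t_pre`` to settle
    the circuit, then stepped by ``step`` for ``t_post``; adaptation of
    ``output_gene`` is scored on the post-stimulus window.
    """

    input_gene: int
    output_gene: int
    baseline: float
    step: float
    t_pre: float = 10.0
    t_post: float = 30.0


def adaptation_of_model(model, spec: FunctionSpec) -> AdaptationMetrics:
    """Sensitivity / adaptation error of a synthesis model's step response."""
    from .hill import score_adaptation
    from .nn import rollout

    G = model.n_genes
    dt = model.dt
    n_pre = int(round(spec.t_pre / dt))
    n_post = int(round(spec.t_post / dt))
    inputs = {
        spec.input_gene: np.concatenate(
            [
                np.full(n_pre + 1, spec.baseline),
                np.full(n_post, spec.baseline + spec.step),
            ]
        )
    }
    g0 = np.full(G, 0.25)
    g0[spec.input_gene] = spec.baseline
    ts = rollout(model, g0, n_pre + n_post, inputs=inputs)
    return score_adaptation(ts, spec.output_gene, stimulus_time=n_pre * dt)


def prune_network(
    model: SynthesisModel,
    series: ExpressionTimeSeries | Sequence[ExpressionTimeSeries],
    spec: FunctionSpec,
    mu: float = 0.0,
    null_frac: float = 0.05,
    sensitivity_tol: float = 0.3,
    error_tol: float = 0.15,
    retrain_epochs: int = 500,
    learning_rate: float = 1e-3,
    rng_seed: int = 0,
) -> list[tuple[RegulatoryNetwork, AdaptationMetrics]]:
    """Iteratively delete the least functionally important link.

    Starting from the network inferred by knockout, each surviving edge is
    tentatively knocked out (mu = 0 in the model's input mask) and the
    mutant's step-response metrics evaluated; the edge whose removal changes
    (sensitivity, adaptation error) least — ties broken lexicographically by
    (regulator, target) — is removed permanently and the network retrained
    with that input forced off. Pruning stops before a removal that would
    drop sensitivity below ``(1 - sensitivity_tol)`` of the initial value or
    raise adaptation error above the initial error plus ``error_tol`` times
    the initial sensitivity: the point where the network would have too few
    links left to perform the function. Returns the topology sequence with
    its metrics, starting with the unpruned network.
    """
    if isinstance(series, ExpressionTimeSeries):
        series = [series]
    series = list(series)
    net = infer_network(model, series, mu=mu, null_frac=null_frac)
    model = model.copy()
    metrics = adaptation_of_model(model, spec)
    if metrics.sensitivity < 0.05 or metrics.adaptation_error > 0.5 * metrics.sensitivity:
        raise PruningError(
            "initial network does not perform the adaptation function "
            f"(sensitivity={metrics.sensitivity:.4g}, "
            f"error={metrics.adaptation_error:.4g})"
        )
    s_ref, e_ref = metrics.sensitivity, metrics.adaptation_error
    history = [(net, metrics)]
    edges = sorted(net.edge_set())
    G = model.n_genes

    while len(edges) > 1:
        candidates = []
        for i, j in edges:
            trial = model.with_mask(_edge_mask(G, [(i, j)], 0.0, model.input_mask))
            m = adaptation_of_model(trial, spec)
            change = (
                abs(m.sensitivity - metrics.sensitivity)
                + abs(m.adaptation_error - metrics.adaptation_error)
            ) / max(s_ref, 1e-12)
            candidates.append((change, i, j, m))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        _, i, j, m_best = candidates[0]
        if (
            m_best.sensitivity < (1.0 - sensitivity_tol) * s_ref
            or m_best.adaptation_error > e_ref + error_tol * s_ref
        ):
            break  # any further removal breaks the function
        model.input_mask = _edge_mask(G, [(i, j)], 0.0, model.input_mask)
        model, _ = train(
            model,
            series,
            epochs=retrain_epochs,
            learning_rate=learning_rate,
            rng_seed=rng_seed,
        )
        edges = [e for e in edges if e != (i, j)]
        signs = history[-1][0].signs.copy()
        weights = history[-1][0].weights.copy()
        signs[i, j] = 0
        weights[i, j] = 0.0
        metrics = adaptation_of_model(model, spec)
        history.append(
            (RegulatoryNetwork(list(model.gene_names), signs, weights, "pruned"), metrics)
        )
    return history


# ---------------------------------------------------------------------------
# Repeated-training majority vote
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VoteTable:
    """Per ordered gene pair, how often repeats called Act / Null / Inh."""

    gene_names: list[str]
    counts: np.ndarray  # (G, G, 3) in the order (activated, absent, inhibited)
    n_repeats: int

    def plurality_network(self) -> RegulatoryNetwork:
        """Majority colouring; ties resolve to the null call."""
        G = len(self.gene_names)
        signs = np.zeros((G, G), dtype=int)
        weights = np.zeros((G, G))
        order = np.array([1, 0, -1])  # act, null, inh
        for i in range(G):
            for j in range(G):
                c = self.counts[i, j]
                best = int(np.argmax(c))
                if np.count_nonzero(c == c[best]) > 1:
                    best = 1  # ambiguous plurality resolves to the null call
                signs[i, j] = order[best]
                weights[i, j] = c[best] / max(self.n_repeats, 1)
        weights[signs == 0] = 0.0
        return RegulatoryNetwork(list(self.gene_names), signs, weights, "vote")


def repeated_vote(
    series: ExpressionTimeSeries | Sequence[ExpressionTimeSeries],
    n_repeats: int = 40,
    hidden_widths: tuple[int, int] = (64, 64),
    epochs: int = 2000,
    learning_rate: float = 1e-3,
    mu: float = 0.0,
    null_frac: float = 0.05,
    rng_seed: int = 0,
    models: Sequence | None = None,
) -> tuple[VoteTable, RegulatoryNetwork]:
    """Train ``n_repeats`` networks with independent seeds and tally edge calls.

    ``models`` can inject pre-built synthesis models (one per repeat), in
    which case no training happens — used for deterministic checks.
    """
    from .nn import fit_dynamics

    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    if isinstance(series, ExpressionTimeSeries):
        series = [series]
    series = list(series)
    counts = None
    names = None
    for r in range(int(n_repeats)):
        if models is not None:
            model = models[r]
            scaled = series
        else:
            model, _, scaled = fit_dynamics(
                series,
                hidden_widths=hidden_widths,
                epochs=epochs,
                learning_rate=learning_rate,
                rng_seed=rng_seed + r,
            )
        net = infer_network(model, scaled, mu=mu, null_frac=null_frac)
        if counts is None:
            names = net.gene_names
            counts = np.zeros((net.n_genes, net.n_genes, 3), dtype=int)
        counts[:, :, 0] += net.signs == 1
        counts[:, :, 1] += net.signs == 0
        counts[:, :, 2] += net.signs == -1
    table = VoteTable(names, counts, int(n_repeats))
    return table, table.plurality_network()
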