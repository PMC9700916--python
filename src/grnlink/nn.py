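"""Learned synthesis-rate function: a four-layer fully connected network.

The network maps the full (normalized) expression state g(t) to per-gene
synthesis rates f(g) in (0,1) — input layer of width n_genes, two ReLU hidden
layers, sigmoid output layer. It is trained by one-step-ahead Euler
prediction: the predicted next state

    g_hat(t+dt) = g(t) + (f(g(t)) - lam * g(t)) * dt

is matched to the observed g(t+dt), with loss sqrt( sum_t ||g_hat - g||^2 )
over all consecutive pairs of all series. Clamped input-signal genes are fed
as inputs but excluded from the loss.

Implemented as a compact numpy MLP (manual backprop, full-batch Adam): the
nets are small and everything stays deterministic per seed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .timeseries import ExpressionTimeSeries, GeneScaler, fit_scaler

__all__ = [
    "SynthesisModel",
    "TrainingReport",
    "build_synthesis_model",
    "one_step_predict",
    "train",
    "fit_dynamics",
    "cross_section",
    "rollout",
    "HillSynthesisOracle",
]

Params = list[tuple[np.ndarray, np.ndarray]]


# ---------------------------------------------------------------------------
# Raw MLP plumbing
# ---------------------------------------------------------------------------

def _init_params(n_in: int, widths: Sequence[int], n_out: int, rng) -> Params:
    sizes = [n_in, *widths, n_out]
    params: Params = []
    for k in range(len(sizes) - 1):
        fan_in = sizes[k]
        # He for the ReLU layers, Xavier for the sigmoid output
        std = np.sqrt(2.0 / fan_in) if k < len(sizes) - 2 else np.sqrt(1.0 / fan_in)
        W = rng.normal(0.0, std, size=(fan_in, sizes[k + 1]))
        params.append((W, np.zeros(sizes[k + 1])))
    return params


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def _forward(params: Params, X: np.ndarray):
    acts = [X]
    a = X
    for k, (W, b) in enumerate(params):
        z = a @ W + b
        a = _sigmoid(z) if k == len(params) - 1 else np.maximum(z, 0.0)
        acts.append(a)
    return a, acts


def _backward(params: Params, acts: list[np.ndarray], dF: np.ndarray):
    """Gradients of a scalar loss wrt params, given dLoss/dF."""
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params)  # type: ignore
    F = acts[-1]
    delta = dF * F * (1.0 - F)  # through the sigmoid
    for k in range(len(params) - 1, -1, -1):
        a_prev = acts[k]
        grads[k] = (a_prev.T @ delta, delta.sum(axis=0))
        if k > 0:
            delta = (delta @ params[k][0].T) * (acts[k] > 0)
    return grads


def _mask_groups(mask: np.ndarray | None, n_genes: int):
    """Group targets sharing the same per-input multiplier column.

    ``mask[i, j]`` multiplies input gene i when evaluating target j. Returns
    [(multiplier vector or None, target index array), ...]; a ``None`` vector
    means the inputs are untouched.
    """
    if mask is None:
        return [(None, np.arange(n_genes))]
    mask = np.asarray(mask, dtype=float)
    if mask.shape != (n_genes, n_genes):
        raise ValueError("input mask must be n_genes x n_genes")
    groups: dict[bytes, list[int]] = {}
    for j in range(n_genes):
        groups.setdefault(mask[:, j].tobytes(), []).append(j)
    out = []
    for key, targets in groups.items():
        v = np.frombuffer(key, dtype=float)
        out.append((None if np.all(v == 1.0) else v, np.asarray(targets)))
    return out


# ---------------------------------------------------------------------------
# Public model objects
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SynthesisModel:
    """Trained (or to-be-trained) synthesis-rate network.

    ``input_mask[i, j]`` permanently discounts regulator i's level in target
    j's synthesis term (1 = intact edge, 0 = knocked out); pruning works by
    accumulating zeros here. ``scaler`` records the per-gene min-max
    normalization of the training data so raw series can be mapped in and out.
    """

    gene_names: list[str]
    params: Params
    hidden_widths: tuple[int, int] = (64, 64)
    scaler: GeneScaler | None = None
    lam: float = 1.0
    dt: float = 1.0
    clamped_genes: frozenset[int] = frozenset()
    input_mask: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def self_persistence(self) -> float:
        """Degradation kernel leaking into the learned map's diagonal.

        Training data comes from the continuous flow, so over one step of
        size dt a gene whose synthesis ignores itself still carries
        e^(-lam*dt) of its own level into the next sample. Solving the
        one-step update for f, that persistence shows up as a spurious
        self-sensitivity of exactly ``lam + (e^(-lam*dt) - 1)/dt`` (zero in
        the fine-step limit). Knockout attribution subtracts it from
        diagonal deltas so self-edges reflect self-regulation, not memory.
        """
        return float(self.lam + (np.exp(-self.lam * self.dt) - 1.0) / self.dt)

    def synthesis(self, states: np.ndarray) -> np.ndarray:
        """f(g) in (0,1) for states of shape ``(G,)`` or ``(m, G)``."""
        X = np.asarray(states, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_genes:
            raise ValueError("state dimension does not match the model")
        F = np.empty_like(X)
        for v, targets in _mask_groups(self.input_mask, self.n_genes):
            out, _ = _forward(self.params, X if v is None else X * v)
            F[:, targets] = out[:, targets]
        return F[0] if single else F

    def with_mask(self, input_mask: np.ndarray) -> "SynthesisModel":
        """Copy of the model with a different permanent input mask."""
        return dataclasses.replace(self, input_mask=np.asarray(input_mask, dtype=float))

    def copy(self) -> "SynthesisModel":
        return dataclasses.replace(
            self,
            params=[(W.copy(), b.copy()) for W, b in self.params],
            input_mask=None if self.input_mask is None else self.input_mask.copy(),
        )


@dataclasses.dataclass
class TrainingReport:
    losses: np.ndarray
    seed: int
    epochs: int
    learning_rate: float

    @property
    def final_loss(self) -> float:
        return float(self.losses[-1]) if self.losses.size else float("nan")


def build_synthesis_model(
    n_genes: int,
    hidden_widths: tuple[int, int] = (64, 64),
    rng_seed: int = 0,
    gene_names: list[str] | None = None,
    lam: float = 1.0,
    dt: float = 1.0,
    clamped_genes: frozenset[int] = frozenset(),
) -> SynthesisModel:
    """Initialise the four-layer network (input, two ReLU hidden, sigmoid out)."""
    if n_genes < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(rng_seed)
    params = _init_params(n_genes, hidden_widths, n_genes, rng)
    return SynthesisModel(
        gene_names=gene_names or [f"G{i + 1}" for i in range(n_genes)],
        params=params,
        hidden_widths=tuple(hidden_widths),
        lam=lam,
        dt=dt,
        clamped_genes=frozenset(clamped_genes),
        seed=int(rng_seed),
    )


# ---------------------------------------------------------------------------
# Prediction / training
# ---------------------------------------------------------------------------

def one_step_predict(
    model, g_t: np.ndarray, clamped_next: np.ndarray | None = None
) -> np.ndarray:
    """Euler step g_hat(t+dt) = g + (f(g) - lam*g)*dt.

    Works for a single state or a batch. Clamped genes are copied from
    ``clamped_next`` (their imposed next values) or, failing that, from the
    current state — they are never predicted.
    """
    g = np.asarray(g_t, dtype=float)
    f = model.synthesis(g)
    pred = g + (f - model.lam * g) * model.dt
    for i in model.clamped_genes:
        pred[..., i] = g[..., i] if clamped_next is None else np.asarray(clamped_next)[..., i]
    return pred


def _training_pairs(series: Sequence[ExpressionTimeSeries]):
    """Stack consecutive (state, next state) pairs; none span series bounds.

    Also returns a per-pair target weight matrix that zeroes genes clamped
    in their series (held genes are inputs there, never prediction targets).
    """
    X, Y, W = [], [], []
    for ts in series:
        X.append(ts.values[:, :-1].T)
        Y.append(ts.values[:, 1:].T)
        w = np.ones(ts.n_genes)
        w[list(ts.clamped_genes)] = 0.0
        W.append(np.tile(w, (ts.n_times - 1, 1)))
    return np.concatenate(X), np.concatenate(Y), np.concatenate(W)


def train(
    model: SynthesisModel,
    series: ExpressionTimeSeries | Sequence[ExpressionTimeSeries],
    epochs: int = 2000,
    learning_rate: float = 1e-3,
    rng_seed: int = 0,
) -> tuple[SynthesisModel, TrainingReport]:
    """Fit the network by full-batch Adam on the one-step Euler loss.

    Expects series already normalized to [0,1]. Honours the model's
    ``input_mask`` (used when retraining after permanent link knockouts).
    Returns a new model; the input model is left untouched. If the loss ever
    turns non-finite, training aborts at the last finite-loss parameters.

    ``losses[k]`` in the report is the loss evaluated with the parameters
    entering epoch k (so the full-batch gradient and the recorded loss refer
    to the same parameters).
    """
    if isinstance(series, ExpressionTimeSeries):
        series = [series]
    series = list(series)
    if any(ts.n_times < 2 for ts in series):
        raise ValueError("every series needs at least two timepoints")
    model = model.copy()
    dt_set = {round(ts.dt, 12) for ts in series}
    if len(dt_set) > 1:
        raise ValueError("all series must share the same grid spacing")
    model.dt = float(series[0].dt)
    X, Y, Wt = _training_pairs(series)
    G = model.n_genes
    for j in model.clamped_genes:
        Wt[:, j] = 0.0
    sel = np.array([j for j in range(G) if j not in model.clamped_genes], dtype=int)
    groups = _mask_groups(model.input_mask, G)

    params = model.params
    mstate = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    vstate = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    dt, lam = model.dt, model.lam
    losses = np.empty(int(epochs))
    checkpoint = [(W.copy(), b.copy()) for W, b in params]
    n_done = 0

    sel_mask = np.zeros(G)
    sel_mask[sel] = 1.0

    for epoch in range(int(epochs)):
        grads = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        sse = 0.0
        for v, targets in groups:
            tsel = targets[np.isin(targets, sel)]
            if tsel.size == 0:
                continue
            Xg = X if v is None else X * v
            F, acts = _forward(params, Xg)
            pred = X + (F - lam * X) * dt
            resid = np.zeros_like(F)
            resid[:, tsel] = (pred[:, tsel] - Y[:, tsel]) * Wt[:, tsel]
            sse += float((resid[:, tsel] ** 2).sum())
            dF = 2.0 * resid * dt
            for k, (gW, gb) in enumerate(_backward(params, acts, dF)):
                grads[k] = (grads[k][0] + gW, grads[k][1] + gb)
        loss = float(np.sqrt(sse))
        if not np.isfinite(loss):
            losses = losses[:n_done]
            params = checkpoint
            break
        checkpoint = [(W.copy(), b.copy()) for W, b in params]
        t = epoch + 1
        new_params: Params = []
        for k, (W, b) in enumerate(params):
            upd = []
            for val, grad, m, vv in (
                (W, grads[k][0], mstate[k][0], vstate[k][0]),
                (b, grads[k][1], mstate[k][1], vstate[k][1]),
            ):
                m[:] = beta1 * m + (1 - beta1) * grad
                vv[:] = beta2 * vv + (1 - beta2) * grad**2
                mhat = m / (1 - beta1**t)
                vhat = vv / (1 - beta2**t)
                upd.append(val - learning_rate * mhat / (np.sqrt(vhat) + eps))
            new_params.append((upd[0], upd[1]))
        params = new_params
        losses[n_done] = loss
        n_done += 1
    model.params = params
    return model, TrainingReport(
        losses=losses[:n_done].copy(),
        seed=int(rng_seed),
        epochs=int(epochs),
        learning_rate=float(learning_rate),
    )


def fit_dynamics(
    series: ExpressionTimeSeries | Sequence[ExpressionTimeSeries],
    hidden_widths: tuple[int, int] = (64, 64),
    epochs: int = 2000,
    learning_rate: float = 1e-3,
    rng_seed: int = 0,
    lam: float = 1.0,
) -> tuple[SynthesisModel, TrainingReport, list[ExpressionTimeSeries]]:
    """Normalize raw series, build and train a model.

    Convenience wrapper used by the CLI and the inference pipeline. Returns
    the trained model (carrying the scaler), the report, and the normalized
    series it was trained on.
    """
    if isinstance(series, ExpressionTimeSeries):
        series = [series]
    series = list(series)
    scaler = fit_scaler(series)
    scaled = [scaler.transform_series(ts) for ts in series]
    model = build_synthesis_model(
        scaled[0].n_genes,
        hidden_widths,
        rng_seed=rng_seed,
        gene_names=scaled[0].gene_names,
        lam=lam,
        dt=scaled[0].dt,
        clamped_genes=scaled[0].clamped_genes,
    )
    model.scaler = scaler
    model, report = train(
        model, scaled, epochs=epochs, learning_rate=learning_rate, rng_seed=rng_seed
    )
    return model, report, scaled


# ---------------------------------------------------------------------------
# Inspection helpers
# ---------------------------------------------------------------------------

def cross_section(
    model,
    target_gene: int | str,
    varied_gene: int | str,
    grid: np.ndarray,
    fixed_state: np.ndarray,
) -> np.ndarray:
    """f_target along a 1-D sweep of one input, the rest held fixed.

    The direct readout of the regulation logic the network has learned
    (rising curve = activation, falling = inhibition).
    """
    names = list(model.gene_names)

    def idx(g):
        if isinstance(g, str):
            if g not in names:
                raise KeyError(f"unknown gene {g!r}")
            return names.index(g)
        return int(g)

    jt, jv = idx(target_gene), idx(varied_gene)
    grid = np.asarray(grid, dtype=float)
    X = np.tile(np.asarray(fixed_state, dtype=float), (grid.size, 1))
    X[:, jv] = grid
    return model.synthesis(X)[:, jt]


def rollout(
    model,
    g0: np.ndarray,
    n_steps: int,
    inputs: dict[int, np.ndarray] | None = None,
) -> ExpressionTimeSeries:
    """Iterate one-step predictions into a trajectory (normalized space).

    ``inputs`` maps each clamped gene to its imposed values, one per step
    (length ``n_steps + 1`` including the initial time).
    """
    inputs = inputs or {}
    g = np.asarray(g0, dtype=float).copy()
    for i in model.clamped_genes:
        if i not in inputs:
            raise ValueError(f"clamped gene {i} needs an input trajectory")
        g[i] = inputs[i][0]
    out = [g.copy()]
    for step in range(1, n_steps + 1):
        f = model.synthesis(g)
        g = g + (f - model.lam * g) * model.dt
        np.clip(g, 0.0, None, out=g)
        for i, vals in inputs.items():
            g[i] = vals[step]
        out.append(g.copy())
    times = np.arange(n_steps + 1) * model.dt
    return ExpressionTimeSeries(
        list(model.gene_names), times, np.asarray(out).T, model.clamped_genes
    )


class HillSynthesisOracle:
    """A Hill model exposed through the SynthesisModel evaluation interface.

    Used wherever the closed-form ground truth should stand in for a trained
    network (sign-recovery checks, cross-section oracles, mutant rollouts).
    If a scaler is given, states are taken in normalized units and the
    returned synthesis rate is expressed in the same normalized ODE,
    f_norm = (f_raw(x) - lam * gmin) / span, so rollouts are comparable.
    """

    def __init__(self, hill_model, scaler: GeneScaler | None = None):
        self.hill = hill_model
        self.scaler = scaler
        self.gene_names = list(hill_model.gene_names)
        self.clamped_genes = hill_model.clamped_genes
        self.lam = hill_model.lam
        self.dt = 1.0
        self.input_mask: np.ndarray | None = None
        self.self_persistence = 0.0  # closed-form synthesis rate, no flow memory

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def with_mask(self, input_mask: np.ndarray) -> "HillSynthesisOracle":
        o = HillSynthesisOracle(self.hill, self.scaler)
        o.dt = self.dt
        o.input_mask = np.asarray(input_mask, dtype=float)
        return o

    def copy(self) -> "HillSynthesisOracle":
        o = HillSynthesisOracle(self.hill, self.scaler)
        o.dt = self.dt
        o.input_mask = None if self.input_mask is None else self.input_mask.copy()
        return o

    def synthesis(self, states: np.ndarray) -> np.ndarray:
        X = np.asarray(states, dtype=float)
        if self.scaler is not None:
            raw = np.clip(self.scaler.inverse_states(X), 0.0, None)
        else:
            raw = X
        f = (
            self.hill.synthesis(raw)
            if self.input_mask is None
            else self.hill.synthesis_masked(raw, self.input_mask)
        )
        if self.scaler is not None:
            f = (f - self.lam * self.scaler.gmin) / self.scaler.span
        return f
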