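"""Hill-function ODE ground truth for gene regulatory circuits.

The synthesis rate of gene *i* is a product of saturating regulatory terms

    f_i(g) = ( sum_j  b_ij * g_j^n / (K_ij^n + g_j^n) )      activation
             * prod_l K_il^n / (K_il^n + g_l^n)              inhibition

and every non-clamped gene follows dg_i/dt = f_i(g) - lambda * g_i. A gene
with no activators has f_i = 0 (empty sum); a gene with no inhibitors gets an
inhibition product of 1. Clamped genes (input signals) follow imposed
trajectories and are neither synthesised nor degraded.

The module also houses the adaptation screen used to decide whether a network
topology can adapt: sample all Hill parameters from the unit-rate exponential,
step the clamped input, and require a response peak that returns close to the
pre-stimulus level.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Mapping

import numpy as np

from .timeseries import ExpressionTimeSeries

__all__ = [
    "IntegrationError",
    "HillModel",
    "AdaptationMetrics",
    "AdaptationScreen",
    "hill_activation",
    "hill_inhibition",
    "synthesis_rate",
    "simulate",
    "sample_hill_parameters",
    "score_adaptation",
    "topology_success_count",
]


class IntegrationError(RuntimeError):
    """Raised when the forward-Euler state stops being finite."""


# ---------------------------------------------------------------------------
# Elementary Hill terms
# ---------------------------------------------------------------------------

def hill_activation(g, b, K, n: int = 2):
    """Activating Hill term b * g^n / (K^n + g^n).

    Monotone non-decreasing in ``g``, bounded by ``b``. Accepts scalars or
    arrays (broadcast).
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("regulator concentration must be non-negative")
    if np.any(np.asarray(b, dtype=float) <= 0) or np.any(np.asarray(K, dtype=float) <= 0):
        raise ValueError("b and K must be positive")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    gn = g**n
    out = b * gn / (np.asarray(K, dtype=float) ** n + gn)
    return float(out) if out.ndim == 0 else out


def hill_inhibition(g, K, n: int = 2):
    """Inhibitory Hill factor K^n / (K^n + g^n) in (0, 1]."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("regulator concentration must be non-negative")
    if np.any(np.asarray(K, dtype=float) <= 0):
        raise ValueError("K must be positive")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    Kn = np.asarray(K, dtype=float) ** n
    out = Kn / (Kn + g**n)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HillModel:
    """A Hill-kinetics gene circuit.

    ``adjacency[i, j]`` is the sign of the regulatory edge i -> j (+1
    activation, -1 inhibition, 0 absent). ``b`` and ``K`` are dense matrices
    indexed the same way; entries off the respective masks are ignored.
    """

    gene_names: list[str]
    adjacency: np.ndarray
    b: np.ndarray
    K: np.ndarray
    n: int = 2
    lam: float = 1.0
    clamped_genes: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.gene_names = list(self.gene_names)
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        G = len(self.gene_names)
        if self.adjacency.shape != (G, G):
            raise ValueError("adjacency must be square over the gene set")
        if not np.all(np.isin(self.adjacency, (-1, 0, 1))):
            raise ValueError("adjacency entries must be -1, 0 or +1")
        self.b = np.asarray(self.b, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.b.shape != (G, G) or self.K.shape != (G, G):
            raise ValueError("b and K must match the adjacency shape")
        act = self.adjacency == 1
        nz = self.adjacency != 0
        if np.any(self.b[act] <= 0):
            raise ValueError("activation b must be positive")
        if np.any(self.K[nz] <= 0):
            raise ValueError("K must be positive on every edge")
        if int(self.n) < 1:
            raise ValueError("Hill coefficient must be >= 1")
        if self.lam < 0:
            raise ValueError("degradation rate must be >= 0")
        self.n = int(self.n)
        self.clamped_genes = frozenset(int(i) for i in self.clamped_genes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def edges(self) -> list[tuple[int, int, int]]:
        """Nonzero edges as (regulator, target, sign), row-major order."""
        regs, tgts = np.nonzero(self.adjacency)
        return [(int(i), int(j), int(self.adjacency[i, j])) for i, j in zip(regs, tgts)]

    # -- synthesis ----------------------------------------------------------

    def synthesis(self, states: np.ndarray) -> np.ndarray:
        """Per-gene synthesis rates for a batch of states ``(..., n_genes)``."""
        return synthesis_rate(self, states)

    def synthesis_masked(self, states: np.ndarray, input_mask: np.ndarray) -> np.ndarray:
        """Synthesis with per-edge input discounting.

        ``input_mask[i, j]`` multiplies regulator i's level wherever it enters
        target j's synthesis term (1 = intact, 0 = full link knockout).
        """
        return synthesis_rate(self, states, input_mask=input_mask)


def synthesis_rate(
    model: HillModel, states: np.ndarray, input_mask: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate f for one state ``(G,)`` or a batch ``(m, G)``."""
    x = np.asarray(states, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    G = model.n_genes
    if x.shape[1] != G:
        raise ValueError(f"state has {x.shape[1]} genes, model has {G}")
    if np.any(x < 0):
        raise ValueError("expression state must be non-negative")

    act = model.adjacency == 1
    inh = model.adjacency == -1
    Kn = np.where(model.adjacency != 0, model.K, 1.0) ** model.n
    if input_mask is None:
        gn = x**model.n  # (m, G)
        gn_ij = gn[:, :, None]  # regulator axis broadcast over targets
    else:
        input_mask = np.asarray(input_mask, dtype=float)
        if input_mask.shape != (G, G):
            raise ValueError("input_mask must be n_genes x n_genes")
        gn_ij = (x[:, :, None] * input_mask[None, :, :]) ** model.n

    act_terms = np.where(act, model.b, 0.0)[None] * gn_ij / (Kn[None] + gn_ij)
    f = np.where(act[None], act_terms, 0.0).sum(axis=1)
    inh_factors = np.where(inh[None], Kn[None] / (Kn[None] + gn_ij), 1.0)
    f = f * inh_factors.prod(axis=1)
    return f[0] if single else f


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

InputFn = Callable[[float], float]


def simulate(
    model: HillModel,
    initial_state: np.ndarray,
    t_end: float,
    dt_int: float = 0.01,
    inputs: Mapping[int, InputFn] | None = None,
    sample_dt: float | None = None,
    input_mask: np.ndarray | None = None,
) -> ExpressionTimeSeries:
    """Forward-Euler integration of dg/dt = f(g) - lambda*g.

    Non-clamped genes update by ``g += (f(g) - lam*g) * dt_int`` and are
    clipped at zero (concentrations cannot go negative). Clamped genes follow
    the callables in ``inputs`` exactly. Output is sub-sampled on the grid of
    spacing ``sample_dt`` (default ``dt_int``).
    """
    if dt_int <= 0:
        raise ValueError("dt_int must be positive")
    sample_dt = dt_int if sample_dt is None else sample_dt
    stride = int(round(sample_dt / dt_int))
    if stride < 1 or abs(stride * dt_int - sample_dt) > 1e-9 * max(sample_dt, 1.0):
        raise ValueError("sample_dt must be a positive multiple of dt_int")
    inputs = dict(inputs or {})
    missing = model.clamped_genes - set(inputs)
    if missing:
        raise ValueError(f"clamped genes {sorted(missing)} need input trajectories")

    g = np.asarray(initial_state, dtype=float).copy()
    if g.shape != (model.n_genes,):
        raise ValueError("initial state has wrong length")
    if np.any(g < 0):
        raise ValueError("initial state must be non-negative")
    free = np.array(
        [i for i in range(model.n_genes) if i not in model.clamped_genes], dtype=int
    )

    n_steps = int(round(t_end / dt_int))
    for i, fn in inputs.items():
        g[i] = fn(0.0)
    samples = [g.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        f = (
            model.synthesis(g)
            if input_mask is None
            else model.synthesis_masked(g, input_mask)
        )
        g[free] = g[free] + (f[free] - model.lam * g[free]) * dt_int
        np.clip(g, 0.0, None, out=g)
        t = step * dt_int
        for i, fn in inputs.items():
            g[i] = fn(t)
        if not np.all(np.isfinite(g)):
            bad = int(np.flatnonzero(~np.isfinite(g))[0])
            raise IntegrationError(
                f"non-finite state for gene {model.gene_names[bad]} at step {step} (t={t:g})"
            )
        if step % stride == 0:
            samples.append(g.copy())
            times.append(t)
    return ExpressionTimeSeries(
        model.gene_names,
        np.asarray(times),
        np.asarray(samples).T,
        model.clamped_genes,
    )


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def sample_hill_parameters(
    topology: np.ndarray,
    n: int = 2,
    lam: float = 1.0,
    rng_seed: int | np.random.Generator = 0,
    gene_names: list[str] | None = None,
    clamped_genes: frozenset[int] = frozenset(),
) -> HillModel:
    """Draw every b and K i.i.d. from the unit-rate exponential p(x)=e^-x.

    Parameters are drawn edge by edge in row-major (regulator, target) order,
    b before K on activating edges, so a fixed seed reproduces the model.
    """
    topology = np.asarray(topology, dtype=int)
    G = topology.shape[0]
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    b = np.ones((G, G))
    K = np.ones((G, G))
    for i, j in np.argwhere(topology != 0):
        if topology[i, j] == 1:
            b[i, j] = rng.exponential()
        K[i, j] = rng.exponential()
    names = gene_names or [f"G{i + 1}" for i in range(G)]
    return HillModel(names, topology, b, K, n=n, lam=lam, clamped_genes=clamped_genes)


# ---------------------------------------------------------------------------
# Adaptation scoring
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AdaptationMetrics:
    """Step-response summary of an output gene.

    ``sensitivity`` is the peak absolute excursion from the pre-stimulus
    baseline; ``adaptation_error`` the residual offset between the fully
    adapted (end-of-horizon) level and the baseline. Perfect adaptation means
    a large sensitivity with near-zero adaptation error.
    """

    baseline: float
    sensitivity: float
    adaptation_error: float
    peak_time: float
    settled: bool = True


def score_adaptation(
    ts: ExpressionTimeSeries,
    output_gene: int | str,
    stimulus_time: float,
    settle_window: float = 0.1,
    settle_tol: float = 1e-3,
) -> AdaptationMetrics:
    """Score the step response of ``output_gene``.

    The baseline is the output level at the last sample at or before
    ``stimulus_time``; sensitivity and adaptation error are measured over the
    samples after it. If the trajectory still drifts by more than
    ``settle_tol`` over the final ``settle_window`` fraction of the horizon,
    the result is flagged as unsettled rather than rejected.
    """
    j = ts.gene_index(output_gene)
    if not ts.times[0] <= stimulus_time <= ts.times[-1]:
        raise ValueError("stimulus_time outside the time grid")
    trace = ts.values[j]
    pre = np.flatnonzero(ts.times <= stimulus_time + 1e-12)
    baseline = float(trace[pre[-1]])
    post = trace[pre[-1] :]
    post_times = ts.times[pre[-1] :]
    dev = np.abs(post - baseline)
    k = int(np.argmax(dev))
    tail = trace[ts.times >= ts.times[-1] - settle_window * (ts.times[-1] - ts.times[0])]
    settled = bool(tail.size < 2 or np.ptp(tail) < settle_tol)
    return AdaptationMetrics(
        baseline=baseline,
        sensitivity=float(dev[k]),
        adaptation_error=float(abs(post[-1] - baseline)),
        peak_time=float(post_times[k]),
        settled=settled,
    )


@dataclasses.dataclass
class AdaptationScreen:
    """Protocol and thresholds for the step-response adaptation screen.

    The clamped input gene is held at ``baseline`` for ``t_pre`` time units
    (to reach the pre-stimulus steady state), then stepped up by ``step`` for
    ``t_post``. A parameter set passes when the output peak is at least
    ``min_sensitivity_frac * |step|`` and the residual offset at the end of
    the horizon is at most ``max_error_frac`` of the peak.
    """

    input_gene: int = 0
    output_gene: int = 2
    baseline: float = 0.5
    step: float = 1.0
    t_pre: float = 10.0
    t_post: float = 30.0
    dt: float = 0.01
    min_sensitivity_frac: float = 0.2
    max_error_frac: float = 0.1

    def passes(self, sensitivity: float, adaptation_error: float) -> bool:
        return (
            sensitivity >= self.min_sensitivity_frac * abs(self.step)
            and adaptation_error <= self.max_error_frac * sensitivity
        )


def topology_success_count(
    topology: np.ndarray,
    n_samples: int,
    screen: AdaptationScreen | None = None,
    rng_seed: int = 0,
    n: int = 2,
    lam: float = 1.0,
    batch_size: int = 100_000,
) -> int:
    """Count exponential parameter draws under which a topology adapts.

    For each of ``n_samples`` parameter sets (every b and K i.i.d. unit-rate
    exponential) the step response of the clamped-input circuit is
    Euler-integrated, vectorised across parameter sets, and the screen
    applied. A topology is conventionally called successful when at least two
    sets pass.
    """
    screen = screen or AdaptationScreen()
    topology = np.asarray(topology, dtype=int)
    G = topology.shape[0]
    edges = [(int(i), int(j), int(topology[i, j])) for i, j in np.argwhere(topology != 0)]
    rng = np.random.default_rng(rng_seed)
    total = 0
    remaining = int(n_samples)
    while remaining > 0:
        m = min(batch_size, remaining)
        remaining -= m
        # draw in the same canonical order as sample_hill_parameters
        b_e: dict[tuple[int, int], np.ndarray] = {}
        Kn_e: dict[tuple[int, int], np.ndarray] = {}
        for i, j, s in edges:
            if s == 1:
                b_e[(i, j)] = rng.exponential(size=m)
            Kn_e[(i, j)] = rng.exponential(size=m) ** n
        total += int(_screen_batch(G, edges, b_e, Kn_e, n, lam, screen, m).sum())
    return total


def _screen_batch(G, edges, b_e, Kn_e, n, lam, screen, m) -> np.ndarray:
    """Vectorised Euler step response for m parameter sets; returns pass mask."""
    by_target: dict[int, list[tuple[int, int]]] = {}
    for i, j, s in edges:
        by_target.setdefault(j, []).append((i, s))
    free = [j for j in range(G) if j != screen.input_gene]

    g = [np.zeros(m) for _ in range(G)]
    g[screen.input_gene] = np.full(m, screen.baseline)
    dt = screen.dt

    def euler(n_steps: int, track: bool, baseline: np.ndarray | None):
        peak = np.zeros(m)
        gn_cache: dict[int, np.ndarray] = {}
        for _ in range(n_steps):
            gn_cache.clear()

            def gn(i: int) -> np.ndarray:
                if i not in gn_cache:
                    gn_cache[i] = g[i] ** n
                return gn_cache[i]

            new = {}
            for j in free:
                f = np.zeros(m)
                prod = None
                for i, s in by_target.get(j, ()):
                    t = gn(i)
                    if s == 1:
                        f = f + b_e[(i, j)] * t / (Kn_e[(i, j)] + t)
                    else:
                        factor = Kn_e[(i, j)] / (Kn_e[(i, j)] + t)
                        prod = factor if prod is None else prod * factor
                if prod is not None:
                    f = f * prod
                new[j] = np.maximum(g[j] + (f - lam * g[j]) * dt, 0.0)
            for j in free:
                g[j] = new[j]
            if track:
                np.maximum(peak, np.abs(g[screen.output_gene] - baseline), out=peak)
        return peak

    euler(int(round(screen.t_pre / dt)), track=False, baseline=None)
    baseline = g[screen.output_gene].copy()
    g[screen.input_gene] = np.full(m, screen.baseline + screen.step)
    peak = euler(int(round(screen.t_post / dt)), track=True, baseline=baseline)
    err = np.abs(g[screen.output_gene] - baseline)
    return (peak >= screen.min_sensitivity_frac * abs(screen.step)) & (
        err <= screen.max_error_frac * peak
    )
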