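"""Containers for gene expression time courses.

The whole package works on one in-memory shape: an :class:`ExpressionTimeSeries`
holding a genes x timepoints matrix of non-negative expression levels on a
uniform time grid, plus the indices of genes whose trajectories are externally
imposed (clamped input signals, e.g. a morphogen gradient).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable

import numpy as np

__all__ = ["ExpressionTimeSeries", "GeneScaler", "fit_scaler"]


@dataclasses.dataclass
class ExpressionTimeSeries:
    """A genes x timepoints expression matrix on a uniform time grid.

    Parameters
    ----------
    gene_names
        One name per row of ``values``; order is shared by every module.
    times
        Strictly increasing, uniformly spaced sample times.
    values
        Array of shape ``(n_genes, n_times)``; finite and non-negative.
    clamped_genes
        Indices of genes whose trajectories are imposed from outside the
        system (input signals). They are fed to models as inputs but never
        predicted or degraded.
    """

    gene_names: list[str]
    times: np.ndarray
    values: np.ndarray
    clamped_genes: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.gene_names = list(self.gene_names)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need a 1-D grid with at least two timepoints")
        if self.values.shape != (len(self.gene_names), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_names)} genes x {self.times.size} timepoints"
            )
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("times must be uniformly spaced (rtol 1e-9)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        self.clamped_genes = frozenset(int(i) for i in self.clamped_genes)
        for i in self.clamped_genes:
            if not 0 <= i < len(self.gene_names):
                raise ValueError(f"clamped gene index {i} out of range")

    # -- basic introspection -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        """Grid spacing (time units)."""
        return float(self.times[1] - self.times[0])

    def gene_index(self, gene: int | str) -> int:
        if isinstance(gene, str):
            try:
                return self.gene_names.index(gene)
            except ValueError:
                raise KeyError(f"unknown gene {gene!r}") from None
        i = int(gene)
        if not 0 <= i < self.n_genes:
            raise KeyError(f"gene index {i} out of range")
        return i

    def copy(self) -> "ExpressionTimeSeries":
        return ExpressionTimeSeries(
            list(self.gene_names),
            self.times.copy(),
            self.values.copy(),
            self.clamped_genes,
        )


@dataclasses.dataclass
class GeneScaler:
    """Per-gene min-max affine scaling to [0, 1].

    Constant genes are mapped to 0 by guarding the span at ``eps``.
    """

    gmin: np.ndarray
    gmax: np.ndarray
    eps: float = 1e-12

    @property
    def span(self) -> np.ndarray:
        return np.maximum(self.gmax - self.gmin, self.eps)

    def transform_states(self, states: np.ndarray) -> np.ndarray:
        """Scale states of shape ``(..., n_genes)``."""
        return (np.asarray(states, dtype=float) - self.gmin) / self.span

    def inverse_states(self, states: np.ndarray) -> np.ndarray:
        return np.asarray(states, dtype=float) * self.span + self.gmin

    def transform_series(self, ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
        scaled = (ts.values - self.gmin[:, None]) / self.span[:, None]
        return ExpressionTimeSeries(
            ts.gene_names, ts.times, np.clip(scaled, 0.0, None), ts.clamped_genes
        )

    def inverse_series(self, ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
        raw = ts.values * self.span[:, None] + self.gmin[:, None]
        return ExpressionTimeSeries(
            ts.gene_names, ts.times, np.clip(raw, 0.0, None), ts.clamped_genes
        )


def fit_scaler(series: ExpressionTimeSeries | Iterable[ExpressionTimeSeries]) -> GeneScaler:
    """Fit a per-gene min-max scaler over one or several series."""
    if isinstance(series, ExpressionTimeSeries):
        series = [series]
    series = list(series)
    if not series:
        raise ValueError("no series given")
    names = series[0].gene_names
    for ts in series[1:]:
        if ts.gene_names != names:
            raise ValueError("all series must share the same gene order")
    stacked = np.concatenate([ts.values for ts in series], axis=1)
    return GeneScaler(stacked.min(axis=1), stacked.max(axis=1))
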