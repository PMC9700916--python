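"""Benchmark-style scoring of predicted edge lists against a gold standard.

Follows the DREAM convention: the candidate universe is every ordered
(TF, gene) pair excluding self-edges; predictions are ranked by weight,
binarized at top-k for the confusion metrics, and scored threshold-free with
AUROC / AUPR. Candidate pairs the prediction omits count as weight 0.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "GoldStandard",
    "MetricReport",
    "top_k_binarize",
    "confusion_metrics",
    "auroc_aupr",
    "network_density",
]


@dataclasses.dataclass
class GoldStandard:
    """True edges over a TF x gene candidate universe (self-edges excluded)."""

    gene_names: list[str]
    tf_names: list[str]
    edges: set[tuple[str, str]]
    exclude_self: bool = True

    def __post_init__(self) -> None:
        genes = set(self.gene_names)
        tfs = set(self.tf_names)
        if not tfs <= genes:
            raise ValueError("TFs must be a subset of the gene set")
        for reg, tgt in self.edges:
            if reg not in tfs:
                raise ValueError(f"gold edge regulator {reg!r} is not a TF")
            if tgt not in genes:
                raise ValueError(f"gold edge target {tgt!r} is not a known gene")
            if self.exclude_self and reg == tgt:
                raise ValueError(f"self-edge {reg!r} not allowed in this gold standard")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def candidate_pairs(self) -> list[tuple[str, str]]:
        return [
            (reg, tgt)
            for reg in self.tf_names
            for tgt in self.gene_names
            if not (self.exclude_self and reg == tgt)
        ]

    def density(self) -> float:
        return network_density(len(self.gene_names), len(self.tf_names), self.n_edges)


@dataclasses.dataclass
class MetricReport:
    tpr: float
    fpr: float
    mcc: float
    acc: float
    f1: float
    k: int | None = None
    auroc: float | None = None
    aupr: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


Prediction = tuple[str, str, float]


def top_k_binarize(
    predictions: Sequence[Prediction], k: int
) -> set[tuple[str, str]]:
    """The k highest-weighted pairs, ties broken by (weight desc, reg, tgt)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ranked = sorted(predictions, key=lambda p: (-p[2], p[0], p[1]))
    return {(reg, tgt) for reg, tgt, _ in ranked[: int(k)]}


def _restrict(pred_pairs: Iterable[tuple[str, str]], gold: GoldStandard):
    candidates = gold.candidate_pairs()
    cand_set = set(candidates)
    pred = set(pred_pairs)
    offenders = sorted(pred - cand_set)
    if offenders:
        raise ValueError(
            f"{len(offenders)} predicted pairs outside the candidate universe, "
            f"e.g. {offenders[:5]}"
        )
    return candidates, pred


def confusion_metrics(
    pred_edges: Iterable[tuple[str, str]], gold: GoldStandard
) -> MetricReport:
    """TPR, FPR, MCC, ACC and F1 from the 2x2 table over candidate pairs.

    MCC is defined as 0 whenever a marginal of the table is zero.
    """
    candidates, pred = _restrict(pred_edges, gold)
    tp = fp = fn = tn = 0
    for pair in candidates:
        p, t = pair in pred, pair in gold.edges
        if p and t:
            tp += 1
        elif p:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    acc = (tp + tn) / max(len(candidates), 1)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricReport(tpr=tpr, fpr=fpr, mcc=float(mcc), acc=acc, f1=f1)


def auroc_aupr(
    predictions: Sequence[Prediction], gold: GoldStandard
) -> tuple[float, float]:
    """Threshold-free ranking quality over the full candidate universe.

    AUROC uses the trapezoidal, tie-aware (Mann-Whitney) convention; AUPR is
    the step-wise precision-recall integral (average precision). Candidate
    pairs missing from the prediction are appended with weight 0.
    """
    weights = {}
    for reg, tgt, w in predictions:
        if (reg, tgt) in weights:
            raise ValueError(f"duplicate prediction for pair ({reg}, {tgt})")
        if not np.isfinite(w):
            raise ValueError(f"non-finite weight for pair ({reg}, {tgt})")
        weights[(reg, tgt)] = float(w)
    candidates, _ = _restrict(weights.keys(), gold)
    y = np.array([pair in gold.edges for pair in candidates], dtype=int)
    s = np.array([weights.get(pair, 0.0) for pair in candidates])
    if y.sum() == 0:
        raise ValueError("gold standard has no positive edges; AUROC/AUPR undefined")
    if y.sum() == y.size:
        return 1.0, 1.0
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def network_density(n_genes: int, n_tfs: int, n_edges: int) -> float:
    """Edge density n_edges / (n_genes * n_tfs), reported to 4 decimals."""
    if n_genes <= 0 or n_tfs <= 0:
        raise ValueError("gene and TF counts must be positive")
    if n_edges < 0:
        raise ValueError("edge count must be non-negative")
    return round(n_edges / (n_genes * n_tfs), 4)
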