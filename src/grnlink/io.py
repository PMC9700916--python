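"""Readers and writers for the tab-delimited interchange formats.

Time series use the GeneNetWeaver/DREAM dialect: a header line starting with
"Time" followed by one column per gene, with blank lines separating multiple
perturbation series. Gold standards and predictions are flat edge lists.
All files are UTF-8 text with LF endings.
"""

from __future__ import annotations

import json
from pathlib import Path
from collections.abc import Sequence

import numpy as np

from .evaluation import GoldStandard
from .hill import HillModel
from .knockout import RegulatoryNetwork
from .nn import SynthesisModel
from .timeseries import ExpressionTimeSeries, GeneScaler

__all__ = [
    "ParseError",
    "read_timeseries",
    "write_timeseries",
    "read_gold",
    "write_gold",
    "read_predictions",
    "write_predictions",
    "write_network",
    "read_topology",
    "write_topology",
    "read_hill_model",
    "write_hill_model",
    "save_model",
    "load_model",
]


class ParseError(ValueError):
    def __init__(self, path, lineno: int | None, message: str):
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def read_timeseries(
    path, clamped_genes: Sequence[int] = ()
) -> list[ExpressionTimeSeries]:
    """Parse a (possibly multi-series) GeneNetWeaver-style TSV file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header: list[str] | None = None
    blocks: list[list[tuple[int, list[str]]]] = []
    current: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0].strip().lower() == "time":
            if header is None:
                header = [f.strip() for f in fields[1:]]
            elif [f.strip() for f in fields[1:]] != header:
                raise ParseError(path, lineno, "inconsistent repeated header")
            continue
        current.append((lineno, fields))
    if current:
        blocks.append(current)
    if header is None:
        raise ParseError(path, 1, 'missing header line starting with "Time"')
    if not blocks:
        raise ParseError(path, None, "no data rows")

    out = []
    for block in blocks:
        times, rows = [], []
        for lineno, fields in block:
            if len(fields) != len(header) + 1:
                raise ParseError(
                    path, lineno, f"expected {len(header) + 1} columns, got {len(fields)}"
                )
            try:
                vals = [float(f) for f in fields]
            except ValueError:
                raise ParseError(path, lineno, "non-numeric field") from None
            if any(v < 0 for v in vals[1:]):
                raise ParseError(path, lineno, "negative expression value")
            times.append(vals[0])
            rows.append(vals[1:])
        times_arr = np.asarray(times)
        if np.any(np.diff(times_arr) <= 0):
            raise ParseError(path, block[0][0], "times must be strictly increasing")
        out.append(
            ExpressionTimeSeries(
                header, times_arr, np.asarray(rows).T, frozenset(clamped_genes)
            )
        )
    return out


def write_timeseries(path, series: ExpressionTimeSeries | Sequence[ExpressionTimeSeries]) -> None:
    if isinstance(series, ExpressionTimeSeries):
        series = [series]
    series = list(series)
    lines = ["\t".join(["Time", *series[0].gene_names])]
    for idx, ts in enumerate(series):
        if ts.gene_names != series[0].gene_names:
            raise ValueError("all series must share the same gene order")
        if idx:
            lines.append("")
        for k in range(ts.n_times):
            row = [ts.times[k], *ts.values[:, k]]
            lines.append("\t".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_gold(path, gene_names=None, tf_names=None) -> GoldStandard:
    """Read a DREAM-style gold standard: "regulator TAB target TAB {0,1}".

    If gene or TF lists are not given they are inferred from the file (TFs =
    all regulators that appear; genes = everything mentioned, naturally
    sorted).
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    seen: set[tuple[str, str]] = set()
    regs, names = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
        reg, tgt, flag = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if flag not in ("0", "1"):
            raise ParseError(path, lineno, f"label must be 0 or 1, got {flag!r}")
        if (reg, tgt) in seen:
            raise ParseError(path, lineno, f"duplicate edge ({reg}, {tgt})")
        seen.add((reg, tgt))
        regs.append(reg)
        names.extend((reg, tgt))
        if flag == "1":
            edges.add((reg, tgt))

    def natural(n: str):
        digits = "".join(c for c in n if c.isdigit())
        return (len(n), int(digits)) if digits else (0, 0), n

    if gene_names is None:
        gene_names = sorted(set(names), key=natural)
    if tf_names is None:
        tf_names = [g for g in gene_names if g in set(regs)] or list(gene_names)
    return GoldStandard(list(gene_names), list(tf_names), edges)


def write_gold(path, gold: GoldStandard) -> None:
    lines = [
        f"{reg}\t{tgt}\t{1 if (reg, tgt) in gold.edges else 0}"
        for reg, tgt in gold.candidate_pairs()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_predictions(path, predictions: Sequence[tuple[str, str, float]]) -> None:
    """Ranked prediction list "regulator TAB target TAB weight", best first."""
    ranked = sorted(predictions, key=lambda p: (-p[2], p[0], p[1]))
    lines = ["regulator\ttarget\tweight"]
    lines += [f"{reg}\t{tgt}\t{w:.10g}" for reg, tgt, w in ranked]
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path) -> list[tuple[str, str, float]]:
    path = Path(path)
    out = []
    seen = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("regulator\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
        reg, tgt = fields[0].strip(), fields[1].strip()
        if (reg, tgt) in seen:
            raise ParseError(path, lineno, f"duplicate prediction ({reg}, {tgt})")
        seen.add((reg, tgt))
        try:
            w = float(fields[2])
        except ValueError:
            raise ParseError(path, lineno, "non-numeric weight") from None
        out.append((reg, tgt, w))
    return out


def write_network(path, network: RegulatoryNetwork) -> None:
    """Signed ranked edge list "regulator TAB target TAB weight TAB sign"."""
    lines = ["regulator\ttarget\tweight\tsign"]
    for i, j, w, s in network.ranked_edges():
        lines.append(
            f"{network.gene_names[i]}\t{network.gene_names[j]}\t{w:.10g}\t{s:+d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hill models
# ---------------------------------------------------------------------------

def write_topology(path, gene_names, adjacency) -> None:
    adjacency = np.asarray(adjacency)
    lines = [
        f"{gene_names[i]}\t{gene_names[j]}\t{int(adjacency[i, j]):+d}"
        for i, j in np.argwhere(adjacency != 0)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path, gene_names=None):
    """Read "regulator TAB target TAB sign"; returns (gene_names, adjacency)."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
        try:
            sign = int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer sign") from None
        if sign not in (-1, 1):
            raise ParseError(path, lineno, f"sign must be +1 or -1, got {sign}")
        rows.append((fields[0].strip(), fields[1].strip(), sign))
    if gene_names is None:
        gene_names = sorted({n for r in rows for n in r[:2]})
    idx = {n: k for k, n in enumerate(gene_names)}
    adj = np.zeros((len(gene_names), len(gene_names)), dtype=int)
    for reg, tgt, sign in rows:
        adj[idx[reg], idx[tgt]] = sign
    return list(gene_names), adj


def write_hill_model(path, model: HillModel) -> None:
    """Flat key-value text serialization of a Hill model."""
    lines = [
        f"n_genes = {model.n_genes}",
        "genes = " + ",".join(model.gene_names),
        f"hill_coefficient = {model.n}",
        f"degradation = {model.lam:.10g}",
        "clamped = " + ",".join(str(i) for i in sorted(model.clamped_genes)),
    ]
    for i, j, s in model.edges():
        key = f"{model.gene_names[i]}->{model.gene_names[j]}"
        if s == 1:
            lines.append(f"{key} : Act b={model.b[i, j]:.10g} K={model.K[i, j]:.10g}")
        else:
            lines.append(f"{key} : Inh K={model.K[i, j]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hill_model(path) -> HillModel:
    path = Path(path)
    meta: dict[str, str] = {}
    links = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if " : " in line:
            key, rest = line.split(" : ", 1)
            parts = rest.split()
            kind = parts[0]
            vals = dict(p.split("=") for p in parts[1:])
            reg, tgt = key.split("->")
            links.append((reg.strip(), tgt.strip(), kind, vals))
        elif " = " in line:
            key, val = line.split(" = ", 1)
            meta[key.strip()] = val.strip()
        else:
            raise ParseError(path, lineno, "unrecognised line")
    genes = meta["genes"].split(",")
    G = len(genes)
    adj = np.zeros((G, G), dtype=int)
    b = np.ones((G, G))
    K = np.ones((G, G))
    idx = {g: k for k, g in enumerate(genes)}
    for reg, tgt, kind, vals in links:
        i, j = idx[reg], idx[tgt]
        adj[i, j] = 1 if kind == "Act" else -1
        if "b" in vals:
            b[i, j] = float(vals["b"])
        K[i, j] = float(vals["K"])
    clamped = frozenset(
        int(i) for i in meta.get("clamped", "").split(",") if i.strip() != ""
    )
    return HillModel(
        genes, adj, b, K, n=int(meta["hill_coefficient"]),
        lam=float(meta["degradation"]), clamped_genes=clamped,
    )


# ---------------------------------------------------------------------------
# Synthesis-model checkpoints
# ---------------------------------------------------------------------------

def save_model(path, model: SynthesisModel) -> None:
    """JSON checkpoint with weights, normalization constants and config."""
    payload = {
        "gene_names": model.gene_names,
        "hidden_widths": list(model.hidden_widths),
        "lam": model.lam,
        "dt": model.dt,
        "seed": model.seed,
        "clamped_genes": sorted(model.clamped_genes),
        "params": [[W.tolist(), b.tolist()] for W, b in model.params],
        "scaler": None
        if model.scaler is None
        else {"gmin": model.scaler.gmin.tolist(), "gmax": model.scaler.gmax.tolist()},
        "input_mask": None if model.input_mask is None else model.input_mask.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> SynthesisModel:
    payload = json.loads(Path(path).read_text())
    scaler = payload["scaler"]
    return SynthesisModel(
        gene_names=payload["gene_names"],
        params=[(np.asarray(W), np.asarray(b)) for W, b in payload["params"]],
        hidden_widths=tuple(payload["hidden_widths"]),
        scaler=None
        if scaler is None
        else GeneScaler(np.asarray(scaler["gmin"]), np.asarray(scaler["gmax"])),
        lam=payload["lam"],
        dt=payload["dt"],
        clamped_genes=frozenset(payload["clamped_genes"]),
        input_mask=None
        if payload["input_mask"] is None
        else np.asarray(payload["input_mask"]),
        seed=payload["seed"],
    )
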