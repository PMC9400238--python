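"""Gold-standard pair construction, ROC/AUC scoring, and the PCC-offset grid search.

Network reliability is judged by how well an edge set's scores separate
functionally related gene pairs (positives: pairs sharing an annotation
term, or planted same-module pairs in simulation) from unrelated ones.
Pairs absent from an edge set score 0 — absence means "not co-expressed".
The AUC is computed as the tie-corrected Mann-Whitney rank statistic
normalized by ``n_pos * n_neg``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .correlation import (
    CorrelationMatrix,
    PccThresholds,
    pcc_edge_filter,
    pcc_quantile_thresholds,
)

__all__ = [
    "GoldStandardPairs",
    "RocResult",
    "OffsetOptimization",
    "build_gold_standard",
    "score_edges",
    "roc_auc",
    "optimize_pcc_offset",
]


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GoldStandardPairs:
    """Labeled gene pairs: functionally related positives and sampled negatives."""

    pairs: pd.DataFrame  # columns gene_a, gene_b, label in {positive, negative}
    source: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        df = self.pairs
        if (df["gene_a"] >= df["gene_b"]).any():
            raise ValueError("gold-standard pairs must satisfy gene_a < gene_b")
        if df.duplicated(subset=["gene_a", "gene_b"]).any():
            raise ValueError("a pair appears more than once in the gold standard")
        labels = set(df["label"])
        if not labels <= {"positive", "negative"}:
            raise ValueError(f"unknown labels: {labels - {'positive', 'negative'}}")
        if "positive" not in labels or "negative" not in labels:
            raise ValueError("gold standard needs at least one positive and one negative")

    @property
    def n_pos(self) -> int:
        return int((self.pairs["label"] == "positive").sum())

    @property
    def n_neg(self) -> int:
        return int((self.pairs["label"] == "negative").sum())


@dataclass(frozen=True)
class RocResult:
    """AUC with the supporting ROC curve and class counts."""

    auc: float
    n_pos: int
    n_neg: int
    curve: list[tuple[float, float]] = field(default_factory=list, repr=False)


@dataclass(frozen=True)
class OffsetOptimization:
    """Result of the AUC-maximizing PCC-offset grid search."""

    best_offset: float
    table: pd.DataFrame  # columns offset, pos_cut, neg_cut, n_edges, auc


def build_gold_standard(
    annotation_map: dict[str, set[str]],
    genes,
    neg_ratio: float = 1.0,
    seed: int = 0,
) -> GoldStandardPairs:
    """Positives share at least one annotation term; negatives share none.

    Negatives are a uniform seeded sample, without replacement, of
    ``round(neg_ratio * n_pos)`` term-disjoint pairs (capped at availability
    with a warning). Genes without any annotation share no term by definition.
    """
    genes = sorted(set(map(str, genes)))
    terms = {g: frozenset(annotation_map.get(g, ())) for g in genes}
    if sum(1 for g in genes if terms[g]) < 2:
        raise ValueError("need at least 2 annotated genes")
    positives, negative_pool = [], []
    for a, b in itertools.combinations(genes, 2):
        if terms[a] & terms[b]:
            positives.append((a, b))
        else:
            negative_pool.append((a, b))
    if not positives:
        raise ValueError("no pair shares an annotation term")
    if not negative_pool:
        raise ValueError("no term-disjoint pair available for negatives")
    n_neg = int(round(neg_ratio * len(positives)))
    if n_neg > len(negative_pool):
        warnings.warn(
            f"requested {n_neg} negatives, only {len(negative_pool)} available",
            stacklevel=2,
        )
        n_neg = len(negative_pool)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negative_pool), size=n_neg, replace=False)
    negatives = [negative_pool[i] for i in sorted(chosen)]
    df = pd.DataFrame(
        [(a, b, "positive") for a, b in positives]
        + [(a, b, "negative") for a, b in negatives],
        columns=["gene_a", "gene_b", "label"],
    )
    return GoldStandardPairs(pairs=df, source="annotation-sharing", seed=seed)


_SCORE_METHODS = ("pcc_abs", "pcc", "neg_mr", "tom", "integrated")


def score_edges(edges: pd.DataFrame, method: str = "pcc_abs") -> pd.DataFrame:
    """Turn an edge table into a ranking score per pair.

    ``pcc_abs`` -> |pcc|; ``pcc`` -> signed pcc; ``neg_mr`` -> 1/mr (low
    mutual rank is strong); ``tom`` -> tom; ``integrated`` -> per-edge max of
    the min-max normalized scores of whichever method columns are present
    (for edge sets with heterogeneous provenance).
    """
    if method not in _SCORE_METHODS:
        raise ValueError(f"unknown score method {method!r}")
    if method == "integrated":
        parts = []
        for col, transform in (("pcc", np.abs), ("mr", lambda v: 1.0 / v), ("tom", None)):
            if col in edges.columns and edges[col].notna().any():
                v = edges[col].to_numpy(dtype=float)
                v = transform(v) if transform is not None else v
                lo, hi = np.nanmin(v), np.nanmax(v)
                norm = np.where(np.isnan(v), np.nan,
                                (v - lo) / (hi - lo) if hi > lo else 1.0)
                parts.append(norm)
        if not parts:
            raise ValueError("edge table has no usable score column")
        score = np.nanmax(np.column_stack(parts), axis=1)
    else:
        col = {"pcc_abs": "pcc", "pcc": "pcc", "neg_mr": "mr", "tom": "tom"}[method]
        if col not in edges.columns or edges[col].isna().all():
            raise ValueError(f"edge table lacks the {col!r} column required by {method!r}")
        v = edges[col].to_numpy(dtype=float)
        if method == "pcc_abs":
            score = np.abs(v)
        elif method == "neg_mr":
            score = 1.0 / v
        else:
            score = v
    return pd.DataFrame({
        "gene_a": edges["gene_a"], "gene_b": edges["gene_b"], "score": score,
    })


def roc_auc(gs: GoldStandardPairs, scores: pd.DataFrame) -> RocResult:
    """Tie-corrected AUC of the scored pairs against the gold standard.

    Gold-standard pairs missing from the score table receive score 0. The
    AUC equals the Mann-Whitney U statistic divided by ``n_pos * n_neg``
    (ties contribute half); the curve is a threshold sweep over distinct
    scores.
    """
    lookup = {
        _canon_pair(a, b): s
        for a, b, s in zip(scores["gene_a"], scores["gene_b"], scores["score"])
    }
    df = gs.pairs
    y = (df["label"] == "positive").to_numpy()
    s = np.array([lookup.get(_canon_pair(a, b), 0.0)
                  for a, b in zip(df["gene_a"], df["gene_b"])], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative pairs")
    ranks = rankdata(s)  # average ranks: the half-credit tie convention
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    # threshold sweep, descending distinct scores
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    boundary = np.r_[np.diff(s_sorted) != 0, True]
    curve = [(0.0, 0.0)] + [
        (fp[i] / n_neg, tp[i] / n_pos) for i in np.flatnonzero(boundary)
    ]
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    return RocResult(auc=auc, n_pos=n_pos, n_neg=n_neg, curve=curve)


def optimize_pcc_offset(
    c: CorrelationMatrix,
    gs: GoldStandardPairs,
    step: float = 0.1,
    max_offset: float = 0.4,
    top_q: float = 0.05,
    bottom_q: float = 0.05,
    symmetric_offset: bool = True,
) -> OffsetOptimization:
    """Grid-search the additive PCC-threshold offset that maximizes AUC.

    Offsets 0, step, 2*step, ... up to ``max_offset`` are evaluated; at each,
    quantile thresholds are tightened by the offset, edges filtered, scored
    by |pcc|, and the AUC computed against the gold standard. Ties go to the
    smallest offset; an offset yielding no edges is recorded with NaN AUC and
    skipped for the argmax.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    offsets = [round(i * step, 10) for i in range(int(np.floor(max_offset / step + 1e-9)) + 1)]
    rows = []
    for delta in offsets:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = pcc_quantile_thresholds(c, top_q=top_q, bottom_q=bottom_q,
                                        offset=delta, symmetric_offset=symmetric_offset)
        edges = pcc_edge_filter(c, t)
        if len(edges) == 0:
            warnings.warn(f"offset {delta} yields an empty edge set; skipped",
                          stacklevel=2)
            auc = np.nan
        else:
            auc = roc_auc(gs, score_edges(edges, "pcc_abs")).auc
        rows.append({"offset": delta, "pos_cut": t.pos_cut, "neg_cut": t.neg_cut,
                     "n_edges": len(edges), "auc": auc})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["auc"])
    if valid.empty:
        raise ValueError("every offset produced an empty edge set")
    best = float(valid.loc[valid["auc"].idxmax(), "offset"])  # idxmax: first max = smallest offset
    return OffsetOptimization(best_offset=best, table=table)
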