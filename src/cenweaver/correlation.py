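"""Pearson correlation, directional ranks, mutual ranks, and the hard-threshold edge filters.

The hard-threshold route keeps a gene pair either because its Pearson
correlation coefficient (PCC) is extreme (above the top-5% quantile or below
the bottom-5% quantile, optionally tightened by an additive offset) or
because the two genes rank each other highly: the mutual rank
``MR(A,B) = sqrt(rank(A->B) * rank(B->A))`` is the geometric mean of the two
directional PCC ranks, and the retention rule combines ``MR < mr_cut`` with
``min rank < uni_cut``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edges import canonical_edge_table, empty_edge_table
from .expression import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "RankMatrix",
    "MutualRankMatrix",
    "PccThresholds",
    "compute_pcc",
    "pcc_quantile_thresholds",
    "compute_ranks",
    "compute_mr",
    "mr_edge_filter",
    "pcc_edge_filter",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric gene-by-gene PCC matrix with a per-gene undefined flag.

    Genes with zero expression variance have no defined correlation; they are
    tracked in ``undefined_mask`` rather than silently propagated as NaN.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    undefined_mask: np.ndarray  # bool per gene, True = zero-variance

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        if self.values.shape != (g, g):
            raise ValueError("correlation matrix shape mismatch")
        defined = ~self.undefined_mask
        block = self.values[np.ix_(defined, defined)]
        if block.size:
            if not np.allclose(block, block.T, atol=1e-12):
                raise ValueError("correlation matrix not symmetric")
            if np.nanmax(np.abs(block)) > 1 + 1e-9:
                raise ValueError("correlation values outside [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def defined_offdiag_values(self) -> np.ndarray:
        """All defined off-diagonal PCC values (each unordered pair once)."""
        defined = ~self.undefined_mask
        sub = self.values[np.ix_(defined, defined)]
        iu = np.triu_indices(sub.shape[0], k=1)
        return sub[iu]


@dataclass(frozen=True)
class RankMatrix:
    """Directional PCC ranks: ``ranks[i, j]`` = rank of gene j among gene i's partners.

    Partners are ordered by PCC descending with lexicographic gene-ID
    tie-breaking; self and undefined genes carry rank 0 (meaning: no rank).
    """

    gene_ids: tuple[str, ...]
    ranks: np.ndarray  # int, 0 on diagonal / undefined


@dataclass(frozen=True)
class MutualRankMatrix:
    """Symmetric mutual ranks: geometric mean of the two directional ranks."""

    gene_ids: tuple[str, ...]
    mr: np.ndarray  # float, 0 where undefined


@dataclass(frozen=True)
class PccThresholds:
    """Hard PCC cutoffs: retain ``pcc >= pos_cut`` or ``pcc <= neg_cut`` (closed)."""

    pos_cut: float
    neg_cut: float
    top_quantile: float = 0.05
    bottom_quantile: float = 0.05
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.neg_cut < self.pos_cut <= 1.0):
            raise ValueError(
                f"require -1 <= neg_cut < pos_cut <= 1, got "
                f"({self.neg_cut}, {self.pos_cut})"
            )


def compute_pcc(m: ExpressionMatrix, block_size: int | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlation of gene expression vectors across samples.

    ``pcc = sum((x - xbar)(y - ybar)) / sqrt(sum((x - xbar)^2) sum((y - ybar)^2))``.
    Zero-variance genes are flagged undefined. ``block_size`` chunks the
    matrix product over row blocks, bounding peak memory of the product;
    results agree with the dense path to floating-point round-off.
    """
    if m.shape[1] < 3:
        raise ValueError("PCC requires at least 3 samples")
    if m.shape[0] < 2:
        raise ValueError("PCC requires at least 2 genes")
    X = m.values
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    undefined = norms == 0.0
    safe = np.where(undefined, 1.0, norms)
    Z = Xc / safe[:, None]
    G = Z.shape[0]
    if block_size is None or block_size >= G:
        C = Z @ Z.T
    else:
        C = np.empty((G, G))
        for start in range(0, G, block_size):
            stop = min(start + block_size, G)
            C[start:stop] = Z[start:stop] @ Z.T
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    C[undefined, :] = np.nan
    C[:, undefined] = np.nan
    # enforce exact symmetry against float non-associativity in blocked products
    defined = ~undefined
    idx = np.ix_(defined, defined)
    C[idx] = (C[idx] + C[idx].T) / 2.0
    return CorrelationMatrix(tuple(m.gene_ids), C, undefined)


def pcc_quantile_thresholds(
    c: CorrelationMatrix,
    top_q: float = 0.05,
    bottom_q: float = 0.05,
    offset: float = 0.0,
    symmetric_offset: bool = True,
) -> PccThresholds:
    """Quantile-anchored PCC cutoffs, optionally tightened by an offset.

    ``pos_cut`` is the ``1 - top_q`` linear-interpolation quantile of all
    defined off-diagonal PCC values plus ``offset`` (clamped to 1);
    ``neg_cut`` is the ``bottom_q`` quantile minus the offset (clamped to
    -1). ``symmetric_offset=False`` applies the offset to the positive cut
    only.
    """
    vals = c.defined_offdiag_values()
    if vals.size == 0:
        raise ValueError("no defined off-diagonal correlations")
    pos_cut = float(np.quantile(vals, 1.0 - top_q)) + offset
    neg_off = offset if symmetric_offset else 0.0
    neg_cut = float(np.quantile(vals, bottom_q)) - neg_off
    if pos_cut > 1.0:
        warnings.warn(f"pos_cut {pos_cut:.4g} clamped to 1", stacklevel=2)
        pos_cut = 1.0
    if neg_cut < -1.0:
        warnings.warn(f"neg_cut {neg_cut:.4g} clamped to -1", stacklevel=2)
        neg_cut = -1.0
    return PccThresholds(pos_cut=pos_cut, neg_cut=neg_cut, top_quantile=top_q,
                         bottom_quantile=bottom_q, offset=offset)


def compute_ranks(c: CorrelationMatrix, rank_on: str = "signed") -> RankMatrix:
    """Directional ranks: partners of each gene sorted by PCC descending.

    ``rank_on='signed'`` (default) ranks by the signed correlation, the
    convention of the mutual-rank co-expression literature; ``'abs'`` ranks
    by |PCC| so strong negative partners also rank highly. Ties are broken
    by lexicographic gene ID so results are deterministic across platforms.
    Undefined genes are excluded from every partner list.
    """
    if rank_on not in ("signed", "abs"):
        raise ValueError("rank_on must be 'signed' or 'abs'")
    G = c.n_genes
    defined_idx = np.flatnonzero(~c.undefined_mask)
    if defined_idx.size < 2:
        raise ValueError("ranking requires at least 2 defined genes")
    ranks = np.zeros((G, G), dtype=np.int64)
    ids = np.array(c.gene_ids, dtype=object)
    for i in defined_idx:
        partners = defined_idx[defined_idx != i]
        pccs = c.values[i, partners]
        if rank_on == "abs":
            pccs = np.abs(pccs)
        # lexsort: last key primary -> sort by -pcc, ties by gene id ascending
        order = np.lexsort((ids[partners], -pccs))
        ranks[i, partners[order]] = np.arange(1, partners.size + 1)
    return RankMatrix(c.gene_ids, ranks)


def compute_mr(r: RankMatrix) -> MutualRankMatrix:
    """Mutual rank: element-wise geometric mean of the two directional ranks."""
    R = r.ranks.astype(float)
    mr = np.sqrt(R * R.T)
    return MutualRankMatrix(r.gene_ids, mr)


def mr_edge_filter(
    mrm: MutualRankMatrix,
    r: RankMatrix,
    c: CorrelationMatrix | None = None,
    mr_cut: float = 30.0,
    uni_cut: int = 3,
    combine: str = "any",
) -> pd.DataFrame:
    """Retain gene pairs by the mutual-rank rules (strict inequalities).

    ``combine='any'`` keeps a pair when ``MR < mr_cut`` OR the smaller
    directional rank is ``< uni_cut``; ``'all'`` requires both. Each kept
    edge carries mr, both directional ranks, and (when the correlation matrix
    is supplied) pcc and its sign.
    """
    if combine not in ("any", "all"):
        raise ValueError("combine must be 'any' or 'all'")
    if mrm.gene_ids != r.gene_ids or (c is not None and c.gene_ids != r.gene_ids):
        raise ValueError("inconsistent gene universes")
    R = r.ranks
    defined = (R > 0) & (R.T > 0)
    min_rank = np.minimum(R, R.T)
    keep_mr = (mrm.mr < mr_cut) & defined
    keep_uni = (min_rank < uni_cut) & defined
    keep = (keep_mr | keep_uni) if combine == "any" else (keep_mr & keep_uni)
    iu = np.triu_indices(len(r.gene_ids), k=1)
    mask = keep[iu]
    if not mask.any():
        return empty_edge_table()
    ai, bi = iu[0][mask], iu[1][mask]
    ids = np.array(r.gene_ids, dtype=object)
    df = pd.DataFrame({
        "gene_a": ids[ai], "gene_b": ids[bi],
        "rank_ab": R[ai, bi].astype(float),
        "rank_ba": R[bi, ai].astype(float),
        "mr": mrm.mr[ai, bi],
    })
    if c is not None:
        pcc = c.values[ai, bi]
        df["pcc"] = pcc
        df["sign"] = np.where(pcc < 0, "-", "+")
    df["methods"] = "mr"
    return canonical_edge_table(df)


def pcc_edge_filter(c: CorrelationMatrix, t: PccThresholds) -> pd.DataFrame:
    """Retain gene pairs with PCC in the closed intervals [pos_cut, 1] or [-1, neg_cut]."""
    iu = np.triu_indices(c.n_genes, k=1)
    pcc = c.values[iu]
    keep = np.isfinite(pcc) & ((pcc >= t.pos_cut) | (pcc <= t.neg_cut))
    if not keep.any():
        return empty_edge_table()
    ai, bi = iu[0][keep], iu[1][keep]
    ids = np.array(c.gene_ids, dtype=object)
    kept = pcc[keep]
    df = pd.DataFrame({
        "gene_a": ids[ai], "gene_b": ids[bi],
        "pcc": kept,
        "sign": np.where(kept < 0, "-", "+"),
        "methods": "pcc",
    })
    return canonical_edge_table(df)
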