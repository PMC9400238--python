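"""Scale-free soft thresholding, unsigned adjacency, and the topological overlap matrix.

The soft-threshold route raises |PCC| to an integer power beta chosen so the
resulting weighted network approximates a scale-free degree distribution
(linear log-log fit of the connectivity histogram with R^2 at or above a
target, 0.90 by default). The topological overlap measure (TOM) then scores
each pair by combining its direct adjacency with the adjacency both genes
share with third parties, and pairs with TOM strictly above a cutoff (0.1 by
default) become candidate edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .edges import canonical_edge_table, empty_edge_table

__all__ = [
    "SoftPowerReport",
    "AdjacencyMatrix",
    "TomMatrix",
    "fit_scale_free",
    "compute_adjacency",
    "compute_tom",
    "tom_edge_filter",
]


@dataclass(frozen=True)
class SoftPowerReport:
    """Per-beta scale-free fit statistics and the selected soft power.

    ``candidates`` has columns beta, r2 (signed: negated when the log-log
    slope is positive), slope, mean_k; ``selected_beta`` is the smallest beta
    whose signed r2 reaches ``r2_target`` (None when no beta qualifies).
    """

    candidates: pd.DataFrame
    selected_beta: int | None
    r2_target: float = 0.90


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Unsigned adjacency ``a_ij = |pcc_ij| ** beta`` with unit diagonal."""

    gene_ids: tuple[str, ...]
    a: np.ndarray
    beta: int

    def __post_init__(self) -> None:
        if self.a.min() < -1e-12 or self.a.max() > 1 + 1e-12:
            raise ValueError("adjacency values outside [0, 1]")


@dataclass(frozen=True)
class TomMatrix:
    """Unsigned topological overlap, values in [0, 1], diagonal 1 by convention."""

    gene_ids: tuple[str, ...]
    tom: np.ndarray


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed R^2 and slope of the log10 p(k) vs log10 k regression."""
    if np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: all genes identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        in_bin = which == b
        cnt = int(in_bin.sum())
        if cnt == 0:
            continue
        mean_k = k[in_bin].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(cnt / k.size))
    if len(xs) < 2:
        raise ValueError("too few non-empty connectivity bins for a fit")
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    signed = r2 if slope < 0 else -r2
    return float(signed), float(slope)


def fit_scale_free(
    c: CorrelationMatrix,
    betas=range(1, 21),
    n_bins: int = 10,
    r2_target: float = 0.90,
) -> SoftPowerReport:
    """Scan soft powers and pick the smallest giving a scale-free topology fit.

    For each beta the unsigned adjacency is formed, per-gene connectivity
    ``k_i = sum_j a_ij`` computed, genes binned into ``n_bins`` equal-width
    connectivity bins, and log10 of the bin frequency regressed on log10 of
    the bin's mean connectivity.
    """
    if c.n_genes < 10:
        raise ValueError("scale-free fit requires at least 10 genes")
    absc = np.abs(np.nan_to_num(c.values, nan=0.0))
    np.fill_diagonal(absc, 0.0)
    if absc.max() == 0:
        raise ValueError("all correlations are zero")
    rows = []
    selected = None
    for beta in betas:
        A = absc ** beta
        k = A.sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append({"beta": int(beta), "r2": r2, "slope": slope,
                     "mean_k": float(k.mean())})
        if selected is None and r2 >= r2_target:
            selected = int(beta)
    return SoftPowerReport(candidates=pd.DataFrame(rows),
                           selected_beta=selected, r2_target=r2_target)


def compute_adjacency(c: CorrelationMatrix, beta: int) -> AdjacencyMatrix:
    """Unsigned adjacency: ``a_ij = |pcc_ij| ** beta``, diagonal 1."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    vals = c.values
    if np.isnan(vals).any():
        warnings.warn("undefined correlations set to adjacency 0", stacklevel=2)
    A = np.abs(np.nan_to_num(vals, nan=0.0)) ** beta
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(c.gene_ids, A, int(beta))


def compute_tom(a: AdjacencyMatrix) -> TomMatrix:
    """Unsigned topological overlap.

    ``tom_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is set to 1.
    """
    A = a.a.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # diagonal of A is 0, so u=i and u=j terms vanish
    k = A.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return TomMatrix(a.gene_ids, tom)


def tom_edge_filter(
    t: TomMatrix,
    tom_cut: float = 0.1,
    c: CorrelationMatrix | None = None,
) -> pd.DataFrame:
    """Candidate pairs with TOM strictly greater than ``tom_cut``.

    When the correlation matrix is supplied each edge also carries the
    underlying pcc and its sign.
    """
    iu = np.triu_indices(len(t.gene_ids), k=1)
    tom = t.tom[iu]
    keep = tom > tom_cut
    if not keep.any():
        return empty_edge_table()
    ai, bi = iu[0][keep], iu[1][keep]
    ids = np.array(t.gene_ids, dtype=object)
    df = pd.DataFrame({"gene_a": ids[ai], "gene_b": ids[bi], "tom": tom[keep]})
    if c is not None:
        pcc = c.values[ai, bi]
        df["pcc"] = pcc
        df["sign"] = np.where(pcc < 0, "-", "+")
    df["methods"] = "tom"
    return canonical_edge_table(df)
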