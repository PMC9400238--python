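"""Edge-set integration, network statistics, family subnetworks, and enrichment.

The integrated network is the union (default) or intersection of the
hard-threshold (PCC/mutual-rank) and soft-threshold (TOM) candidate edge
sets, with per-edge method provenance preserved so every edge can be traced
back to the rule that admitted it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .correlation import CorrelationMatrix
from .edges import (
    EDGE_COLUMNS,
    canonical_edge_table,
    degree_table,
    edge_gene_set,
    merge_method_sets,
)

__all__ = [
    "NetworkStats",
    "FamilySubnetwork",
    "integrate",
    "network_stats",
    "family_subnetwork",
    "top_k_neighborhood",
    "homolog_overlap",
    "enrich_terms",
    "hub_rank",
]

_NUMERIC_COLS = ["pcc", "rank_ab", "rank_ba", "mr", "tom"]


@dataclass(frozen=True)
class NetworkStats:
    """Headline statistics of an edge set against a stated gene universe."""

    n_genes_in_network: int
    n_edges: int
    gene_coverage_pct: float
    mean_connectivity: float
    pct_negative_edges: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_genes_in_network": self.n_genes_in_network,
            "n_edges": self.n_edges,
            "gene_coverage_pct": self.gene_coverage_pct,
            "mean_connectivity": self.mean_connectivity,
            "pct_negative_edges": self.pct_negative_edges,
        }


@dataclass(frozen=True)
class FamilySubnetwork:
    """Edges between (or within) gene families, with per-gene degrees.

    ``pairs_per_gene`` = n_edges / n_distinct_genes (the convention used in
    the co-expression literature for "average co-expressed pairs per gene");
    ``mean_connectivity`` = 2 * n_edges / n_distinct_genes.
    """

    edges: pd.DataFrame
    degrees: pd.Series
    pairs_per_gene: float
    mean_connectivity: float


def integrate(
    edges_a: pd.DataFrame,
    edges_b: pd.DataFrame,
    mode: str = "union",
) -> pd.DataFrame:
    """Merge two edge tables pair-wise, preserving method provenance.

    ``union`` keeps every pair from either table; a score column present in
    both with materially different values (beyond 1e-9) is kept under
    method-qualified names (``<col>__a`` / ``<col>__b``) alongside the first
    value. ``intersection`` keeps only pairs present in both tables.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    a = canonical_edge_table(edges_a).set_index(["gene_a", "gene_b"])
    b = canonical_edge_table(edges_b).set_index(["gene_a", "gene_b"])
    how = "outer" if mode == "union" else "inner"
    merged = a.join(b, how=how, lsuffix="__a", rsuffix="__b")
    out = pd.DataFrame(index=merged.index)
    extra_cols: dict[str, pd.Series] = {}
    for col in _NUMERIC_COLS:
        va, vb = merged[f"{col}__a"], merged[f"{col}__b"]
        both = va.notna() & vb.notna()
        conflict = both & (np.abs(va - vb) > 1e-9)
        out[col] = va.combine_first(vb)
        if conflict.any():
            warnings.warn(
                f"column {col!r} differs between inputs for "
                f"{int(conflict.sum())} pairs; keeping both method-qualified",
                stacklevel=2,
            )
            extra_cols[f"{col}__a"] = va
            extra_cols[f"{col}__b"] = vb
    sa = merged["sign__a"].fillna("")
    sb = merged["sign__b"].fillna("")
    out["sign"] = np.where(sa != "", sa, sb)
    out["methods"] = [
        merge_method_sets("" if pd.isna(x) else x, "" if pd.isna(y) else y)
        for x, y in zip(merged["methods__a"], merged["methods__b"])
    ]
    for name, series in extra_cols.items():
        out[name] = series
    out = out.reset_index()
    cols = EDGE_COLUMNS + [c for c in out.columns if c not in EDGE_COLUMNS]
    return out[cols].sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)


def network_stats(edges: pd.DataFrame, gene_universe) -> NetworkStats:
    """Coverage, mean connectivity, and negative-edge percentage of an edge set."""
    universe = set(map(str, gene_universe))
    in_net = edge_gene_set(edges)
    missing = in_net - universe
    if missing:
        raise ValueError(f"edge genes missing from universe: {sorted(missing)[:5]}")
    n_genes = len(in_net)
    n_edges = len(edges)
    signed = edges["sign"].isin(["+", "-"])
    n_signed = int(signed.sum())
    n_neg = int((edges.loc[signed, "sign"] == "-").sum())
    return NetworkStats(
        n_genes_in_network=n_genes,
        n_edges=n_edges,
        gene_coverage_pct=100.0 * n_genes / len(universe) if universe else 0.0,
        mean_connectivity=2.0 * n_edges / n_genes if n_genes else 0.0,
        pct_negative_edges=100.0 * n_neg / n_signed if n_signed else 0.0,
    )


def family_subnetwork(
    edges: pd.DataFrame,
    family_a,
    family_b=None,
) -> FamilySubnetwork:
    """Edges with one endpoint in each family (or both within one family).

    With ``family_b`` omitted or equal to ``family_a``, returns the
    within-family subnetwork.
    """
    fa = set(map(str, family_a))
    fb = fa if family_b is None else set(map(str, family_b))
    if not fa or not fb:
        raise ValueError("family gene lists must be non-empty")
    ga, gb = edges["gene_a"], edges["gene_b"]
    keep = (ga.isin(fa) & gb.isin(fb)) | (ga.isin(fb) & gb.isin(fa))
    sub = edges.loc[keep].reset_index(drop=True)
    degrees = degree_table(sub)
    n_genes = len(edge_gene_set(sub))
    n_edges = len(sub)
    return FamilySubnetwork(
        edges=sub,
        degrees=degrees,
        pairs_per_gene=n_edges / n_genes if n_genes else 0.0,
        mean_connectivity=2.0 * n_edges / n_genes if n_genes else 0.0,
    )


def top_k_neighborhood(c: CorrelationMatrix, gene: str, k: int = 300) -> list[str]:
    """The k partners with highest PCC to ``gene``, in rank order.

    Ties break lexicographically on gene ID; requesting more partners than
    exist returns all of them with a warning.
    """
    if gene not in c.gene_ids:
        raise KeyError(f"gene {gene!r} not in correlation matrix")
    i = c.gene_ids.index(gene)
    if c.undefined_mask[i]:
        raise ValueError(f"gene {gene!r} has undefined correlations")
    ids = np.array(c.gene_ids, dtype=object)
    partners = np.flatnonzero(~c.undefined_mask)
    partners = partners[partners != i]
    order = np.lexsort((ids[partners], -c.values[i, partners]))
    ordered = [str(g) for g in ids[partners[order]]]
    if k >= len(ordered):
        if k > len(ordered):
            warnings.warn(
                f"k={k} exceeds the {len(ordered)} available partners",
                stacklevel=2,
            )
        return ordered
    return ordered[:max(k, 0)]


def homolog_overlap(neigh_a, neigh_b, homolog_pairs) -> tuple[int, list[tuple[str, str]]]:
    """Count cross-species homolog pairs linking two neighborhoods.

    ``homolog_pairs`` is an iterable of (gene_in_a_species, gene_in_b_species)
    pairs; a hit is a pair with the first gene in ``neigh_a`` and the second
    in ``neigh_b``.
    """
    sa, sb = set(map(str, neigh_a)), set(map(str, neigh_b))
    hits = sorted({(str(x), str(y)) for x, y in homolog_pairs
                   if str(x) in sa and str(y) in sb})
    return len(hits), hits


def enrich_terms(gene_set, annotation_map: dict[str, set[str]], universe) -> pd.DataFrame:
    """Hypergeometric term enrichment with Benjamini-Hochberg correction.

    For each term: k = genes in the set carrying it, K = universe genes
    carrying it, n = set size, N = universe size; p is the upper-tail
    hypergeometric probability P(X >= k), q the BH-adjusted value across all
    tested terms.
    """
    universe = sorted(set(map(str, universe)))
    gene_set = sorted(set(map(str, gene_set)))
    if not gene_set or not universe:
        raise ValueError("gene set and universe must be non-empty")
    missing = set(gene_set) - set(universe)
    if missing:
        raise ValueError(f"gene set not contained in universe: {sorted(missing)[:5]}")
    N, n = len(universe), len(gene_set)
    in_set = set(gene_set)
    term_universe: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for g in universe:
        for term in annotation_map.get(g, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if g in in_set:
                term_set[term] = term_set.get(term, 0) + 1
    rows = []
    for term in sorted(term_universe):
        K = term_universe[term]
        k = term_set.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def hub_rank(edges: pd.DataFrame, candidates) -> list[tuple[str, int]]:
    """Candidates ordered by degree in the edge table, ties lexicographic."""
    degrees = degree_table(edges)
    ranked = sorted(
        ((str(g), int(degrees.get(str(g), 0))) for g in candidates),
        key=lambda gd: (-gd[1], gd[0]),
    )
    return ranked
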