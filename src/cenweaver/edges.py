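"""EdgeTable schema: undirected gene pairs with per-method scores and provenance.

An edge table is a pandas DataFrame with one row per undirected pair,
``gene_a < gene_b`` lexicographically, carrying whichever score columns the
producing method defines (PCC, directional ranks, mutual rank, TOM), the
correlation sign, and a comma-joined ``methods`` provenance set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EDGE_COLUMNS = [
    "gene_a", "gene_b", "pcc", "rank_ab", "rank_ba", "mr", "tom", "sign", "methods",
]

_SCORE_COLUMNS = ["pcc", "rank_ab", "rank_ba", "mr", "tom"]


def empty_edge_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in _SCORE_COLUMNS})
    df.insert(0, "gene_a", pd.Series(dtype=str))
    df.insert(1, "gene_b", pd.Series(dtype=str))
    df["sign"] = pd.Series(dtype=str)
    df["methods"] = pd.Series(dtype=str)
    return df[EDGE_COLUMNS]


def canonical_edge_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize an edge table: order endpoints, sort rows, order columns."""
    df = df.copy()
    swap = df["gene_a"] > df["gene_b"]
    if swap.any():
        a = df.loc[swap, "gene_a"].copy()
        df.loc[swap, "gene_a"] = df.loc[swap, "gene_b"]
        df.loc[swap, "gene_b"] = a
        if "rank_ab" in df and "rank_ba" in df:
            r = df.loc[swap, "rank_ab"].copy()
            df.loc[swap, "rank_ab"] = df.loc[swap, "rank_ba"]
            df.loc[swap, "rank_ba"] = r
    for c in EDGE_COLUMNS:
        if c not in df.columns:
            df[c] = "" if c in ("sign", "methods") else np.nan
    if df.duplicated(subset=["gene_a", "gene_b"]).any():
        raise ValueError("duplicate gene pairs in edge table")
    df = df.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    return df[EDGE_COLUMNS]


def sign_of(pcc: float) -> str:
    return "-" if pcc < 0 else "+"


def merge_method_sets(a: str, b: str) -> str:
    parts = {p for p in str(a).split(",") if p} | {p for p in str(b).split(",") if p}
    return ",".join(sorted(parts))


def edge_gene_set(df: pd.DataFrame) -> set[str]:
    return set(df["gene_a"]) | set(df["gene_b"])


def degree_table(df: pd.DataFrame) -> pd.Series:
    """Per-gene degree over the edge table (undirected)."""
    counts = pd.concat([df["gene_a"], df["gene_b"]]).value_counts()
    return counts.sort_index()


def write_edges_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str,
                                            "sign": str, "methods": str})
    df["methods"] = df["methods"].fillna("")
    df["sign"] = df["sign"].fillna("")
    return canonical_edge_table(df)
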