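"""Expression-matrix I/O, the 3-sigma low-TPM gene filter, and sample outlier detection.

The substrate of the whole pipeline is a genes x samples matrix of TPM
(transcripts per kilobase of exon model per million mapped reads) values.
Genes whose abundance is uniformly low produce spuriously small correlation
coefficients, so before any correlation is computed a TPM floor is derived
from the data itself: the mean of the lowest 5% of positive values plus
three times their standard deviation (the "3-sigma" criterion). A gene is
dropped only if it falls below that floor in *every* sample, so
tissue-specific genes survive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "DuplicateIdError",
    "ExpressionMatrix",
    "TpmThreshold",
    "SampleClusteringReport",
    "read_expression_tsv",
    "write_expression_tsv",
    "compute_tpm_threshold",
    "filter_low_expression",
    "detect_outlier_samples",
    "merge_sample_groups",
]

GENE_ID_COLUMN = "gene_id"


class DuplicateIdError(ValueError):
    """Raised when gene or sample identifiers are not unique."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes x samples TPM matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene ID, columns by sample ID, float TPM values.
        All values must be finite and non-negative, identifiers unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate gene IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample IDs: {dups}")
        vals = df.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if vals.size and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative TPM value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])


@dataclass(frozen=True)
class TpmThreshold:
    """The 3-sigma expression floor: ``threshold = mean_low + 3 * d``.

    ``mean_low`` and ``d`` are the mean and sample standard deviation of the
    low-tail value set (the lowest ``tail_fraction`` of all strictly positive
    TPM values in the matrix, pooled across genes and samples).
    """

    threshold: float
    mean_low: float
    d: float
    tail_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("dispersion d must be non-negative")
        if not math.isclose(self.threshold, self.mean_low + 3.0 * self.d,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("threshold must equal mean_low + 3*d")


@dataclass(frozen=True)
class SampleClusteringReport:
    """Ward-linkage clustering of samples with merge-height outlier flags."""

    linkage: np.ndarray
    merge_heights: dict[str, float]
    height_cutoff: float
    flagged_outliers: list[str] = field(default_factory=list)


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a TPM matrix from TSV (first column gene IDs, header = sample IDs)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"duplicate gene IDs in {path}: {dups}")
    try:
        df = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            for i, v in enumerate(raw[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {raw.index[i]!r}, "
                        f"sample {col!r} (row {i + 2}, column {j + 2}): {v!r}"
                    ) from None
        raise  # pragma: no cover - unreachable
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = GENE_ID_COLUMN
    return ExpressionMatrix(df)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    """Write a TPM matrix to TSV with full float round-trip precision."""
    df = m.data.copy()
    df.index.name = GENE_ID_COLUMN
    df.to_csv(path, sep="\t", float_format="%.17g")


def compute_tpm_threshold(m: ExpressionMatrix, tail_fraction: float = 0.05) -> TpmThreshold:
    """Derive the 3-sigma TPM floor from the low tail of positive values.

    The low tail is the lowest ``ceil(tail_fraction * N)`` of the N strictly
    positive values in the matrix; the threshold is the tail mean plus three
    times its sample standard deviation (zero for a singleton tail).
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    vals = m.values.ravel()
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("no strictly positive TPM values in matrix")
    n_tail = math.ceil(tail_fraction * pos.size)
    tail = np.sort(pos)[:n_tail]
    mean_low = float(tail.mean())
    d = float(tail.std(ddof=1)) if tail.size > 1 else 0.0
    return TpmThreshold(threshold=mean_low + 3.0 * d, mean_low=mean_low, d=d,
                        tail_fraction=tail_fraction)


def filter_low_expression(
    m: ExpressionMatrix, t: TpmThreshold
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove genes below the TPM floor in every sample.

    Returns the filtered matrix and a removal report with columns
    ``gene_id``, ``max_tpm``, ``threshold``. A gene is removed exactly when
    its maximum TPM across samples is strictly below the threshold.
    """
    max_tpm = m.data.max(axis=1)
    removed_mask = max_tpm < t.threshold
    report = pd.DataFrame({
        GENE_ID_COLUMN: m.data.index[removed_mask].astype(str),
        "max_tpm": max_tpm[removed_mask].to_numpy(),
        "threshold": t.threshold,
    }).reset_index(drop=True)
    kept = ExpressionMatrix(m.data.loc[~removed_mask])
    return kept, report


def detect_outlier_samples(
    m: ExpressionMatrix, height_quantile: float = 0.99
) -> SampleClusteringReport:
    """Flag outlier samples by Ward clustering of expression profiles.

    Samples are clustered on Euclidean distances between their expression
    profiles with Ward linkage in the ward.D2 convention (squared distances
    inside the update, as scipy's ``ward`` implements). A sample is flagged
    when the height at which it first merges into the tree strictly exceeds
    the ``height_quantile`` quantile of all merge heights. Report-only:
    nothing is dropped automatically.
    """
    if m.shape[1] < 3:
        raise ValueError("outlier detection requires at least 3 samples")
    profiles = m.values.T  # samples x genes
    Z = linkage(profiles, method="ward")
    n = profiles.shape[0]
    # height at which each original sample (leaf) is first merged
    leaf_height: dict[int, float] = {}
    for a, b, h, _ in Z:
        for leaf in (int(a), int(b)):
            if leaf < n and leaf not in leaf_height:
                leaf_height[leaf] = float(h)
    cutoff = float(np.quantile(Z[:, 2], height_quantile))
    sample_ids = m.sample_ids
    heights = {sample_ids[i]: leaf_height.get(i, 0.0) for i in range(n)}
    flagged = sorted(s for s, h in heights.items() if h > cutoff)
    return SampleClusteringReport(
        linkage=Z, merge_heights=heights, height_cutoff=cutoff,
        flagged_outliers=flagged,
    )


def merge_sample_groups(m: ExpressionMatrix, groups: dict[str, str]) -> ExpressionMatrix:
    """Mean-merge samples belonging to the same group (e.g. same tissue).

    ``groups`` maps sample ID to group label; samples absent from the map are
    kept as their own singleton groups.
    """
    labels = [groups.get(s, s) for s in m.sample_ids]
    merged = m.data.T.groupby(pd.Index(labels, name="sample"), sort=False).mean().T
    if merged.shape[1] < m.shape[1]:
        warnings.warn(
            f"merged {m.shape[1]} samples into {merged.shape[1]} groups",
            stacklevel=2,
        )
    return ExpressionMatrix(merged)
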