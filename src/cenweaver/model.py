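"""The end-to-end co-expression network model.

``CoexpressionNetwork`` holds a TPM matrix plus every stage parameter;
``fit()`` runs the integrated pipeline — 3-sigma low-expression filtering,
the hard-threshold route (PCC quantile cuts, optionally AUC-optimized, plus
mutual-rank retention), the soft-threshold route (scale-free power selection,
adjacency, TOM cutoff), and edge-set integration — and returns a
``CoexpressionNetworkResults`` carrying the network, per-stage diagnostics,
and a ``summary()`` table. When a gold standard is supplied, the fit also
reports ROC/AUC reliability of each route and of the integrated network.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (
    CorrelationMatrix,
    PccThresholds,
    compute_mr,
    compute_pcc,
    compute_ranks,
    mr_edge_filter,
    pcc_edge_filter,
    pcc_quantile_thresholds,
)
from .edges import write_edges_tsv
from .evaluation import (
    GoldStandardPairs,
    OffsetOptimization,
    optimize_pcc_offset,
    roc_auc,
    score_edges,
)
from .expression import (
    ExpressionMatrix,
    TpmThreshold,
    compute_tpm_threshold,
    detect_outlier_samples,
    filter_low_expression,
    read_expression_tsv,
)
from .network import NetworkStats, integrate, network_stats
from .tom import SoftPowerReport, compute_adjacency, compute_tom, fit_scale_free, tom_edge_filter

__all__ = ["CoexpressionNetwork", "CoexpressionNetworkResults"]

#: defaults follow the published pipeline's printed parameters
DEFAULT_PARAMS: dict[str, Any] = {
    "tail_fraction": 0.05,
    "top_q": 0.05,
    "bottom_q": 0.05,
    "offset": 0.0,
    "optimize_offset": False,
    "offset_step": 0.1,
    "max_offset": 0.4,
    "symmetric_offset": True,
    "mr_cut": 30.0,
    "uni_cut": 3,
    "combine": "any",
    "rank_on": "signed",
    "r2_target": 0.90,
    "beta": None,  # None = auto-select by the scale-free fit
    "n_bins": 10,
    "tom_cut": 0.1,
    "integration": "union",
    "score_method": "integrated",
    "check_outliers": True,
    "height_quantile": 0.99,
    # recorded for provenance only; module detection is out of this model's scope
    "min_module_size": 30,
    "merge_cut_height": 0.25,
    "reassign_threshold": 0,
}


class CoexpressionNetwork:
    """Integrated co-expression network model for a genes x samples TPM matrix.

    Parameters
    ----------
    expression : ExpressionMatrix
        The input TPM matrix.
    gold_standard : GoldStandardPairs, optional
        Labeled functional pairs; enables ROC/AUC evaluation and the
        ``optimize_offset`` grid search.
    **params
        Any key of ``DEFAULT_PARAMS``; unknown keys raise.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        gold_standard: GoldStandardPairs | None = None,
        **params: Any,
    ) -> None:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise TypeError(f"unknown parameters: {sorted(unknown)}")
        self.expression = expression
        self.gold_standard = gold_standard
        self.params: dict[str, Any] = {**DEFAULT_PARAMS, **params}
        if self.params["optimize_offset"] and gold_standard is None:
            raise ValueError("optimize_offset=True requires a gold standard")

    @classmethod
    def from_tsv(cls, path, gold_standard=None, **params) -> "CoexpressionNetwork":
        return cls(read_expression_tsv(path), gold_standard=gold_standard, **params)

    def fit(self) -> "CoexpressionNetworkResults":
        p = self.params
        clustering = (
            detect_outlier_samples(self.expression, p["height_quantile"])
            if p["check_outliers"] and self.expression.shape[1] >= 3
            else None
        )
        tpm_threshold = compute_tpm_threshold(self.expression, p["tail_fraction"])
        filtered, removal_report = filter_low_expression(self.expression, tpm_threshold)
        corr = compute_pcc(filtered)

        # hard-threshold route: PCC quantile cuts (optionally AUC-optimized) + MR rules
        offset_opt: OffsetOptimization | None = None
        offset = p["offset"]
        if p["optimize_offset"]:
            offset_opt = optimize_pcc_offset(
                corr, self.gold_standard, step=p["offset_step"],
                max_offset=p["max_offset"], top_q=p["top_q"], bottom_q=p["bottom_q"],
                symmetric_offset=p["symmetric_offset"],
            )
            offset = offset_opt.best_offset
        thresholds = pcc_quantile_thresholds(
            corr, top_q=p["top_q"], bottom_q=p["bottom_q"], offset=offset,
            symmetric_offset=p["symmetric_offset"],
        )
        pcc_edges = pcc_edge_filter(corr, thresholds)
        ranks = compute_ranks(corr, rank_on=p["rank_on"])
        mrm = compute_mr(ranks)
        mr_edges = mr_edge_filter(mrm, ranks, corr, mr_cut=p["mr_cut"],
                                  uni_cut=p["uni_cut"], combine=p["combine"])
        hard_edges = integrate(pcc_edges, mr_edges, mode="union")

        # soft-threshold route: scale-free power -> adjacency -> TOM cutoff
        softpower: SoftPowerReport | None = None
        beta = p["beta"]
        if beta is None:
            softpower = fit_scale_free(corr, n_bins=p["n_bins"], r2_target=p["r2_target"])
            beta = softpower.selected_beta
            if beta is None:
                beta = int(
                    softpower.candidates.loc[softpower.candidates["r2"].idxmax(), "beta"]
                )
                warnings.warn(
                    f"no soft power reached r2 >= {p['r2_target']}; "
                    f"using the best-fitting beta={beta}",
                    stacklevel=2,
                )
        adjacency = compute_adjacency(corr, int(beta))
        tom = compute_tom(adjacency)
        tom_edges = tom_edge_filter(tom, tom_cut=p["tom_cut"], c=corr)

        edges = integrate(hard_edges, tom_edges, mode=p["integration"])
        stats = network_stats(edges, filtered.gene_ids)

        aucs: dict[str, float] = {}
        if self.gold_standard is not None:
            for name, table, method in (
                ("pcc", pcc_edges, "pcc_abs"),
                ("mr", mr_edges, "neg_mr"),
                ("tom", tom_edges, "tom"),
                ("integrated", edges, p["score_method"]),
            ):
                if len(table):
                    aucs[name] = roc_auc(
                        self.gold_standard, score_edges(table, method)
                    ).auc

        return CoexpressionNetworkResults(
            model=self,
            edges=edges,
            stats=stats,
            tpm_threshold=tpm_threshold,
            removal_report=removal_report,
            filtered_expression=filtered,
            sample_clustering=clustering,
            correlation=corr,
            pcc_thresholds=thresholds,
            offset_optimization=offset_opt,
            pcc_edges=pcc_edges,
            mr_edges=mr_edges,
            tom_edges=tom_edges,
            softpower=softpower,
            beta=int(beta),
            aucs=aucs,
        )


@dataclass
class CoexpressionNetworkResults:
    """Fitted integrated network with per-stage diagnostics."""

    model: CoexpressionNetwork
    edges: pd.DataFrame
    stats: NetworkStats
    tpm_threshold: TpmThreshold
    removal_report: pd.DataFrame
    filtered_expression: ExpressionMatrix
    sample_clustering: object
    correlation: CorrelationMatrix
    pcc_thresholds: PccThresholds
    offset_optimization: OffsetOptimization | None
    pcc_edges: pd.DataFrame
    mr_edges: pd.DataFrame
    tom_edges: pd.DataFrame
    softpower: SoftPowerReport | None
    beta: int
    aucs: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Integrated Co-expression Network Results",
            "=" * 48,
            f"genes (input / retained)   {self.model.expression.shape[0]:>8d} / "
            f"{self.filtered_expression.shape[0]}",
            f"samples                    {self.model.expression.shape[1]:>8d}",
            f"TPM floor (3-sigma)        {self.tpm_threshold.threshold:>12.4g}",
            f"PCC cuts [neg, pos]        [{self.pcc_thresholds.neg_cut:.4f}, "
            f"{self.pcc_thresholds.pos_cut:.4f}] (offset {self.pcc_thresholds.offset:g})",
            f"MR rules                   MR < {p['mr_cut']:g} {p['combine']} "
            f"min-rank < {p['uni_cut']}",
            f"soft power beta            {self.beta:>8d}"
            + (" (auto)" if p["beta"] is None else ""),
            f"TOM cutoff                 {p['tom_cut']:>10.3g}",
            f"integration                {p['integration']:>8s}",
            "-" * 48,
            f"edges: pcc / mr / tom      {len(self.pcc_edges)} / {len(self.mr_edges)}"
            f" / {len(self.tom_edges)}",
            f"edges: integrated          {self.stats.n_edges:>8d}",
            f"genes in network           {self.stats.n_genes_in_network:>8d} "
            f"({self.stats.gene_coverage_pct:.2f}% coverage)",
            f"mean connectivity          {self.stats.mean_connectivity:>10.3f}",
            f"negative edges             {self.stats.pct_negative_edges:>9.2f}%",
        ]
        if self.aucs:
            lines.append("-" * 48)
            for name, auc in self.aucs.items():
                lines.append(f"AUC ({name:<11s})          {auc:>8.4f}")
        if self.offset_optimization is not None:
            lines.append(
                f"best PCC offset            "
                f"{self.offset_optimization.best_offset:>8.2f}"
            )
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, str]:
        """Materialize every stage output plus a run manifest; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        def _record(name: str, path: Path) -> None:
            paths[name] = str(path)

        write_edges_tsv(self.edges, outdir / "network.tsv")
        _record("network", outdir / "network.tsv")
        write_edges_tsv(self.pcc_edges, outdir / "edges_pcc.tsv")
        write_edges_tsv(self.mr_edges, outdir / "edges_mr.tsv")
        write_edges_tsv(self.tom_edges, outdir / "edges_tom.tsv")
        self.removal_report.to_csv(outdir / "removed_genes.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        stats = self.stats.as_dict()
        stats["tpm_threshold"] = self.tpm_threshold.threshold
        stats["beta"] = self.beta
        stats["aucs"] = self.aucs
        (outdir / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
        _record("stats", outdir / "stats.json")
        if self.softpower is not None:
            tbl = self.softpower.candidates.copy()
            tbl["selected"] = (tbl["beta"] == self.beta).astype(int)
            tbl.to_csv(outdir / "softpower.tsv", sep="\t", index=False,
                       float_format="%.10g")
            _record("softpower", outdir / "softpower.tsv")
        if self.offset_optimization is not None:
            self.offset_optimization.table.to_csv(
                outdir / "auc_table.tsv", sep="\t", index=False, float_format="%.10g")
            _record("auc_table", outdir / "auc_table.tsv")
        manifest = {
            "package": "cenweaver",
            "version": __version__,
            "parameters": _jsonable(self.model.params),
            "input": {
                "n_genes": self.model.expression.shape[0],
                "n_samples": self.model.expression.shape[1],
                "checksum": _matrix_checksum(self.model.expression),
            },
            "tpm_threshold": asdict(self.tpm_threshold),
            "pcc_thresholds": asdict(self.pcc_thresholds),
            "beta": self.beta,
            "flagged_outlier_samples": (
                list(self.sample_clustering.flagged_outliers)
                if self.sample_clustering is not None else []
            ),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        _record("manifest", outdir / "manifest.json")
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _matrix_checksum(m: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update("\n".join(m.gene_ids).encode())
    h.update("\n".join(m.sample_ids).encode())
    h.update(np.ascontiguousarray(m.values).tobytes())
    return h.hexdigest()
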