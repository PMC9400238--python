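"""Seeded synthetic TPM matrices with planted co-expression structure.

The generator emulates the statistical features the pipeline assumes of a
bulk RNA-seq TPM matrix: groups of co-regulated genes following shared latent
sample profiles (smooth random walks, mimicking developmental / tissue
gradients), a fraction of module genes loading negatively (anti-correlated
regulators), uncorrelated background genes, and a planted set of
low-expression genes sitting below the intended 3-sigma TPM floor.
Expression is log-normal in abundance with a linear module response:
``TPM = exp(baseline + noise) * (1 + strength * sign * z_module)`` where the
module profile z is bounded to keep TPM positive. The response is linear on
the abundance scale deliberately: it makes a noiseless pair of module genes
correlate at exactly +1 or -1 regardless of loading signs, whereas a
log-additive signed loading cannot reach -1 after exponentiation (the
Pearson correlation of two anti-dependent log-normals is bounded well above
-1), which would leave planted anti-correlated pairs undetectable on the
TPM scale the pipeline actually measures. Everything is deterministic given
the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import GoldStandardPairs
from .expression import ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "gold_standard_from_truth"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults define the package's reference scenario.

    200 genes x 40 samples: four planted modules of 30 genes, 10 planted
    low-expression genes (uniform below ``low_expr_ceiling`` TPM), and 70
    uncorrelated background genes. ``module_strength`` is the relative
    amplitude of the module response on the abundance scale (must stay below
    1 to keep TPM positive); with log-scale noise 0.25 the default 0.9 puts
    within-module |PCC| around 0.7-0.8, where tightly co-regulated modules
    sit in bulk RNA-seq.
    """

    n_genes: int = 200
    n_samples: int = 40
    module_sizes: tuple[int, ...] = (30, 30, 30, 30)
    anti_corr_fraction: float = 0.2
    noise_sd: float = 0.25
    module_strength: float = 0.9
    n_low_expr_genes: int = 10
    low_expr_ceiling: float = 0.01
    baseline_log_tpm_range: tuple[float, float] = (0.0, 4.0)
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes) - self.n_low_expr_genes

    def validate(self) -> None:
        if any(s < 0 for s in self.module_sizes) or self.n_low_expr_genes < 0:
            raise ValueError("counts must be non-negative")
        if self.n_background < 0:
            raise ValueError(
                "module sizes plus low-expression genes exceed n_genes "
                f"({sum(self.module_sizes)} + {self.n_low_expr_genes} > {self.n_genes})"
            )
        if not 0.0 <= self.anti_corr_fraction <= 1.0:
            raise ValueError("anti_corr_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.module_strength < 1.0:
            raise ValueError("module_strength must be in [0, 1) to keep TPM positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated matrix plus its ground truth.

    ``module_of`` maps every gene to its module id (0 = background or planted
    low-expression); ``loading_sign`` gives each module gene's loading
    direction.
    """

    matrix: ExpressionMatrix
    module_of: dict[str, int]
    loading_sign: dict[str, str]
    low_expression_genes: tuple[str, ...]
    config: SyntheticConfig = field(repr=False, default=None)

    def module_genes(self, module: int | None = None) -> list[str]:
        if module is None:
            return [g for g, m in self.module_of.items() if m > 0]
        return [g for g, m in self.module_of.items() if m == module]


def _latent_profiles(rng: np.random.Generator, n_modules: int, n_samples: int) -> np.ndarray:
    """Mutually orthogonal smooth standardized random walks across samples.

    Independent random walks are frequently correlated by chance (spurious
    Brownian correlation), which would make cross-module "negative" pairs
    genuinely co-expressed and contradict the ground-truth labels; successive
    Gram-Schmidt projection removes that while keeping the profiles smooth.
    """
    if n_modules > max(n_samples - 1, 0):
        raise ValueError("cannot plant more orthogonal modules than samples - 1")
    Z = np.empty((n_modules, n_samples))
    for m in range(n_modules):
        z = np.cumsum(rng.standard_normal(n_samples))
        z = z - z.mean()
        for prev in Z[:m]:
            z = z - (z @ prev) / (prev @ prev) * prev
        peak = np.abs(z).max()
        Z[m] = z / peak if peak > 0 else z  # bounded to [-1, 1], zero mean
    return Z


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw a synthetic TPM matrix with planted modules and ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    sample_ids = [f"s{j:02d}" for j in range(1, cfg.n_samples + 1)]
    lo, hi = cfg.baseline_log_tpm_range
    X = np.empty((cfg.n_genes, cfg.n_samples))
    module_of: dict[str, int] = {}
    loading_sign: dict[str, str] = {}
    cursor = 0
    latents = _latent_profiles(rng, cfg.n_modules, cfg.n_samples)
    for m, size in enumerate(cfg.module_sizes, start=1):
        z = latents[m - 1]
        for _ in range(size):
            g = gene_ids[cursor]
            baseline = rng.uniform(lo, hi)
            s = -1.0 if rng.random() < cfg.anti_corr_fraction else 1.0
            eps = rng.standard_normal(cfg.n_samples) * cfg.noise_sd
            X[cursor] = np.exp(baseline + eps) * (1.0 + s * cfg.module_strength * z)
            module_of[g] = m
            loading_sign[g] = "+" if s > 0 else "-"
            cursor += 1
    for _ in range(cfg.n_background):
        g = gene_ids[cursor]
        baseline = rng.uniform(lo, hi)
        eps = rng.standard_normal(cfg.n_samples) * cfg.noise_sd
        X[cursor] = np.exp(baseline + eps)
        module_of[g] = 0
        loading_sign[g] = "+"
        cursor += 1
    low_genes = []
    for _ in range(cfg.n_low_expr_genes):
        g = gene_ids[cursor]
        X[cursor] = rng.uniform(0.0, cfg.low_expr_ceiling, size=cfg.n_samples)
        module_of[g] = 0
        loading_sign[g] = "+"
        low_genes.append(g)
        cursor += 1
    df = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return SyntheticDataset(
        matrix=ExpressionMatrix(df),
        module_of=module_of,
        loading_sign=loading_sign,
        low_expression_genes=tuple(low_genes),
        config=cfg,
    )


def gold_standard_from_truth(
    d: SyntheticDataset, neg_ratio: float = 1.0, seed: int = 0
) -> GoldStandardPairs:
    """Labeled pairs from the planted truth.

    Positives are all within-module pairs; negatives are a seeded sample of
    pairs from different modules or the background. Planted low-expression
    genes are excluded from both sides, since the pipeline removes them
    before any correlation is computed.
    """
    low = set(d.low_expression_genes)
    genes = sorted(g for g in d.module_of if g not in low)
    positives, negative_pool = [], []
    for a, b in itertools.combinations(genes, 2):
        ma, mb = d.module_of[a], d.module_of[b]
        if ma > 0 and ma == mb:
            positives.append((a, b))
        else:
            negative_pool.append((a, b))
    if not positives:
        raise ValueError("no module of size >= 2: no positive pairs exist")
    rng = np.random.default_rng(seed)
    n_neg = min(int(round(neg_ratio * len(positives))), len(negative_pool))
    chosen = rng.choice(len(negative_pool), size=n_neg, replace=False)
    negatives = [negative_pool[i] for i in sorted(chosen)]
    df = pd.DataFrame(
        [(a, b, "positive") for a, b in positives]
        + [(a, b, "negative") for a, b in negatives],
        columns=["gene_a", "gene_b", "label"],
    )
    return GoldStandardPairs(pairs=df, source="planted-modules", seed=seed)
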