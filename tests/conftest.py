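import numpy as np
import pandas as pd
import pytest

import cenweaver as cw


def make_matrix(values, gene_ids=None, sample_ids=None) -> cw.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(s)]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=sample_ids)
    return cw.ExpressionMatrix(df)


@pytest.fixture
def toy_matrix() -> cw.ExpressionMatrix:
    """Four genes over five samples with hand-checkable correlations.

    g2 = 2*g1 (PCC +1), g3 is g1 reversed (PCC -1), and PCC(g1, g4) = 0.8.
    """
    return make_matrix([
        [1, 2, 3, 4, 5],
        [2, 4, 6, 8, 10],
        [5, 4, 3, 2, 1],
        [1, 3, 2, 5, 4],
    ])


@pytest.fixture
def toy_corr(toy_matrix) -> cw.CorrelationMatrix:
    return cw.compute_pcc(toy_matrix)


@pytest.fixture(scope="session")
def default_dataset() -> cw.SyntheticDataset:
    return cw.generate(cw.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_gold(default_dataset) -> cw.GoldStandardPairs:
    return cw.gold_standard_from_truth(default_dataset, seed=11)


@pytest.fixture(scope="session")
def fitted(default_dataset, default_gold) -> cw.CoexpressionNetworkResults:
    model = cw.CoexpressionNetwork(default_dataset.matrix, gold_standard=default_gold)
    return model.fit()


def random_edge_table(rng: np.random.Generator, n_genes: int = 12,
                      n_edges: int = 15, method: str = "pcc") -> pd.DataFrame:
    """A random valid edge table over genes g01..g{n_genes}."""
    genes = [f"g{i:02d}" for i in range(1, n_genes + 1)]
    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    rows = []
    for i in sorted(idx):
        a, b = pairs[i]
        pcc = float(rng.uniform(-1, 1))
        rows.append({
            "gene_a": a, "gene_b": b, "pcc": pcc,
            "mr": float(rng.uniform(1, 50)), "tom": float(rng.uniform(0, 1)),
            "sign": "-" if pcc < 0 else "+", "methods": method,
        })
    from cenweaver.edges import canonical_edge_table
    return canonical_edge_table(pd.DataFrame(rows))
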