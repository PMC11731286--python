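import numpy as np
import pandas as pd
import pytest

from tempotrend.containers import CountMatrix
from tempotrend.simulate import SimulationConfig, simulate_counts


def make_count_matrix(counts, genotypes=None, weeks=None, lengths=None,
                      biotype="protein_coding", secreted=None, surface=None):
    """Build a CountMatrix from a plain array for hand-constructed cases."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gid = [f"g{i:03d}" for i in range(n_genes)]
    sid = [f"s{j:02d}" for j in range(n_samples)]
    genotypes = genotypes or ["CRE"] * (n_samples // 2) + ["KPC"] * (n_samples - n_samples // 2)
    weeks = weeks if weeks is not None else [4] * n_samples
    samples = pd.DataFrame(
        {"genotype": genotypes, "week": weeks, "replicate": range(1, n_samples + 1)},
        index=pd.Index(sid, name="sample_id"),
    )
    genes = pd.DataFrame(
        {
            "length_bp": lengths if lengths is not None else [1000] * n_genes,
            "biotype": biotype if isinstance(biotype, list) else [biotype] * n_genes,
            "secreted": secreted if secreted is not None else [False] * n_genes,
            "cell_surface": surface if surface is not None else [False] * n_genes,
        },
        index=pd.Index(gid, name="gene_id"),
    )
    return CountMatrix(pd.DataFrame(counts, index=gid, columns=sid).astype(np.int64), samples, genes)


@pytest.fixture(scope="session")
def small_sim():
    """A small but full five-week simulated dataset with planted effects."""
    cfg = SimulationConfig(
        n_genes=400, n_trend_up=8, n_trend_down=8, n_late=12,
        enrich_planted_annotation=True, seed=11,
    )
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth
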