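import numpy as np
import pandas as pd
import pytest

from methlink.simulate import (
    SimConfig,
    generate_reference,
    simulate_expression,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def small_sim():
    """One small ground-truthed simulation shared across tests."""
    cfg = SimConfig(seed=11, chrom_length=300_000, n_genes=25)
    reference, genes = generate_reference(cfg)
    sites, truth = simulate_methylome(cfg, reference, genes)
    counts, lengths, truth = simulate_expression(
        cfg, genes, truth.promoter_methylation, truth
    )
    return {
        "config": cfg,
        "reference": reference,
        "genes": genes,
        "sites": sites,
        "counts": counts,
        "lengths": lengths,
        "truth": truth,
    }


def make_site_table(rows, samples):
    """Tiny hand-built cytosine table.

    ``rows``: list of (chrom, pos, strand, context, {sample: (m, u)}).
    """
    data = []
    for chrom, pos, strand, context, counts in rows:
        rec = {"chrom": chrom, "pos": pos, "strand": strand, "context": context}
        for s in samples:
            m, u = counts.get(s, (0, 0))
            rec[f"m_{s}"] = m
            rec[f"u_{s}"] = u
        data.append(rec)
    return pd.DataFrame(data)


@pytest.fixture
def toy_design():
    return pd.Series(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, name="group"
    ).rename_axis("sample")


@pytest.fixture
def rng():
    return np.random.default_rng(7)
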