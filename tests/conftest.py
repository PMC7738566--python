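import numpy as np
import pandas as pd
import pytest

import enhancerkit as ek


@pytest.fixture(scope="session")
def small_sim():
    """Compact synthetic study: 3 cancer types x 60 samples, 6 planted pairs."""
    cfg = ek.demo_config(
        seed=7, n_cancer_types=3, samples_per_type=60, n_pairs=6, n_genes=60,
        n_chroms=2, chrom_length=5_000_000, n_noise=12,
    )
    return ek.simulate.simulate_all(cfg)


@pytest.fixture(scope="session")
def small_catalog(small_sim):
    cfg = small_sim.config
    return ek.call_enhancers(small_sim.calls, small_sim.genome.genes, cfg.replicate_map())


def random_calls(rng, n, chroms=("chr1", "chr2"), span=1_000_000, max_len=5_000):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(200, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
            "name": [f"c{i}" for i in range(n)],
            "rpkm": rng.uniform(1, 10, size=n),
            "strand": ".",
            "cell_line": rng.choice(["CL1", "CL2", "CL3"], size=n),
        }
    )


def random_genes(rng, n, chroms=("chr1", "chr2"), span=1_000_000):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(2_000, 20_000, size=n)
    strands = rng.choice(["+", "-"], size=n)
    df = pd.DataFrame(
        {
            "gene_id": [f"G{i:03d}" for i in range(n)],
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
        }
    )
    df["utr5_anchor"] = np.where(df["strand"] == "+", df["start"], df["end"])
    df["utr3_anchor"] = np.where(df["strand"] == "+", df["end"], df["start"])
    return df
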