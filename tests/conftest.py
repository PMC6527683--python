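import numpy as np
import pandas as pd
import pytest

from prenet import synthetic


@pytest.fixture(scope="session")
def sim_data():
    """One default-condition synthetic dataset shared across read-only tests."""
    return synthetic.simulate(synthetic.SimConfig(seed=11))


@pytest.fixture()
def toy_catalogue():
    """Two-SNP worked example: s1 carries PEX evidence from 3 experiments,
    s2 repressive evidence from 1, both targeting gene G in bucket T."""
    return pd.DataFrame(
        {
            "snp_id": ["s1", "s2"],
            "feature_id": ["f1", "f2"],
            "feature_type": ["enhancer", "repressor"],
            "reg_class": ["PEX", "R"],
            "cell_raw": ["CD4_T_primary", "CD4_T_primary"],
            "bucket": ["T", "T"],
            "n_experiments": [3, 1],
            "target_gene": ["G", "G"],
        }
    )


def random_mini_catalogue(rng: np.random.Generator, max_rows: int = 20):
    """Small random evidence table + region map for oracle comparisons."""
    n = int(rng.integers(1, max_rows + 1))
    snps = [f"s{i}" for i in range(4)]
    genes = [f"g{i}" for i in range(5)]
    buckets = ["T", "B"]
    cat = pd.DataFrame(
        {
            "snp_id": rng.choice(snps, n),
            "feature_id": [f"f{i}" for i in range(n)],
            "feature_type": "enhancer",
            "reg_class": rng.choice(["PEX", "ZQI", "R"], n),
            "cell_raw": "x",
            "bucket": rng.choice(buckets, n),
            "n_experiments": rng.integers(1, 6, n),
            "target_gene": rng.choice(genes, n),
        }
    )
    region_snps = {
        1: set(rng.choice(snps, size=int(rng.integers(1, 4)), replace=False)),
        2: set(rng.choice(snps, size=int(rng.integers(1, 3)), replace=False)),
    }
    return cat, region_snps


def brute_force_pre(region_snps, catalogue, totals, dosage=None):
    """Independent triple-loop PRE oracle: iterate (region, SNP-match, row)."""
    sign = {"PEX": 1.0, "ZQI": 0.0, "R": -1.0}
    out: dict = {}
    for region, snps in region_snps.items():
        for row in catalogue.itertuples(index=False):
            if row.snp_id not in snps:
                continue
            d = 1.0 if dosage is None else dosage.get(row.snp_id, 1.0)
            key = (row.target_gene, region, row.bucket)
            out[key] = out.get(key, 0.0) + (
                d * sign[row.reg_class] * row.n_experiments / totals[row.bucket]
            )
    return out
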