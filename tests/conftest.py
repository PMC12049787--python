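import numpy as np
import pandas as pd
import pytest

from asoctools import ASoCSimConfig, simulate_allelic_counts


def make_record(snp_id="rs1", ref_count=10, alt_count=10, gt="0/1",
                chrom="chr8", pos=27_608_798, sample_id="d0", **extra):
    row = {
        "snp_id": snp_id, "chrom": chrom, "pos": pos,
        "ref_allele": "T", "alt_allele": "C", "sample_id": sample_id,
        "gt": gt, "ref_count": ref_count, "alt_count": alt_count,
    }
    row.update(extra)
    return row


@pytest.fixture
def record_table():
    """Small hand-built allelic count table exercising the filter boundaries."""
    return pd.DataFrame([
        make_record("rs_depth19", 10, 9),            # depth 19 < 20
        make_record("rs_boundary", 18, 2),           # depth 20, min allele 2
        make_record("rs_allele1", 19, 1),            # min allele 1 < 2
        make_record("rs_hom", 30, 0, gt="0/0"),      # not heterozygous
        make_record("rs_phased", 12, 12, gt="0|1"),  # phased het passes
        make_record("rs_big", 200, 0),               # min allele 0 -> excluded
        make_record("rs_imb", 90, 10),               # strong imbalance
        make_record("rs_imb", 85, 15, sample_id="d1"),
    ])


@pytest.fixture(scope="session")
def null_records():
    """Global-null simulated records shared across tests."""
    cfg = ASoCSimConfig(n_snps=2000, n_donors=10, het_prob=0.5,
                        depth_mean=60.0, frac_imbalanced=0.0, ref_bias=1.0, seed=42)
    records, truth = simulate_allelic_counts(cfg)
    return records, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
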