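import numpy as np
import pandas as pd
import pytest

from methylbmi import (BetaMatrix, ProbeAnnotation, ReferenceProfiles,
                       SynthConfig, simulate_cohort,
                       simulate_reference_profiles)


@pytest.fixture(scope="session")
def small_cohort():
    """Clean 80-sample cohort (no noise obstacles) for downstream stages."""
    cfg = SynthConfig(n_samples=80, n_probes=400, n_causal=8, noise_sd=0.02,
                      missing_rate=0.0, n_batches=1, batch_shift_sd=0.0,
                      seed=5)
    refs = simulate_reference_profiles(400, 10, 0.75, seed=5)
    return simulate_cohort(cfg, refs), refs


@pytest.fixture(scope="session")
def messy_cohort():
    """Cohort with missing values and batch structure for QC tests."""
    cfg = SynthConfig(n_samples=60, n_probes=200, n_causal=5, noise_sd=0.02,
                      missing_rate=0.05, n_batches=3, batch_shift_sd=0.05,
                      seed=9)
    refs = simulate_reference_profiles(200, 8, 0.75, seed=9)
    return simulate_cohort(cfg, refs), refs


def make_annotation(probe_ids, chrom=None, region=None, cgi=None, snp=None,
                    gene=None):
    n = len(probe_ids)
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids,
        "chr": chrom if chrom is not None else ["1"] * n,
        "pos": np.arange(1, n + 1),
        "gene": gene if gene is not None else [""] * n,
        "region_group": region if region is not None else ["Body"] * n,
        "cgi_relation": cgi if cgi is not None else ["open_sea"] * n,
        "snp_flag": snp if snp is not None else [False] * n,
    }))


def make_beta(values, probe_prefix="cg", sample_prefix="S"):
    values = np.asarray(values, dtype=float)
    return BetaMatrix(values,
                      [f"{probe_prefix}{i}" for i in range(values.shape[0])],
                      [f"{sample_prefix}{j}" for j in range(values.shape[1])])
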