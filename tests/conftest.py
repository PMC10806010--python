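import numpy as np
import pandas as pd
import pytest

from myotcr import diversity
from myotcr.model import Compartment, RepertoireSample
from myotcr.simulate import CohortConfig, generate_cohort


def make_sample(
    counts,
    sample_id="S1",
    subject_id="P01",
    compartment=Compartment.MUSCLE,
    cdr3s=None,
    v_genes=None,
):
    """Build a small RepertoireSample from a count vector."""
    n = len(counts)
    if cdr3s is None:
        cdr3s = [f"CA{_spell(i)}F" for i in range(n)]  # distinct, valid
    if v_genes is None:
        v_genes = [f"TRBV{(i % 7) + 2}" for i in range(n)]
    table = pd.DataFrame(
        {
            "v_gene": v_genes,
            "cdr3_aa": cdr3s,
            "j_gene": "TRBJ2-1",
            "umi_count": list(counts),
        }
    )
    return RepertoireSample(sample_id, subject_id, compartment, table)


def _spell(i):
    # fixed-width base-20 spelling of i over the amino-acid alphabet, so
    # every index maps to a distinct CDR3 core
    alpha = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for _ in range(5):
        out.append(alpha[i % 20])
        i //= 20
    return "".join(out)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    config = CohortConfig(n_patients=5, n_controls=2, clones_per_sample=600,
                          depth_reads=15_000)
    return generate_cohort(config, seed=11), config


@pytest.fixture(scope="session")
def small_cohort_subsampled(small_cohort):
    (samples, meta, truth), config = small_cohort
    sub = [diversity.subsample_reads(s, depth=10_000, seed=i)
           for i, s in enumerate(samples)]
    return sub, meta, truth, config
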