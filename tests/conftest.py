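import numpy as np
import pandas as pd
import pytest

from hifburden import ExpressionExperiment, VariantObservation, Consequence
from hifburden.datasets import discovery_cohort


@pytest.fixture(scope="session")
def cohort():
    """Packaged discovery cohort: observations plus cohort metadata."""
    return discovery_cohort()


@pytest.fixture
def observation_factory():
    def make(**kw):
        defaults = dict(
            individual_id="P01",
            gene="VHL",
            chrom="chr3",
            pos=10_183_605,
            ref="C",
            alt="T",
            consequence=Consequence.MISSENSE,
            maf=0.00299,
        )
        defaults.update(kw)
        return VariantObservation(**defaults)

    return make


def build_two_group_experiment(counts_array, n_per_side, gene_prefix="g"):
    """Wrap a (genes x 2n) count array as hypoxia-vs-normoxia controls."""
    n_genes = counts_array.shape[0]
    cols = [f"h{i}" for i in range(n_per_side)] + [
        f"n{i}" for i in range(n_per_side)
    ]
    counts = pd.DataFrame(
        np.asarray(counts_array, dtype=int),
        index=[f"{gene_prefix}{i}" for i in range(n_genes)],
        columns=cols,
    )
    samples = pd.DataFrame(
        {
            "group": "control",
            "condition": ["hypoxia"] * n_per_side + ["normoxia"] * n_per_side,
            "individual": cols,
            "replicate": "biological",
        },
        index=cols,
    )
    lengths = pd.Series(1000, index=counts.index)
    return ExpressionExperiment(counts, lengths, samples), cols[:n_per_side], cols[n_per_side:]
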