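import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from somaclone import Sample, SampleMeta, VariantTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_table(alt, depth, samples=None, chrom="1", ids=None):
    """Build a VariantTable from plain arrays (test helper)."""
    alt = np.atleast_2d(np.asarray(alt))
    depth = np.atleast_2d(np.asarray(depth))
    n, s = alt.shape
    samples = samples or [f"S{i}" for i in range(s)]
    ids = ids if ids is not None else [f"m{i:04d}" for i in range(n)]
    index = pd.Index(ids, name="mutation_id")
    chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.arange(1, n + 1) * 100, "ref": "A", "alt": "T"},
        index=index,
    )
    return VariantTable(
        sites,
        pd.DataFrame(alt, index=index, columns=samples),
        pd.DataFrame(depth, index=index, columns=samples),
    )


def make_meta(samples, sex="female", matched=None):
    matched = matched if matched is not None else [True] * len(samples)
    return SampleMeta(
        [
            Sample(sample_id=s, tissue=f"t{i}", is_matched_reference=m, sex=sex)
            for i, (s, m) in enumerate(zip(samples, matched))
        ]
    )


@pytest.fixture
def two_sample_meta():
    return make_meta(["S0", "S1"])
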