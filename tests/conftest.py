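import numpy as np
import pandas as pd
import pytest

from planktrace import SVTable, SampleMetadata, TaxonomyMap


def make_table(data: dict, sv_ids) -> SVTable:
    """Small SV table from {sample_id: counts} columns."""
    return SVTable(pd.DataFrame(data, index=list(sv_ids)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_table(rng):
    """20 SVs x 10 samples of moderately sparse random counts."""
    counts = rng.integers(0, 50, size=(20, 10))
    return SVTable(
        pd.DataFrame(
            counts,
            index=[f"SV{i:03d}" for i in range(20)],
            columns=[f"samp{j}" for j in range(10)],
        )
    )


@pytest.fixture
def monthly_meta():
    """Surface large-fraction sample per month, plus one deep sample."""
    frame = pd.DataFrame(
        {
            "month": ["m1", "m2", "m3", "m3"],
            "depth_m": [10.0, 10.0, 10.0, 5000.0],
            "fraction": ["large"] * 4,
        },
        index=["s1", "s2", "s3", "s3deep"],
    ).rename_axis("sample_id")
    return SampleMetadata(frame)


def make_taxonomy(lineages: dict, trophic: dict | None = None) -> TaxonomyMap:
    trophic = trophic or {}
    frame = pd.DataFrame(
        {
            "lineage": pd.Series(lineages),
            "trophic_flag": pd.Series({k: trophic.get(k, "phototroph") for k in lineages}),
        }
    ).rename_axis("sv_id")
    return TaxonomyMap(frame)
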