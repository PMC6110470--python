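from pathlib import Path

import numpy as np
import pandas as pd
import pytest

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def published_deletions() -> pd.DataFrame:
    """Published deletion call set from two epilepsy cohorts (RE and GGE):
    cohort, chrom, start, end, z_score, printed length, genes."""
    return pd.read_csv(DATA / "published_deletions.tsv", sep="\t")


def make_targets(n: int, chrom: str = "chr1", start: int = 1000, spacing: int = 1200, length: int = 200) -> pd.DataFrame:
    """Evenly spaced synthetic targets on one chromosome."""
    starts = start + spacing * np.arange(n)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + length})


@pytest.fixture
def targets8() -> pd.DataFrame:
    return make_targets(8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
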