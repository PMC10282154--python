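import numpy as np
import pandas as pd
import pytest

from mrpath.summary_data import HarmonizedSet, SummaryStats


def make_harmonized(bx, by, sy, sx=None, names=("X", "Y")) -> HarmonizedSet:
    """HarmonizedSet straight from beta/SE vectors, for estimator tests."""
    bx = np.asarray(bx, dtype=float)
    if sx is None:
        sx = np.full_like(bx, 0.01)
    variants = [f"rs{i:03d}" for i in range(len(bx))]
    return HarmonizedSet(names[0], names[1], variants, bx, sx, by, sy)


def make_stats(rows, trait_name="trait", trait_type="continuous") -> SummaryStats:
    """SummaryStats from a list of dicts with any subset of canonical fields."""
    defaults = {"chrom": "1", "pos": 1000, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.01,
                "pval": 1e-8, "n": 10_000}
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults, variant_id=f"rs{i:03d}", pos=1000 + 2_000_000 * i)
        d.update(r)
        full.append(d)
    return SummaryStats(trait_name, trait_type, pd.DataFrame(full))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
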