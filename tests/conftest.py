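import numpy as np
import pandas as pd
import pytest

from myorra.intervals import PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peakset(rng, n, chrom_sizes, width_range=(50, 300), name="peaks"):
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms])
    widths = rng.integers(*width_range, size=n)
    ci = rng.integers(0, len(chroms), size=n)
    starts = (rng.random(n) * (lengths[ci] - widths)).astype(np.int64)
    df = pd.DataFrame(
        {"chrom": np.array(chroms)[ci], "start": starts, "end": starts + widths}
    )
    return PeakSet(name=name, df=df)


@pytest.fixture
def toy_chrom_sizes():
    return {"chr1": 1_000_000, "chr2": 800_000}
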