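import numpy as np
import pytest

from chromloop_v2g.intervals import GenomicInterval, LoopCall, Peak, PromoterWindow
from chromloop_v2g.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study, shared across tests (read-only)."""
    return simulate(SyntheticConfig())


def random_cre_instance(rng: np.random.Generator, cell_type: str = "CT"):
    """A random small peak/loop/promoter instance for oracle comparisons."""
    span = 100_000
    chroms = ["chr1", "chr2"][: int(rng.integers(1, 3))]

    def rand_iv(width_lo=50, width_hi=3000):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(width_lo, width_hi))
        return GenomicInterval(chrom, start, start + width)

    peaks = [Peak(rand_iv(100, 800), cell_type) for _ in range(int(rng.integers(5, 40)))]
    promoters = []
    for i in range(int(rng.integers(2, 15))):
        iv = rand_iv(2000, 2001)
        promoters.append(
            PromoterWindow(f"G{i}", iv, "+" if rng.integers(0, 2) else "-", iv.start + 1500)
        )
    loops = []
    for i in range(int(rng.integers(0, 25))):
        a = rand_iv(500, 2500)
        b_start = int(rng.integers(0, span))
        b_width = int(rng.integers(500, 2500))
        b = GenomicInterval(a.chrom, b_start, b_start + b_width)
        loops.append(
            LoopCall(a, b, cell_type, score=5.0, resolution=1000, name=f"l{i}")
        )
    return peaks, loops, promoters
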