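import numpy as np
import pytest

from pchtools.genome import GenomeLayout, GenomicInterval, tile_genome
from pchtools.tracks import SignalTrack


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout((("chrT", 8_000_000), ("chrU", 6_000_000)))


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    return GenomeLayout((("chrT", 20_000),))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_track(
    layout: GenomeLayout,
    rng: np.random.Generator,
    n_segments: int = 100,
    kind: str = "cpm",
    max_len: int = 500,
) -> SignalTrack:
    """Random sparse non-overlapping track for oracle comparisons."""
    segments = []
    for chrom, length in layout.chromosomes:
        pos = 0
        for _ in range(n_segments):
            gap = int(rng.integers(0, max_len))
            seg = int(rng.integers(1, max_len))
            start = pos + gap
            end = start + seg
            if end > length:
                break
            segments.append(
                (GenomicInterval(chrom, start, end), float(rng.normal()))
            )
            pos = end
    return SignalTrack.from_segments(layout, segments, kind=kind)
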