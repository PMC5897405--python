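import numpy as np
import pytest

from mthet.sam_io import AlignedRead, parse_cigar


def make_read(
    bases: str,
    position: int = 100,
    cigar: str | None = None,
    quality: int = 35,
    qualities=None,
    name: str = "r1",
    flag: int = 0,
    reference_name: str = "chrM",
) -> AlignedRead:
    """Construct a read with uniform (or explicit) qualities."""
    if cigar is None:
        cigar = f"{len(bases)}M"
    if qualities is None:
        qualities = tuple([quality] * len(bases))
    return AlignedRead(
        name=name,
        reference_name=reference_name,
        position=position,
        cigar=parse_cigar(cigar),
        bases=bases,
        qualities=tuple(qualities),
        flag=flag,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
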