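import numpy as np
import pytest

from methylselex import LigandLibrary

BASES = "ACGT"


def random_library(n=1000, L=30, seed=0, cycle=0, methylated=False, flank=""):
    """Uniform random library; flanks (if given) are outside the region."""
    rng = np.random.default_rng(seed)
    regions = ["".join(BASES[c] for c in row) for row in rng.integers(0, 4, (n, L))]
    reads = [flank + r + flank for r in regions]
    return LigandLibrary(
        reads=reads,
        cycle=cycle,
        methylated=methylated,
        random_region=(len(flank), L),
    )


def planted_library(insert, n=1000, L=30, seed=0, frac=1.0, offset=None):
    """Random library with ``insert`` planted in a fraction of reads."""
    rng = np.random.default_rng(seed)
    lib = random_library(n=n, L=L, seed=seed + 1)
    reads = list(lib.reads)
    n_plant = round(frac * n)
    for i in range(n_plant):
        off = (
            offset
            if offset is not None
            else int(rng.integers(0, L - len(insert) + 1))
        )
        r = reads[i]
        reads[i] = r[:off] + insert + r[off + len(insert):]
    return lib.replace_reads(reads)


@pytest.fixture
def uniform_library():
    return random_library(n=1000, L=30, seed=11)
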