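import numpy as np
import pytest

from chromlink.genome import GenomicInterval
from chromlink.simulate import StudyParams, generate_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 1), shared across tests."""
    return generate_study(StudyParams(), seed=1)


@pytest.fixture(scope="session")
def null_study():
    """The no-effect parameterization of the synthetic study (seed 1)."""
    return generate_study(StudyParams.null(), seed=1)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """Default study written to disk once per session."""
    outdir = tmp_path_factory.mktemp("study")
    generate_study(StudyParams(), seed=1, outdir=outdir)
    return outdir


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1_000_000, max_len=5_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_522)
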