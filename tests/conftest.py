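import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pirnakit.genomic_io import GenomicInterval
from pirnakit.hit_processing import GenomicHit
from pirnakit.synthetic_fixtures import generate_fixture

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_bundle():
    """The packaged study conditions: seed-1 synthetic bundle + truth."""
    return generate_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Seed-1 bundle written to disk for file-based / CLI tests."""
    out = tmp_path_factory.mktemp("fixture") / "bundle"
    generate_fixture(FIXTURE_SEED, out_dir=out)
    return out


def random_hits(rng: np.random.Generator, n: int, chrom: str = "chrT",
                chrom_len: int = 100_000) -> list[GenomicHit]:
    """Random stranded hits (26-32 nt) on one chromosome, sorted by start."""
    starts = np.sort(rng.integers(0, chrom_len - 32, size=n))
    hits = []
    for i, s in enumerate(starts):
        length = int(rng.integers(26, 33))
        strand = "+" if rng.random() < 0.5 else "-"
        hits.append(
            GenomicHit(f"p{i}", GenomicInterval(chrom, int(s), int(s) + length, strand), 1e-12)
        )
    return hits
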