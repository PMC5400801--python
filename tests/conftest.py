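import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mhcamp.simulate import (DESK_COVERAGE_RANGES, build_allele_database,
                             sample_population, simulate_study)


@pytest.fixture(scope="session")
def allele_db():
    """Small deterministic allele database (all loci, all variant classes)."""
    return build_allele_database(seed=1)


@pytest.fixture(scope="session")
def small_study():
    """A 6-sample noisy study at desk-scale coverage with ground truth."""
    return simulate_study(seed=11, n_samples=6,
                          coverage_ranges=DESK_COVERAGE_RANGES)


@pytest.fixture(scope="session")
def cohort_truth(allele_db):
    db, meta = allele_db
    return sample_population(db, meta, n_samples=12, n_trios=1, n_dyads=1,
                             seed=7)
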