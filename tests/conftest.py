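import numpy as np
import pytest

from sweepscan.core import GenomicInterval, GenotypeMatrix


def make_gm(dosages, positions=None, length=None, chrom="chr1"):
    """Build a GenotypeMatrix from a plain list of dosage rows."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites = dosages.shape[1]
    if positions is None:
        positions = np.arange(n_sites)
    positions = np.asarray(positions, dtype=np.int64)
    if length is None:
        length = int(positions[-1]) + 1 if n_sites else 1
    return GenotypeMatrix(GenomicInterval(chrom, 0, length), positions, dosages)


def random_gm(rng, n_ind=6, n_sites=12, missing_rate=0.0, length=None):
    """Random dosage matrix, optionally with missing entries."""
    from sweepscan.core import MISSING

    d = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
    # keep every column observable at least once
    if missing_rate > 0:
        miss = rng.random((n_ind, n_sites)) < missing_rate
        for j in range(n_sites):
            if miss[:, j].all():
                miss[rng.integers(n_ind), j] = False
        d[miss] = MISSING
    return make_gm(d, length=length)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def scaled_experiment():
    """The scaled-down training experiment, shared across acceptance checks.

    Simulates the balanced five-class corpus at the desk-scale study
    conditions, trains the classifier, and evaluates on held-out data.
    Session-scoped because the corpus simulation dominates the suite's
    runtime.
    """
    from sweepscan.pipeline import run_scaled_experiment

    return run_scaled_experiment(seed=2026)
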