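import numpy as np
import pytest

from cnvrscan.io_formats import CnvCall, SampleRecord, SnpMap
from cnvrscan.synthetic import SimConfig, generate_cohort


def make_sample(sid, phenotype="CONTROL", cohort="COH1", call_rate=0.995,
                lrr_sd=0.1, gc_wave=0.0, **kw):
    return SampleRecord(sid, cohort, phenotype, call_rate, lrr_sd, gc_wave, **kw)


@pytest.fixture(scope="session")
def tiny_map():
    """Three markers on chr1 at 100/200/300 plus two on chr2."""
    return SnpMap(
        [
            ("m1", "chr1", 100),
            ("m2", "chr1", 200),
            ("m3", "chr1", 300),
            ("n1", "chr2", 150),
            ("n2", "chr2", 400),
        ]
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Mid-size cohort with no planted structure (shared: generation is the
    expensive part)."""
    cfg = SimConfig(
        n_samples=2000,
        n_markers=10_000,
        seed=11,
        include_tracks=False,
        qc_fail_fractions={},
    )
    return generate_cohort(cfg)


def random_small_cohort(rng):
    """A random cohort of <= 50 samples / <= 200 markers for oracle checks.

    Returns (calls, snp_map, sample_ids). Markers sit on a 2 Mb chromosome
    so the 1 Mb span bound is actually exercised.
    """
    n_samples = int(rng.integers(5, 51))
    n_markers = int(rng.integers(10, 201))
    chrom_len = 2_000_000
    pos = np.sort(rng.choice(np.arange(1, chrom_len), size=n_markers, replace=False))
    snp_map = SnpMap([(f"r{i}", "chr1", int(p)) for i, p in enumerate(pos)])
    sample_ids = [f"T{i}" for i in range(n_samples)]
    calls = []
    for sid in sample_ids:
        for _ in range(int(rng.integers(0, 6))):
            s = int(rng.integers(1, chrom_len))
            e = min(s + int(rng.integers(1_000, 600_000)), chrom_len)
            cn = int(rng.choice([0, 1, 1, 3]))
            calls.append(CnvCall(sid, "chr1", s, e, cn))
    return calls, snp_map, sample_ids
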