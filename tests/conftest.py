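import numpy as np
import pytest

from medlsm import annotation as ann
from medlsm import simulate as sim


@pytest.fixture(scope="session")
def small_study():
    """A 100-gene genome with ground truth, shared across read-only tests."""
    return sim.make_genome(n_genes=100, frac_ic=0.5, frac_rp=0.25, seed=7)


@pytest.fixture(scope="session")
def curation_fixture():
    """Annotation + 127 planted peaks + HCRs with known bookkeeping."""
    return sim.make_curation_fixture(seed=0)


@pytest.fixture()
def toy_gene():
    return ann.Gene(
        id="toy1",
        name="TOY1",
        chrom="chrI",
        strand="+",
        cds_start=100,
        cds_end=400,
        exons=[(100, 200), (300, 400)],
    )


@pytest.fixture()
def flat_tracks():
    """Matched IP/control tracks of pure Poisson background."""
    from medlsm.chip import CoverageTrack

    rng = np.random.default_rng(0)
    ip = rng.poisson(1.0, 20_000).astype(float)
    ctl = rng.poisson(1.0, 20_000).astype(float)
    return (
        CoverageTrack("ip", 10, {"chr1": ip}, float(ip.sum())),
        CoverageTrack("ctl", 10, {"chr1": ctl}, float(ctl.sum())),
    )
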