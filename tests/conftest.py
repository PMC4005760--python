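import numpy as np
import pytest

from vdrmeta import (
    AnalysisParams,
    GenomicInterval,
    PeakCall,
    SampleSet,
    SimulationConfig,
    dr3_pwm,
    simulate_motif_peak_set,
    simulate_study,
)
from vdrmeta.simulate import _spaced_positions


@pytest.fixture(scope="session")
def pwm():
    return dr3_pwm()


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def study():
    """Full 6-cell-type, 12-sample synthetic study at default conditions."""
    return simulate_study(SimulationConfig(seed=42))


def make_jittered_samples(
    positions, n_samples=6, jitter=5, seed=0, chrom="chr1", fe=8.0
):
    """One sample per replicate, one peak per planted site with jittered summit."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_samples):
        peaks = []
        for pos in positions:
            s = int(pos) + int(rng.integers(-jitter, jitter + 1)) if jitter else int(pos)
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(chrom, s - 150, s + 150),
                    summit=s,
                    fold_enrichment=fe,
                    neg_log10_q=5.0,
                )
            )
        samples.append(
            SampleSet(sample_id=f"rep{i}", cell_type=f"ct{i}", stimulated=True, peaks=peaks)
        )
    return samples


@pytest.fixture(scope="session")
def planted_sites():
    """200 true sites spaced >= 400 bp on a 1 Mb chromosome (seed 42)."""
    rng = np.random.default_rng(42)
    return _spaced_positions(200, 1_000_000, 400, 200, rng)


@pytest.fixture(scope="session")
def jittered_samples(planted_sites):
    return make_jittered_samples(planted_sites, n_samples=6, jitter=5, seed=42)


@pytest.fixture(scope="session")
def motif_peak_set():
    """2,000 peaks with DR3 planting logistic in FE (default generator law)."""
    return simulate_motif_peak_set(2000, seed=0)
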