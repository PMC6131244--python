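import numpy as np
import pandas as pd
import pytest

from aiscape import GenomeLayout, PipelineConfig, SimulationConfig


@pytest.fixture(scope="session")
def toy_genome() -> GenomeLayout:
    return GenomeLayout.default_toy()


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-sample cohort with default event structure, shared across tests."""
    from aiscape import simulate_cohort
    return simulate_cohort(SimulationConfig(n_samples=12), seed=1234)


def make_probes(chrom="chr1", start=0, spacing=10_000, baf=None, lrr=None,
                sample_id="s1"):
    """Construct a probe table from explicit BAF/LRR arrays."""
    baf = np.asarray(baf, dtype=float)
    lrr = np.zeros_like(baf) if lrr is None else np.asarray(lrr, dtype=float)
    pos = start + spacing * np.arange(len(baf))
    return pd.DataFrame({"sample_id": sample_id, "chrom": chrom, "pos": pos,
                         "baf": baf, "lrr": lrr})


def make_segments(rows):
    """Segment table from (chrom, start, end, sample, klass, lrr, mbaf, n) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id",
                                       "klass", "mean_lrr", "mean_mbaf",
                                       "n_probes"])
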