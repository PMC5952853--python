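import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirdecay.io_formats import ExpressionMatrix, SampleMeta

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_design(times=(0.0, 2.0, 4.0, 8.0), replicates=2):
    samples = []
    for genotype in ("WT", "KO"):
        for t in times:
            for rep in range(1, replicates + 1):
                samples.append(SampleMeta(f"{genotype}_t{t:g}_r{rep}",
                                          genotype, t, rep))
    return samples


def make_matrix(rows: dict[str, list[float]], samples=None) -> ExpressionMatrix:
    """Rows are transcript -> values in canonical sample order
    (WT t0 r1, WT t0 r2, ..., KO t8 r2)."""
    samples = samples or make_design()
    df = pd.DataFrame(rows, index=[s.sample_id for s in samples]).T
    df.index.name = "transcript_id"
    return ExpressionMatrix(df, samples)


def exponential_rows(params: dict[str, tuple[float, float, float, float]],
                     times=(0.0, 2.0, 4.0, 8.0), replicates=2):
    """params: transcript -> (X_wt, D_wt, X_ko, D_ko); noiseless series."""
    rows = {}
    for tx, (x_wt, d_wt, x_ko, d_ko) in params.items():
        vals = []
        for x, d in ((x_wt, d_wt), (x_ko, d_ko)):
            for t in times:
                vals.extend([x * np.exp(-d * t)] * replicates)
        rows[tx] = vals
    return rows


@pytest.fixture
def toy_matrix():
    """3 decaying transcripts + 2 stable references, 16 samples."""
    params = {
        "txA": (40.0, 0.10, 44.0, 0.09),
        "txB": (100.0, 0.20, 100.0, 0.20),
        "txC": (25.0, 0.35, 25.0, 0.35),
        "refA": (200.0, 0.0, 200.0, 0.0),
        "refB": (150.0, 0.0, 150.0, 0.0),
    }
    return make_matrix(exponential_rows(params))


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
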