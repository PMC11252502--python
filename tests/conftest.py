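import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from viractive.tables_io import CountTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

ZONES = ("GR", "OR", "PL")


def make_count_table(counts: dict, lengths=None, zones=ZONES, assay=None) -> CountTable:
    """Build a CountTable from {sample_id: list-of-counts}.

    Sample ids of the form ``<zone>_<assay>`` are parsed into the map unless
    ``assay`` forces one assay for all samples.
    """
    df = pd.DataFrame(counts)
    n = len(df)
    if lengths is None:
        lengths = [10_000] * n
    idx = pd.Index([f"g{i + 1:03d}" for i in range(n)], name="genome_id")
    df.index = idx
    rows = []
    for s in df.columns:
        if assay is not None:
            zone, a = s.rsplit("_", 1)[0], assay
        else:
            zone, a = s.rsplit("_", 1)
        rows.append((s, zone, a))
    smap = pd.DataFrame(rows, columns=["sample_id", "zone", "assay"]
                        ).set_index("sample_id")
    return CountTable(df, pd.Series(lengths, index=idx, name="length"), smap)


@pytest.fixture
def toy_tables():
    from viractive.simulate import toy10

    return toy10()


@pytest.fixture
def small_community():
    """A 150-genome community for fast end-to-end and property tests."""
    from viractive.simulate import CommunitySpec, simulate_community

    spec = CommunitySpec(n_genomes=150, seed=7)
    return spec, simulate_community(spec)


def rng_nb_matrix(rng: np.random.Generator, n_genes: int, n_samples: int,
                  mean_scale: float = 50.0, dispersion: float = 0.2) -> np.ndarray:
    """Random negative-binomial count matrix with genewise lognormal means."""
    mu = rng.lognormal(np.log(mean_scale), 1.0, size=n_genes)
    depth = rng.uniform(0.5, 2.0, size=n_samples)
    mean = mu[:, None] * depth[None, :]
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean)).astype(np.int64) + (
        rng.random((n_genes, n_samples)) < 0.02)  # sprinkle of extra singletons
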