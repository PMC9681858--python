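import numpy as np
import pandas as pd
import pytest

from nbmeth.simgen import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared by read-only tests."""
    return generate_cohort(SimConfig(n_samples=100, seed=7))


@pytest.fixture()
def toy_manifest():
    """Six-probe manifest on two chromosomes for filter tests."""
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "1", "X", "2"],
            "pos": [100, 200, 300, 400, 500, 600],
            "arm": ["p"] * 5 + ["p"],
            "cross_reactive": [False, True, False, False, False, False],
            "snp_dist_bp": [np.nan, np.nan, 2.0, 3.0, np.nan, 2.0],
            "snp_maf": [np.nan, np.nan, 0.05, 0.5, np.nan, 0.04],
        },
        index=pd.Index([f"cg{i}" for i in range(6)], name="probe_id"),
    )


def block_distance(sizes, within, between, seed=0):
    """Symmetric distance matrix with block (cluster) structure."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    D = np.where(
        labels[:, None] == labels[None, :],
        within + rng.uniform(0, within + 1e-9, (n, n)),
        between + rng.uniform(0, 0.1, (n, n)),
    )
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = pd.Index([f"S{i}" for i in range(n)])
    return pd.DataFrame(D, index=ids, columns=ids), labels
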