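import numpy as np
import pytest
import scipy.sparse as sp

from spatialsig.core_io import SpotDataset
from spatialsig.preprocessing import normalize_log
from spatialsig.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted synthetic sample, shared across read-only tests."""
    dataset, polyline, truth = generate_dataset(SyntheticSpec(seed=1))
    return {
        "dataset": dataset,
        "polyline": polyline,
        "truth": truth,
        "norm": normalize_log(dataset),
    }


@pytest.fixture()
def toy_dataset():
    """3 genes x 4 spots with hand-checkable counts."""
    counts = np.array(
        [
            [0, 2, 0, 5],
            [1, 0, 0, 3],
            [4, 3, 0, 0],
        ]
    )
    return SpotDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(["ga", "gb", "gc"], dtype=object),
        spot_ids=np.array(["b1", "b2", "b3", "b4"], dtype=object),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        sample_ids=np.array(["s1"] * 4, dtype=object),
        regions=np.array(["blastema", "blastema", "digit", "digit"], dtype=object),
    )


def make_dataset(counts, regions=None, coords=None, sample="s1"):
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    return SpotDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array([f"g{i:03d}" for i in range(n_genes)], dtype=object),
        spot_ids=np.array([f"b{j:03d}" for j in range(n_spots)], dtype=object),
        coords=np.zeros((n_spots, 2)) if coords is None else np.asarray(coords, float),
        sample_ids=np.array([sample] * n_spots, dtype=object),
        regions=np.array(
            ["r"] * n_spots if regions is None else regions, dtype=object
        ),
    )
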