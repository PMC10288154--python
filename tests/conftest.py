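import numpy as np
import pytest
import scipy.sparse as sp

from scjointnmf import CountMatrix, MultiModalDataset, SimConfig, simulate_multimodal


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def small_sim(seed=1, noise_level="none", **kw):
    """A fast 3-cluster dual-modality dataset for unit tests."""
    cfg = SimConfig(
        n_clusters=3,
        cells_per_cluster=20,
        features_per_modality=(80, 140),
        modality_kinds=("rna", "atac"),
        d_true=6,
        noise_level=noise_level,
        seed=seed,
        **kw,
    )
    return simulate_multimodal(cfg)


@pytest.fixture
def small_dataset():
    data, _ = small_sim()
    return data


@pytest.fixture
def small_normalized(small_dataset):
    from scjointnmf import filter_features, median_library_normalize

    filtered = small_dataset.map(lambda cm: filter_features(cm, 3))
    return filtered.map(median_library_normalize)


def random_count_matrix(rng, m=10, n=6, name="rna", density=0.6):
    dense = np.where(rng.random((m, n)) < density, rng.integers(1, 20, (m, n)), 0)
    return CountMatrix(
        sp.csr_matrix(dense.astype(float)),
        [f"f{i}" for i in range(m)],
        [f"c{j}" for j in range(n)],
        modality_name=name,
        flavor="raw",
    )


def random_positive_factors(rng, shapes, d):
    """Strictly positive (W list, H) for given per-modality feature counts."""
    w_list = [rng.uniform(0.2, 2.0, (m, d)) for m in shapes[:-1]]
    h = rng.uniform(0.2, 2.0, (d, shapes[-1]))
    return w_list, h


def normalized_dataset_from_arrays(arrays, kinds=None):
    """Wrap dense arrays as a normalized MultiModalDataset (columns = cells)."""
    n = arrays[0].shape[1]
    cells = [f"c{j}" for j in range(n)]
    mods = []
    for v, arr in enumerate(arrays):
        kind = kinds[v] if kinds else f"m{v}"
        mods.append(
            CountMatrix(
                sp.csr_matrix(np.asarray(arr, dtype=float)),
                [f"{kind}_f{i}" for i in range(arr.shape[0])],
                cells,
                modality_name=kind,
                flavor="normalized",
            )
        )
    return MultiModalDataset(mods)
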