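import numpy as np
import pandas as pd
import pytest

from spotkit import SynthConfig, generate_section


@pytest.fixture(scope="session")
def small_section():
    """A small synthetic section with planted doublets and low-quality cells."""
    cfg = SynthConfig(
        n_cells=60,
        n_genes=24,
        transcripts_per_cell=150,
        extent_um=(350.0, 350.0),
        doublet_rate=0.1,
        low_quality_frac=0.1,
        seed=7,
    )
    return cfg, *generate_section(cfg)


@pytest.fixture()
def square_spots():
    """Unit-square corners plus edge midpoints on one z-plane."""
    pts = [(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0), (1, 0.5), (0.5, 1), (0, 0.5)]
    return pd.DataFrame({"x": [p[0] for p in pts], "y": [p[1] for p in pts], "z": 0.0})


def planted_doublet_counts(seed=0, n_singlets=200, n_doublets=30, n_types=4, n_genes=30):
    """Counts matrix of typed singlets plus summed cross-type doublet profiles."""
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.ones(n_genes) * 0.3, size=n_types)
    types = rng.integers(0, n_types, n_singlets)
    sing = np.vstack([rng.multinomial(150, profiles[t]) for t in types])
    pairs = [
        (i, j)
        for i, j in zip(rng.integers(0, n_singlets, 3 * n_doublets),
                        rng.integers(0, n_singlets, 3 * n_doublets))
        if types[i] != types[j]
    ][:n_doublets]
    doub = np.vstack([sing[i] + sing[j] for i, j in pairs])
    X = np.vstack([sing, doub])
    truth = np.array([False] * n_singlets + [True] * len(pairs))
    return X, truth
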