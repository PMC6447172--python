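import numpy as np
import pytest

from triazqsar import compound_data, mif_engine


@pytest.fixture(scope="session")
def triazine_table():
    return compound_data.load_triazine_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_molecule():
    """A 5-atom asymmetric molecule with mixed charges."""
    return mif_engine.Molecule(
        id=1,
        elements=["C", "N", "O", "H", "Cl"],
        coords=np.array(
            [[0.0, 0.0, 0.0], [1.4, 0.2, -0.3], [-1.1, 0.9, 0.4],
             [0.3, -1.0, 0.8], [2.1, -1.2, 0.1]]
        ),
        charges=np.array([0.2, -0.4, -0.3, 0.1, 0.4]),
    )


@pytest.fixture()
def small_grid():
    spec = mif_engine.GridSpec(extents=(6.0, 6.0, 6.0), spacing=2.0,
                               origin=(-3.0, -3.0, -3.0))
    return mif_engine.make_grid(spec)


def make_mif(values, kinds, indices, grid=None, ids=None):
    """Hand-build a MifMatrix (all columns kept) for unit tests."""
    values = np.asarray(values, dtype=float)
    n_cols = values.shape[1]
    return mif_engine.MifMatrix(
        molecule_ids=ids or list(range(1, values.shape[0] + 1)),
        kinds=np.asarray(kinds, dtype=object),
        grid_indices=np.asarray(indices, dtype=int),
        values=values,
        kept=np.ones(n_cols, dtype=bool),
        drop_reason=[None] * n_cols,
        grid=grid,
    )
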