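import numpy as np
import pytest

from msistream.store import SampleDataset, create_workspace


def make_sample(
    sample_id="s",
    n_pixels=6,
    n_features=4,
    rng=None,
    with_mask=False,
    mz=None,
):
    """Small random but valid sample dataset."""
    rng = rng or np.random.default_rng(0)
    if mz is None:
        mz = np.sort(rng.uniform(100, 1000, n_features))
    nx = int(np.ceil(np.sqrt(n_pixels)))
    coords = np.array([(i % nx, i // nx) for i in range(n_pixels)], dtype=np.int64)
    intens = rng.uniform(0, 100, size=(n_pixels, n_features))
    mask = rng.random(n_pixels) < 0.5 if with_mask else None
    return SampleDataset(sample_id=sample_id, mz=mz, intensities=intens, coords=coords, tissue_mask=mask)


@pytest.fixture
def sample_factory():
    return make_sample


@pytest.fixture
def workspace(tmp_path):
    ws = create_workspace(str(tmp_path / "ws.h5"))
    yield ws
    ws.close()


@pytest.fixture
def filled_workspace(tmp_path):
    """Workspace with 3 random samples sharing one m/z axis."""
    ws = create_workspace(str(tmp_path / "filled.h5"))
    rng = np.random.default_rng(42)
    mz = np.sort(rng.uniform(100, 1000, 8))
    for i in range(3):
        ws.add_sample(make_sample(f"s{i}", n_pixels=10, n_features=8, rng=rng, mz=mz, with_mask=True))
    yield ws
    ws.close()
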