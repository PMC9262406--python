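import nibabel as nib
import numpy as np
import pytest

from mvpdkit.io_volumes import RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mask():
    """3x3x2 mask with 4 scattered voxels."""
    grid = np.zeros((3, 3, 2), dtype=bool)
    grid[0, 0, 0] = grid[2, 1, 0] = grid[1, 2, 1] = grid[0, 1, 1] = True
    return RoiMask(grid=grid, affine=np.eye(4), label="small")


def save_nifti(path, data, affine=None, dtype=None):
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, affine if affine is not None else np.eye(4))
    if dtype is not None:
        img.header.set_data_dtype(dtype)
    nib.save(img, str(path))
    return path
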