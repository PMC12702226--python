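import numpy as np
import pytest

from asldyn.phantom import PhantomSpec, build_phantom
from asldyn.quantify import QuantParams


@pytest.fixture(scope="session")
def default_truth():
    """One default phantom, shared read-only across tests."""
    return build_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def quant59():
    return QuantParams(alpha=0.59)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def bfs_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Brute-force flood-fill component labelling, independent of skimage.

    Returns the list of components as sets of flat indices.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    if connectivity == 6:
        offsets = [
            (dx, dy, dz)
            for dx, dy, dz in [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        ]
    else:
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        stack = [idx]
        seen[idx] = True
        comp = set()
        while stack:
            x, y, z = stack.pop()
            comp.add(np.ravel_multi_index((x, y, z), shape))
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and mask[nx, ny, nz]
                    and not seen[nx, ny, nz]
                ):
                    seen[nx, ny, nz] = True
                    stack.append((nx, ny, nz))
        comps.append(comp)
    return comps
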