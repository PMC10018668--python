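import numpy as np
import pytest

import isomargin as im


@pytest.fixture(scope="session")
def u_margin2_rot1() -> im.SetupUncertainty:
    """The clinical evaluation setting: 2 mm translational margin, 1.0 deg rotational SD."""
    return im.SetupUncertainty.from_margin(2.0, 1.0)


@pytest.fixture(scope="session")
def u_translation_only() -> im.SetupUncertainty:
    return im.SetupUncertainty.from_margin(2.0, 0.0)


def brute_force_ptv(ts: im.TargetSet, isocenter, u: im.SetupUncertainty, grid: im.VoxelGrid):
    """Independent oracle: every voxel centre against every target and sample ball.

    Pure numpy broadcasting, no shared code with the painting kernel.
    """
    centers = grid.centers()
    inside = np.zeros(len(centers), dtype=bool)
    for t in ts.targets:
        if t.sphere_params is None:
            raise NotImplementedError("oracle covers analytic spheres only")
        c, d = t.sphere_params
        inside |= np.linalg.norm(centers - np.asarray(c), axis=1) <= 0.5 * d
        radii = im.margins(t.points, isocenter, u)
        dist = np.linalg.norm(centers[:, None, :] - t.points[None, :, :], axis=2)
        inside |= (dist <= radii[None, :]).any(axis=1)
    return inside.reshape(grid.shape)
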