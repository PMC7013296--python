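import numpy as np
import pytest

from mmar.mask import MyocardiumMask
from mmar.synthetic import (
    LvShellParams,
    TreeParams,
    generate_coronary_tree,
    generate_lv_shell,
)
from mmar.tree import CenterlineTree, Node


@pytest.fixture(scope="session")
def shell_params():
    return LvShellParams()


@pytest.fixture(scope="session")
def shell(shell_params):
    return generate_lv_shell(shell_params)


@pytest.fixture(scope="session")
def coronary_tree(shell_params):
    return generate_coronary_tree(shell_params, TreeParams(seed=42))


def make_slab(ny=10, nx=20, nz=6, spacing=1.0):
    """Rectangular slab with two straight vessels along opposite x-faces.

    Voxel centers sit at y = 0..ny-1 (world mm); vessel A runs along x at
    y = -0.5, vessel B at y = ny - 0.5, so the Voronoi midplane falls
    between voxel rows and splits the slab exactly in half when ny is even.
    """
    grid = np.ones((nx, ny, nz), dtype=bool)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    mask = MyocardiumMask(grid=grid, affine=affine)
    xs = np.linspace(0, (nx - 1) * spacing, 5)
    nodes = []
    nid = 0
    for artery, y in (("LAD", -0.5 * spacing), ("RCA", (ny - 0.5) * spacing)):
        parent = None
        for x in xs:
            nodes.append(
                Node(nid, np.array([x, y, (nz - 1) * spacing / 2]), parent, artery, "main")
            )
            parent = nid
            nid += 1
    tree = CenterlineTree(nodes)
    tree.validate()
    return mask, tree


@pytest.fixture()
def slab():
    return make_slab()
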