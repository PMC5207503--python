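import numpy as np
import pytest
import trimesh

from vbsalab.mesh_core import Mesh
from vbsalab.body_synth import BodyParams, make_body

UNIT_CUBE_OBJ = """\
# unit cube, 6 quads
v 0 0 0
v 1 0 0
v 1 1 0
v 0 1 0
v 0 0 1
v 1 0 1
v 1 1 1
v 0 1 1
f 1 2 3 4
f 5 8 7 6
f 1 5 6 2
f 2 6 7 3
f 3 7 8 4
f 4 8 5 1
"""


@pytest.fixture
def unit_cube_path(tmp_path):
    p = tmp_path / "cube.obj"
    p.write_text(UNIT_CUBE_OBJ)
    return p


def icosphere_mesh(subdivisions: int, radius: float = 5.0) -> Mesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Mesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def icosphere4():
    return icosphere_mesh(4)


@pytest.fixture(scope="session")
def default_params():
    return BodyParams(stature=175.0, girth=1.0, muscle_fat=0.5,
                      gender_shape=0.3, age=30.0)


@pytest.fixture(scope="session")
def default_body(default_params):
    return make_body(default_params)
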