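import numpy as np
import pytest
import trimesh as tm

from cardiosynth import TriMesh, build_lv, default_profile


@pytest.fixture(scope="session")
def unit_cube() -> TriMesh:
    box = tm.creation.box(extents=(1.0, 1.0, 1.0))
    return TriMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


@pytest.fixture(scope="session")
def default_model():
    return build_lv(default_profile())


def rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
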