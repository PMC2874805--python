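import numpy as np
import pytest

from bbscore.geometry import LocalFrame


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_frame(rng: np.random.Generator, scale: float = 5.0) -> LocalFrame:
    R = random_rotation(rng)
    return LocalFrame(
        origin=rng.normal(size=3) * scale,
        u_x=R[:, 0],
        u_y=R[:, 1],
        u_z=R[:, 2],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  CB  ALA A   1      12.217   4.681  -4.867  1.00  0.00           C
ATOM      5  N   GLY A   2      12.994   7.500  -3.730  1.00  0.00           N
ATOM      6  CA  GLY A   2      13.989   8.512  -3.430  1.00  0.00           C
ATOM      7  C   GLY A   2      13.481   9.905  -3.771  1.00  0.00           C
ATOM      8  N   LEU A   3      12.238  10.185  -3.398  1.00  0.00           N
ATOM      9  CA  LEU A   3      11.634  11.481  -3.667  1.00  0.00           C
ATOM     10  C   LEU A   3      10.191  11.496  -3.175  1.00  0.00           C
ATOM     11  CB  LEU A   3      11.691  11.794  -5.166  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p
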