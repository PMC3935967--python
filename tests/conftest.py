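import numpy as np
import pytest

from meftop.io_structures import Residue, StructureModel, annotate
from meftop.synthetic_fixtures import build_native


def ideal_helix_ca(n: int, radius: float = 2.3, rise: float = 1.5,
                   twist_deg: float = 100.0) -> np.ndarray:
    """CA trace of an ideal right-handed alpha helix."""
    t = np.arange(n, dtype=float)
    w = np.radians(twist_deg)
    return np.stack([radius * np.cos(w * t), radius * np.sin(w * t), rise * t], axis=1)


def extended_ca(n: int, rise: float = 3.8) -> np.ndarray:
    """Collinear fully extended CA trace."""
    return np.stack([rise * np.arange(n), np.zeros(n), np.zeros(n)], axis=1)


def model_from_ca(ca: np.ndarray, sequence: str | None = None,
                  scm: np.ndarray | None = None, model_id: str = "toy") -> StructureModel:
    """Build a StructureModel from a CA array (SCM defaults to CA)."""
    n = len(ca)
    sequence = sequence or "A" * n
    residues = []
    for i in range(n):
        s = scm[i] if scm is not None else ca[i]
        residues.append(Residue(index=i + 1, aa=sequence[i],
                                ca=np.asarray(ca[i], float), scm=np.asarray(s, float)))
    return StructureModel(model_id=model_id, residues=residues)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def mixed_native() -> StructureModel:
    """A mixed alpha/beta generated native fold, annotated."""
    return build_native(["H10", "E6", "E6", "H10", "H8"], seed=1)


@pytest.fixture(scope="session")
def helical_native() -> StructureModel:
    return build_native(["H10", "H9", "H11", "H8"], seed=3)
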