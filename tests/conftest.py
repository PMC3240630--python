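import numpy as np
import pytest

from ubamap import synthdata as sd
from ubamap.structgeom import StructureModel


@pytest.fixture
def mono_titration():
    """Noisy 10-point, 15-residue titration with true Kd 249 uM."""
    design = sd.TitrationDesign(rng_seed=11, true_kd_uM=249.0)
    return design, sd.gen_titration(design)


@pytest.fixture
def relax_design():
    return sd.RelaxDesign(rng_seed=7)


def make_model(xyz, element="C", chain="A", resnum=None, name="CA"):
    """Minimal synthetic structure from bare coordinates."""
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    n = len(xyz)
    masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
    elements = [element] * n if isinstance(element, str) else list(element)
    return StructureModel(
        serial=np.arange(1, n + 1),
        name=np.full(n, name, dtype=object),
        element=np.asarray(elements, dtype=object),
        resnum=np.arange(1, n + 1) if resnum is None else np.asarray(resnum),
        restype=np.full(n, "ALA", dtype=object),
        chain=np.full(n, chain, dtype=object),
        xyz=xyz,
        mass=np.array([masses.get(e, 12.0) for e in elements]),
    )


@pytest.fixture
def random_rotation():
    def _make(seed=1):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        Q, R = np.linalg.qr(A)
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        return Q

    return _make
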