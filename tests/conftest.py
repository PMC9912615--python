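import numpy as np
import pytest

from craniomorph.io import LandmarkScheme
from craniomorph.simulate import make_template


@pytest.fixture
def toy_scheme() -> LandmarkScheme:
    """Two bilateral pairs plus one midline landmark, all facial."""
    return LandmarkScheme(
        ids=("L1", "R1", "L2", "R2", "M1"),
        side=("L", "R", "L", "R", "M"),
        mirror_partner=("R1", "L1", "R2", "L2", "M1"),
        module=("facial",) * 5,
    )


@pytest.fixture
def small_template():
    """Compact symmetric template: 6 pairs + 5 midline over three modules."""
    return make_template(
        (2, 2, 2), (2, 1, 2), seed=2, min_separation=0.4,
        process_pairs_per_module=(0, 0, 0),
    )


def random_scheme(rng: np.random.Generator) -> LandmarkScheme:
    """Random valid scheme for property tests (1-3 modules, b pairs, m midline)."""
    ids, side, partner, module = [], [], [], []
    n_modules = int(rng.integers(1, 4))
    names = [f"mod{j}" for j in range(n_modules)]
    n_pair = n_mid = 0
    for name in names:
        b = int(rng.integers(0, 5))
        m = int(rng.integers(0, 5))
        for _ in range(b):
            n_pair += 1
            ids += [f"L{n_pair}", f"R{n_pair}"]
            side += ["L", "R"]
            partner += [f"R{n_pair}", f"L{n_pair}"]
            module += [name, name]
        for _ in range(m):
            n_mid += 1
            ids.append(f"M{n_mid}")
            side.append("M")
            partner.append(f"M{n_mid}")
            module.append(name)
    if not ids:  # ensure non-empty
        ids, side, partner, module = ["M1"], ["M"], ["M1"], ["mod0"]
    return LandmarkScheme(tuple(ids), tuple(side), tuple(partner), tuple(module))


def proper_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
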