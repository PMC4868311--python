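import numpy as np
import pytest

from hcdr3torso.fixtures import BackboneSpec, ResidueSpec, build_backbone
from hcdr3torso.profiles import reference_profile


@pytest.fixture(scope="session")
def bulged_profile():
    return reference_profile("bulged")


@pytest.fixture(scope="session")
def non_bulged_profile():
    return reference_profile("non-bulged")


@pytest.fixture(scope="session")
def extended_chain():
    """An 18-residue ideal extended chain (one flank + 16-residue loop + one flank)."""
    return build_backbone(
        BackboneSpec(residues=tuple(ResidueSpec(aa="G") for _ in range(18)))
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
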