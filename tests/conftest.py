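import numpy as np
import pytest

from pathfactor.genesets import PathwayMask
from pathfactor.model import FactorModel, ModalityData


def make_random_model(
    rng: np.random.Generator,
    m: int = 12,
    p: int = 5,
    k: int = 3,
    n: int = 6,
    bimodal: bool = False,
) -> FactorModel:
    """Small random-but-valid model instance for derivative/update checks."""
    mods = []
    labels = ["rna", "prot"] if bimodal else ["rna"]
    for i, label in enumerate(labels):
        mi = m if i == 0 else max(m // 2, 2)
        C = (rng.random((mi, p)) < 0.4).astype(float)
        C[0, :] = 1.0  # ensure at least one covered marker per pathway
        mask = PathwayMask(
            C,
            [f"{label}_{j}" for j in range(mi)],
            [f"pw_{j}" for j in range(p)],
        )
        mods.append(
            ModalityData(
                rng.normal(size=(mi, n)),
                mask,
                rng.uniform(0.5, 2.0, mi),
                0.7 + 0.5 * i,
                label,
            )
        )
    return FactorModel(
        rng.uniform(0.1, 1.0, (p, k)),
        rng.normal(size=(k, n)),
        rng.uniform(0.2, 2.0, (p, k)),
        rng.uniform(0.2, 2.0, k),
        mods,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model(rng):
    return make_random_model(rng)


@pytest.fixture
def bimodal_model(rng):
    return make_random_model(rng, bimodal=True)
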