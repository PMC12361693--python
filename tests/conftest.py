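import numpy as np
import pytest

from opsinsol import FixtureSpec, StructureModel, make_7tm_bundle
from opsinsol.synthetic_data import _1TO3


def ca_model_from_sequence(residues: str, chain: str = "A",
                           coords: np.ndarray | None = None) -> StructureModel:
    """Cα-only model carrying a given one-letter sequence (helical geometry
    unless coordinates are supplied)."""
    from opsinsol import build_ideal_helix

    n = len(residues)
    if coords is None:
        coords = build_ideal_helix(max(n, 2))[:n]
    return StructureModel(
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        res_indices=np.arange(1, n + 1),
        res_names=np.array([_1TO3[r] for r in residues]),
        chain_ids=np.array([chain] * n),
        coords=np.asarray(coords, dtype=float),
    )


@pytest.fixture(scope="session")
def bundle():
    """One deterministic 7-TM Cα bundle plus its annotated sequence."""
    return make_7tm_bundle(FixtureSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
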