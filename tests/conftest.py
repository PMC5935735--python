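import numpy as np
import pytest

from protonpath import synth
from protonpath.structures import Atom, FrameSet, Structure, TitratableSite


@pytest.fixture
def born_structure():
    return synth.born_ion(1.0, 2.0)


@pytest.fixture
def toy_site():
    return synth.toy_titratable_site(seed=0)


@pytest.fixture
def small_structure():
    """Five-atom neutral-ish cluster for cheap PB solves."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [0.0, 1.5, 0.0],
            [0.0, 0.0, 1.5],
            [-1.2, -0.8, 0.4],
        ]
    )
    charges = [0.4, -0.3, 0.2, -0.2, -0.1]
    atoms = [
        Atom(index=k, name=f"A{k}", residue_label="TOY", position=coords[k],
             charge=charges[k], radius=1.5)
        for k in range(5)
    ]
    return Structure(atoms=atoms, title="small test cluster")


@pytest.fixture
def two_frame_set(small_structure):
    base = small_structure.positions
    rng = np.random.default_rng(3)
    return FrameSet(
        n_atoms=5, frames=[base, base + 0.1 * rng.normal(size=base.shape)]
    )


@pytest.fixture
def simple_site():
    return TitratableSite(label="s", atom_indices=[0, 1], delta_q=[0.4, 0.6])
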