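import numpy as np
import pytest

from pgpflex import synthetic
from pgpflex.ensemble_io import AtomRecord, StructureEnsemble, element_mass


def build_ensemble(atom_specs, coords):
    """Assemble a StructureEnsemble from (name, resname, resid, chain,
    element) tuples and an (F, N, 3) coordinate array."""
    atoms = [
        AtomRecord(serial=i + 1, name=name, resname=resname, resid=resid,
                   chain=chain, element=element, mass=element_mass(element))
        for i, (name, resname, resid, chain, element) in enumerate(atom_specs)
    ]
    return StructureEnsemble(atoms=atoms, coords=np.asarray(coords, dtype=float))


@pytest.fixture(scope="session")
def hinged():
    """A default hinged two-domain trajectory plus its manifest."""
    cfg = synthetic.HingedTrajectoryConfig(seed=7)
    return synthetic.make_hinged_trajectory(cfg)


@pytest.fixture(scope="session")
def helix12():
    return synthetic.make_ideal_helix(12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
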