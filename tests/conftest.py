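import numpy as np
import pandas as pd
import pytest

from cryptic_triage import synth
from cryptic_triage.kdi import DESCRIPTORS, fit_index_params
from cryptic_triage.synth import ToyAtom


@pytest.fixture(scope="session")
def reference_table() -> pd.DataFrame:
    return synth.gen_reference_descriptors(2000, seed=42)


@pytest.fixture(scope="session")
def index_params(reference_table):
    return fit_index_params(reference_table)


@pytest.fixture()
def toy_structure_path(tmp_path):
    """Synthetic three-residue fixture: a GLY pair plus one het ligand atom.

    Residue 1 sits near the origin, residue 2 is 15 A out along x, and
    the het nitrogen carries an exactly known coordinate.
    """
    atoms = [
        ToyAtom("N", "GLY", 1, "A", 0.000, 0.000, 0.000),
        ToyAtom("CA", "GLY", 1, "A", 1.000, 2.000, 3.000),
        ToyAtom("C", "GLY", 1, "A", 3.000, 4.000, 0.000),
        ToyAtom("O", "GLY", 1, "A", 2.000, 0.000, 0.000),
        ToyAtom("N", "GLY", 2, "A", 15.000, 0.000, 0.000),
        ToyAtom("CA", "GLY", 2, "A", 16.000, 1.000, 0.000),
        ToyAtom("N1", "LIG", 90, "B", -23.075, 10.028, -15.986, element="N", het=True),
        ToyAtom("C2", "LIG", 90, "B", 5.000, 0.000, 0.000, element="C", het=True),
        ToyAtom("O", "HOH", 101, "W", 2.000, 2.000, 2.000, element="O", het=True),
    ]
    return synth.gen_toy_structure(atoms, tmp_path / "toy.pdb")
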