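import numpy as np
import pytest

from rnakb.annotator import annotate_model
from rnakb.schema import load_schema
from rnakb.structure_io import Atom, Residue
from rnakb.synthetic import DuplexSpec, make_duplex


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def duplex_2model():
    """GGCGCC duplex, 2 models, noise-free, with ground truth."""
    return make_duplex(DuplexSpec(sequence="GGCGCC", n_models=2))


@pytest.fixture(scope="session")
def duplex_annotations(duplex_2model):
    msf, _ = duplex_2model
    return [annotate_model(m) for m in msf.models]


def make_residue(res_name, atom_coords, chain="A", seq=1, icode=""):
    """Residue from a {atom_name: xyz} mapping (test helper)."""
    atoms = [Atom(name=n, element=n.strip("'0123456789")[0], position=np.asarray(p, float))
             for n, p in atom_coords.items()]
    return Residue(chain_id=chain, seq_num=seq, icode=icode, res_name=res_name, atoms=atoms)
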