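import pytest

from npfrag.chem import parse_molecule
from npfrag.fixtures import fixture_molecules
from npfrag.fragmenter import FragmenterConfig, fragment_molecule
from npfrag.scoring import train_default_bde_model

SYRINGIC = "COc1cc(C(=O)O)cc(OC)c1O"
ACACETIN = "COc1ccc(-c2cc(=O)c3c(O)cc(O)cc3o2)cc1"
FORMONONETIN = "COc1ccc(C2=COc3cc(O)ccc3C2=O)cc1"


@pytest.fixture(scope="session")
def syringic():
    return parse_molecule(SYRINGIC)


@pytest.fixture(scope="session")
def acacetin():
    return parse_molecule(ACACETIN)


@pytest.fixture(scope="session")
def formononetin():
    return parse_molecule(FORMONONETIN)


@pytest.fixture(scope="session")
def syringic_fragments_d3(syringic):
    return fragment_molecule(syringic, "negative", "[M-H]-", max_depth=3)


@pytest.fixture(scope="session")
def panel():
    """The full fixture molecule panel (worked examples + decoys)."""
    return fixture_molecules()


@pytest.fixture(scope="session")
def panel_fragments_d1(panel):
    cfg = FragmenterConfig(max_depth=1)
    return {
        mol.meta.source_id: {
            mode: fragment_molecule(mol, mode, None, config=cfg)
            for mode in ("negative", "positive")
        }
        for mol in panel
    }


@pytest.fixture(scope="session")
def bde_model(panel):
    return train_default_bde_model(panel, seed=7)
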