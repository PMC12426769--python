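import numpy as np
import pytest

from condrec.binning import BinSchemes
from condrec.chem import AgentVocabulary, Molecule, ReactionRecord
from condrec.stages import FeatureConfig
from condrec.synthetic import WorldConfig, generate_world, sample_records


@pytest.fixture(scope="session")
def small_world():
    """Noiseless 2-class world shared by cheap integration tests."""
    return generate_world(
        WorldConfig(
            n_classes=2,
            vocab_size=16,
            agent_swap_prob=0.0,
            temperature_jitter_c=0.0,
            amount_jitter_frac=0.0,
            records_per_document=20,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_records(small_world):
    return sample_records(small_world, 400, seed=7)


@pytest.fixture(scope="session")
def small_fc():
    return FeatureConfig(fp_bits=256)


@pytest.fixture(scope="session")
def schemes():
    return BinSchemes.default()


@pytest.fixture
def toy_vocab():
    return AgentVocabulary(["CCO", "CO", "O", "ClCCl"])


def make_record(
    reactants=(("CCO", 0.01),),
    agents=(("O", 0.02),),
    products=("CCO",),
    temperature_c=25.0,
    class_id="1.1.1",
    document_id="doc0",
):
    return ReactionRecord(
        document_id=document_id,
        reactants=tuple((Molecule.from_smiles(s), q) for s, q in reactants),
        agents=tuple((Molecule.from_smiles(s), q) for s, q in agents),
        products=tuple(Molecule.from_smiles(s) for s in products),
        temperature_c=temperature_c,
        class_id=class_id,
    )
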