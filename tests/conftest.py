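import numpy as np
import pytest

from gtbind.model import ModelConfig, init_model
from gtbind.pipeline import featurize_dataset, feature_dims
from gtbind.synthetic import SyntheticSpec, make_dataset

# hand-written 3-residue CA-only chain, consecutive spacing 3.8 A
TINY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  CYS A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ASP A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  MET B   1      20.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  TRP B   2      23.800   0.000   0.000  1.00  0.00           C
ATOM      5  CA  LYS B   3      27.600   0.000   0.000  1.00  0.00           C
HETATM    6  O   HOH B   4      40.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture(scope="session")
def small_dataset():
    """Six collapsed-walk proteins with sequence-detectable label signal."""
    spec = SyntheticSpec(n_proteins=6, length_range=(30, 45), embed_dim=8,
                         pn_ratio_target=0.18, signal_mode="sequence_only",
                         snr=3.0, seed=11)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    ds = small_dataset
    ids, graphs, labels, stats = featurize_dataset(ds.records, ds.embeddings)
    return {"ids": ids, "graphs": graphs, "labels": labels, "stats": stats}


@pytest.fixture(scope="session")
def tiny_model(small_graphs):
    din, de = feature_dims(8)
    cfg = ModelConfig(input_dim=din, edge_dim=de, num_layers=2,
                      hidden_dim=32, num_heads=4, seed=7)
    return cfg, init_model(cfg)
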