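import numpy as np
import pytest

from phagematch.features import KmerHashEmbedder, represent_entities, build_pair_matrix
from phagematch.simulate import demo_config, generate_dataset, tiny_config


#: embedding dimension used for the desk-scale evaluation runs
DEMO_EMBED_DIM = 64


@pytest.fixture(scope="session")
def demo_dataset():
    """Desk-scale noiseless dataset (30 phages, 48 bacteria, 9 KL-types)."""
    return generate_dataset(demo_config(seed=1))


@pytest.fixture(scope="session")
def demo_features(demo_dataset):
    phages, bacteria, table, truth = demo_dataset
    embedder = KmerHashEmbedder(dim=DEMO_EMBED_DIM)
    phage_reps = represent_entities(
        ((p.phage_id, "phage", p.rbps) for p in phages), embedder
    )
    bact_reps = represent_entities(
        ((b.bacterium_id, "bacterium", b.klocus_proteins) for b in bacteria),
        embedder,
    )
    X = build_pair_matrix(table.frame, phage_reps, bact_reps)
    y = table.frame["label"].to_numpy()
    return X, y, table, phage_reps, bact_reps


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared across tests (seed-fixed)."""
    return generate_dataset(tiny_config(seed=7))


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    """Pair-feature matrix + table for the tiny dataset."""
    phages, bacteria, table, truth = tiny_dataset
    embedder = KmerHashEmbedder(dim=64)
    phage_reps = represent_entities(
        ((p.phage_id, "phage", p.rbps) for p in phages), embedder
    )
    bact_reps = represent_entities(
        ((b.bacterium_id, "bacterium", b.klocus_proteins) for b in bacteria),
        embedder,
    )
    X = build_pair_matrix(table.frame, phage_reps, bact_reps)
    y = table.frame["label"].to_numpy()
    return X, y, table, phage_reps, bact_reps
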