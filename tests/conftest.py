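"""Shared fixtures.

The expensive fixtures (training corpus, trained encoders) are
session-scoped and lazy: only tests that need a trained model pay for
it, and the three-seed separation study shares its corpus and its
seed-0 model with the end-to-end recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from surfaceid.atoms import parse_structure
from surfaceid.features import featurize
from surfaceid.mesh import compute_surface_mesh
from surfaceid.model import (ContrastiveDataset, DatasetSplit, EncoderConfig,
                             SurfaceEncoder, pairwise_distance_report, train)
from surfaceid.patches import sample_training_pairs
from surfaceid.synthetic import (make_feature_mesh, make_icosphere,
                                 make_planted_pair, make_toy_peptide)


@pytest.fixture(scope="session")
def icosphere():
    return make_icosphere(subdivisions=3, radius=9.0)


@pytest.fixture(scope="session")
def feature_mesh():
    """A featurized bumpy sphere — the standard synthetic surface."""
    return make_feature_mesh(seed=0)


@pytest.fixture(scope="session")
def toy_peptide():
    text, n_atoms = make_toy_peptide(n_residues=3, seed=0)
    return text, n_atoms


@pytest.fixture(scope="session")
def peptide_atoms(toy_peptide):
    return parse_structure(toy_peptide[0])


@pytest.fixture(scope="session")
def peptide_mesh(peptide_atoms):
    mesh = compute_surface_mesh(peptide_atoms, probe_radius=1.4,
                                target_edge_len=1.0)
    return featurize(mesh, peptide_atoms)


@pytest.fixture(scope="session")
def planted_pair():
    return make_planted_pair(seed=11, noise_sd=0.1)


# ------------------------------------------------------------ training
N_TRAIN_MESHES = 50
PATCHES_PER_MESH = 100
TRAIN_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def training_corpus():
    """50 synthetic surfaces with 100 contrastive anchors each, split by
    structure into 40 train / 5 val / 5 test."""
    meshes = [make_feature_mesh(seed=i) for i in range(N_TRAIN_MESHES)]
    samples = sample_training_pairs(meshes, PATCHES_PER_MESH, seed=0)
    grid = SurfaceEncoder(EncoderConfig()).grid
    dataset = ContrastiveDataset.from_meshes(meshes, samples, grid)
    ids = [m.mesh_id for m in meshes]
    split = DatasetSplit(train=ids[:40], val=ids[40:45], test=ids[45:])
    return dataset, split


@pytest.fixture(scope="session")
def trained_encoders(training_corpus):
    """Contrastive encoders trained from three seeds on the shared corpus,
    with their held-out distance reports."""
    dataset, split = training_corpus
    out = {}
    for seed in TRAIN_SEEDS:
        encoder, log = train(dataset, split, EncoderConfig(seed=seed))
        report = pairwise_distance_report(encoder, dataset, split.test)
        out[seed] = {"encoder": encoder, "log": log, "report": report}
    return out


@pytest.fixture(scope="session")
def trained_encoder(trained_encoders):
    """The seed-0 trained encoder (shared with end-to-end tests)."""
    return trained_encoders[TRAIN_SEEDS[0]]["encoder"]
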