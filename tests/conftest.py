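"""Shared fixtures: a small synthetic study reused across the suite.

The session-scoped pipeline fixture trains once on a strong-signal
synthetic dataset (noise-free labels driven by degree, conservation and
substitution distance) so the learning, gray-zone and saturation tests
share the cost of the 10-fold grid search.
"""

import numpy as np
import pandas as pd
import pytest

from sevscan import fixtures as fx
from sevscan import pipeline

# Study conditions for the signal-recovery experiments: a 60-residue
# random coil, 300 labeled substitutions, noise-free logistic labels with
# strong coefficients, ~37% severe (the imbalance of curated registries).
STRONG_SPEC = fx.SyntheticSpec(
    n_residues=60,
    geometry="random_coil",
    n_mutations=300,
    noise_sd=0.0,
    coefficients={"degree": 2.0, "conservation": -2.5, "aa_distance": 2.0},
    severe_fraction=0.37,
    seed=11,
)

# Pure-noise control: label = fair coin, independent of every feature.
NOISE_SPEC = fx.SyntheticSpec(
    n_residues=60,
    geometry="random_coil",
    n_mutations=300,
    noise_sd=1.0,
    coefficients={"degree": 0.0, "conservation": 0.0, "aa_distance": 0.0},
    severe_fraction=0.5,
    seed=11,
)

N_SPHERE_POINTS = 240  # surface sampling for the toy structures


@pytest.fixture(scope="session")
def strong_prep():
    pdb = fx.make_toy_structure(STRONG_SPEC)
    return pipeline.prepare_inputs(
        pdb,
        fx.make_conservation_file(STRONG_SPEC),
        fx.make_toy_property_table(STRONG_SPEC),
        n_sphere_points=N_SPHERE_POINTS,
    )


@pytest.fixture(scope="session")
def strong_mutations(strong_prep):
    return fx.make_synthetic_mutations(
        STRONG_SPEC, strong_prep.residue_features, strong_prep.centralities,
        strong_prep.distance_matrix,
    )


@pytest.fixture(scope="session")
def strong_run(strong_prep, strong_mutations):
    return pipeline.run_training(strong_prep, strong_mutations, seed=1,
                                 folds=10)


@pytest.fixture(scope="session")
def helix_residues():
    from sevscan import structure

    spec = fx.SyntheticSpec(n_residues=20, geometry="ideal_helix", seed=5)
    return structure.parse_structure(fx.make_toy_structure(spec))


@pytest.fixture()
def complete_features_10():
    """A feature-complete 10-position residue feature + centrality pair."""
    rng = np.random.default_rng(42)
    aas = list("ACDEFGHIKL")
    feats = pd.DataFrame({
        "chain": "A",
        "position": np.arange(1, 11),
        "insertion_code": "",
        "aa": aas,
        "areaSAS": rng.uniform(20, 150, 10),
        "areaSES": rng.uniform(10, 100, 10),
        "kdHydrophobicity": rng.uniform(-4.5, 4.5, 10),
        "PSI": rng.uniform(-180, 180, 10),
        "PHI": rng.uniform(-180, 180, 10),
        "bFactor": rng.uniform(10, 60, 10),
        "conservation": rng.normal(0, 1, 10),
    }, index=pd.Index([f"A:{i}" for i in range(1, 11)], name="residue"))
    cents = pd.DataFrame({
        "degree": rng.integers(1, 8, 10),
        "betweenness": rng.uniform(0, 5, 10),
        "closeness": rng.uniform(0.1, 0.9, 10),
        "constraint": rng.uniform(0.2, 1.0, 10),
        "authority": rng.uniform(0, 0.2, 10),
        "pagerank": rng.uniform(0.05, 0.15, 10),
        "kcore": rng.integers(1, 4, 10),
    }, index=feats.index)
    return feats, cents


@pytest.fixture(scope="session")
def toy_distance_matrix():
    from sevscan import aadist

    table = fx.make_toy_property_table(
        fx.SyntheticSpec(n_properties=25, seed=7))
    return aadist.distance_matrix_from_properties(table)
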