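"""End-to-end orchestration: inputs -> features -> model -> predictions.

Thin glue over the per-stage modules so scripts, the CLI and tests share
one code path: parse the structure, compute structural features, build
the residue interaction network and its centralities, derive the
substitution distance matrix, assemble the design matrix, run the
cross-validated model search, train the score-averaging ensemble,
calibrate the gray zone on out-of-fold scores, and scan all possible
substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aadist, grayzone, learning, rin, saturation, structure

__all__ = ["PreparedInputs", "prepare_inputs", "TrainingRun", "run_training",
           "calibrate_zone", "run_saturation"]


@dataclass
class PreparedInputs:
    residues: list
    residue_features: pd.DataFrame
    network: object
    centralities: pd.DataFrame
    centrality_meta: dict
    distance_matrix: aadist.AADistanceMatrix


def prepare_inputs(
    pdb_text: str,
    conservation: str | dict | None,
    properties,
    contact_cutoff: float = 5.0,
    n_sphere_points: int = 960,
    variance_target: float = 0.99,
) -> PreparedInputs:
    """Compute every per-residue feature source from the raw inputs."""
    residues = structure.parse_structure(pdb_text)
    surfaces = structure.compute_surfaces(
        residues, n_sphere_points=n_sphere_points
    )
    torsions = structure.compute_torsions(residues)
    if isinstance(conservation, str):
        conservation = structure.load_conservation(conservation)
    feats = structure.assemble_residue_features(
        residues, surfaces, torsions, conservation
    )
    G = rin.build_rin(residues, contact_cutoff=contact_cutoff)
    cents, meta = rin.compute_centralities(G)
    dist = aadist.distance_matrix_from_properties(
        properties, variance_target=variance_target
    )
    return PreparedInputs(
        residues=residues, residue_features=feats, network=G,
        centralities=cents, centrality_meta=meta, distance_matrix=dist,
    )


@dataclass
class TrainingRun:
    design: learning.DesignMatrix
    search: dict[str, learning.ModelSearchResult]
    ensemble: learning.TrainedEnsemble

    def oof_ensemble_scores(self) -> np.ndarray:
        """Out-of-fold Severity Scores of the ensemble members, averaged."""
        member_oof = [self.search[name].oof_scores
                      for name, _, _ in self.ensemble.members]
        return learning.ensemble_scores(member_oof)


def run_training(
    prep: PreparedInputs,
    mutations: pd.DataFrame,
    seed: int = 0,
    folds: int = 10,
    augment: bool = True,
    top_k: int = 2,
    position_offset: int = 0,
) -> TrainingRun:
    dm = learning.build_design_matrix(
        mutations, prep.residue_features, prep.centralities,
        prep.distance_matrix, position_offset=position_offset,
    )
    search = learning.cross_validated_grid_search(
        dm, folds=folds, seed=seed, augment=augment
    )
    ens = learning.train_ensemble(dm, search, top_k=top_k, seed=seed,
                                  augment=augment)
    return TrainingRun(design=dm, search=search, ensemble=ens)


def calibrate_zone(
    run: TrainingRun,
    min_coverage: float = 0.5,
    resolution: float = 0.01,
) -> tuple[grayzone.GrayZone, pd.DataFrame]:
    """Sweep thresholds on the out-of-fold ensemble scores, pick the zone."""
    scores = run.oof_ensemble_scores()
    landscape = grayzone.sweep_thresholds(scores, run.design.y,
                                          resolution=resolution)
    zone = grayzone.select_gray_zone(landscape, min_coverage=min_coverage)
    return zone, landscape


def run_saturation(
    prep: PreparedInputs,
    run: TrainingRun,
    zone: grayzone.GrayZone | None = None,
) -> pd.DataFrame:
    return saturation.saturation_scan(
        prep.residue_features, prep.centralities, prep.distance_matrix,
        run.ensemble, zone,
    )
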