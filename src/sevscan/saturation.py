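"""In-silico saturation mutagenesis: score every possible substitution.

Every structure position is mutated to each of the 19 non-wild-type amino
acids; the structural and network features of a position are constant
across its 19 rows and only the wild-type-to-mutant substitution distance
varies.  Each row receives the ensemble Severity Score and a ternary call
under the calibrated gray zone.  A per-position aggregate (mean of the 19
scores by default) can be written back into the B-factor column of the
input PDB for structure viewers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .aadist import AA_ORDER
from .grayzone import GrayZone, classify_with_zone
from .learning import DESIGN_FEATURES

logger = logging.getLogger(__name__)

__all__ = ["saturation_scan", "aggregate_position_scores", "annotate_structure"]


def saturation_scan(
    residue_features: pd.DataFrame,
    centralities: pd.DataFrame,
    distance_matrix,
    ensemble,
    zone: GrayZone | None = None,
) -> pd.DataFrame:
    """Score all 19 substitutions at every feature-complete position.

    Returns one row per (position, mutant) with the Severity Score and,
    when a gray zone is given, the ternary call.  Rows are sorted by
    position then mutant code; positions lacking any feature are skipped
    and counted in the ``skipped_positions`` frame attribute.
    """
    feats = residue_features.join(centralities, how="left")
    struct_cols = [c for c in DESIGN_FEATURES if c != "aa_distance"]

    rows = []
    skipped = 0
    for _, feat in feats.iterrows():
        base = {c: feat[c] for c in struct_cols}
        if any(pd.isna(v) for v in base.values()):
            skipped += 1
            continue
        wt = feat["aa"]
        for mut in AA_ORDER:
            if mut == wt:
                continue
            rows.append({
                "chain": feat["chain"], "position": int(feat["position"]),
                "wt_aa": wt, "mut_aa": mut,
                **base,
                "aa_distance": distance_matrix[wt, mut],
            })
    if skipped:
        logger.warning("%d positions skipped for missing features", skipped)
    if not rows:
        raise ValueError("no feature-complete positions to scan")
    table = pd.DataFrame(rows)
    X = table[DESIGN_FEATURES]
    table["severity_score"] = ensemble.predict_scores(X)
    if zone is not None:
        table["call"] = classify_with_zone(
            table["severity_score"].to_numpy(), zone
        )
    table = table.sort_values(["chain", "position", "mut_aa"],
                              kind="stable").reset_index(drop=True)
    out_cols = ["chain", "position", "wt_aa", "mut_aa", "aa_distance",
                "severity_score"] + (["call"] if zone is not None else [])
    out = table[out_cols]
    out.attrs["skipped_positions"] = skipped
    return out


def aggregate_position_scores(
    table: pd.DataFrame, how: str = "mean"
) -> pd.Series:
    """Per-position display score: mean (default) or max of the 19 rows."""
    if how not in ("mean", "max"):
        raise ValueError(f"unknown aggregation {how!r}")
    grouped = table.groupby("position")["severity_score"]
    return grouped.mean() if how == "mean" else grouped.max()


def annotate_structure(
    pdb_text: str, per_position_score: dict[int, float] | pd.Series
) -> str:
    """Write per-residue scores into the B-factor column of a PDB file.

    Every ATOM/HETATM B-factor becomes its residue's score scaled to
    [0, 100] with 2 decimals; residues without a score get the sentinel
    -1.00 (logged).  All other columns are preserved byte-for-byte.
    """
    scores = dict(per_position_score)
    for v in scores.values():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"score {v} outside [0, 1]")
    missing: set[int] = set()
    out_lines = []
    for line in pdb_text.splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            try:
                pos = int(line[22:26])
            except ValueError:
                out_lines.append(line)
                continue
            if pos in scores:
                b = f"{scores[pos] * 100.0:6.2f}"
            else:
                missing.add(pos)
                b = f"{-1.0:6.2f}"
            line = line[:60] + b + line[66:]
        out_lines.append(line)
    if missing:
        logger.warning("no score for residues %s; B-factor set to -1.00",
                       sorted(missing))
    return "".join(out_lines)
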