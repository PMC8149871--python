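"""Gray-zone abstention calibration for Severity Scores.

Instead of forcing a binary call everywhere, a score interval [lo, hi)
is declared "unknown": scores below lo are called mild/moderate, scores
at or above hi severe, and scores inside the zone abstain.  Sweeping the
(lo, hi) grid over held-out scores yields an accuracy/coverage landscape
from which a zone is selected — by default the one maximising the worse
of the two per-class accuracies subject to a coverage floor, with ties
going to larger coverage and then to the narrower interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrayZone",
    "classify_with_zone",
    "sweep_thresholds",
    "select_gray_zone",
    "MILD_MODERATE",
    "UNKNOWN",
    "SEVERE",
]

MILD_MODERATE = "mild/moderate"
UNKNOWN = "unknown"
SEVERE = "severe"


@dataclass(frozen=True)
class GrayZone:
    """Half-open abstention interval [lo, hi) on the Severity Score."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ValueError(f"invalid gray zone [{self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo


def classify_with_zone(score, zone: GrayZone):
    """Ternary call for a score (scalar or array) under a gray zone.

    score < lo -> mild/moderate; lo <= score < hi -> unknown;
    score >= hi -> severe.  With lo == hi nothing is ever unknown.
    """
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("Severity Scores must lie in [0, 1]")
    calls = np.where(arr < zone.lo, MILD_MODERATE,
                     np.where(arr < zone.hi, UNKNOWN, SEVERE))
    if np.isscalar(score) or arr.ndim == 0:
        return str(calls)
    return calls


def sweep_thresholds(
    scores,
    labels,
    lo_grid=None,
    hi_grid=None,
    resolution: float = 0.01,
) -> pd.DataFrame:
    """Accuracy/coverage landscape over all valid (lo <= hi) grid pairs.

    For each zone: per-class accuracy among the classified (non-abstained)
    instances — NaN, never 0, when a class has no classified instance —
    plus overall accuracy, coverage (classified fraction) and the number
    of abstentions.  Labels: 1 = severe, 0 = mild/moderate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if lo_grid is None:
        lo_grid = np.round(np.arange(0.0, 1.0 + 1e-9, resolution), 10)
    if hi_grid is None:
        hi_grid = np.round(np.arange(0.0, 1.0 + 1e-9, resolution), 10)
    n = len(scores)
    severe_mask = labels == 1
    rows = []
    for lo in lo_grid:
        for hi in hi_grid:
            if hi < lo:
                continue
            as_mild = scores < lo
            as_severe = scores >= hi
            classified = as_mild | as_severe
            n_unknown = int(n - classified.sum())
            cov = classified.sum() / n if n else np.nan
            sev_cls = severe_mask & classified
            mm_cls = (~severe_mask) & classified
            acc_severe = (
                float(as_severe[sev_cls].mean()) if sev_cls.any() else np.nan
            )
            acc_mm = (
                float(as_mild[mm_cls].mean()) if mm_cls.any() else np.nan
            )
            correct = (as_severe & severe_mask) | (as_mild & ~severe_mask)
            acc_overall = (
                float(correct.sum() / classified.sum()) if classified.any()
                else np.nan
            )
            rows.append({
                "lo": float(lo), "hi": float(hi),
                "acc_severe": acc_severe, "acc_mildmod": acc_mm,
                "acc_overall": acc_overall,
                "coverage": float(cov), "n_unknown": n_unknown,
            })
    return pd.DataFrame(rows)


def select_gray_zone(
    landscape: pd.DataFrame,
    criterion: str = "min_class_accuracy",
    min_coverage: float = 0.0,
) -> GrayZone:
    """Pick the zone maximising the criterion under a coverage floor.

    ``min_class_accuracy`` (default) scores a cell by the smaller of its
    two per-class accuracies; ``overall_accuracy`` uses the pooled
    accuracy on classified instances.  Cells with an undefined criterion
    are ignored.  Ties break toward larger coverage, then the narrower
    interval, then lower lo (determinism).
    """
    if landscape.empty:
        raise ValueError("empty landscape")
    if criterion == "min_class_accuracy":
        crit = landscape[["acc_severe", "acc_mildmod"]].min(axis=1)
        defined = landscape[["acc_severe", "acc_mildmod"]].notna().all(axis=1)
    elif criterion == "overall_accuracy":
        crit = landscape["acc_overall"]
        defined = crit.notna()
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    ok = defined & (landscape["coverage"] >= min_coverage)
    if not ok.any():
        best_cov = landscape["coverage"].max()
        raise ValueError(
            f"no zone reaches coverage {min_coverage}; best attainable "
            f"coverage is {best_cov:.3f}"
        )
    cand = landscape[ok].copy()
    cand["_crit"] = crit[ok]
    cand["_width"] = cand["hi"] - cand["lo"]
    cand = cand.sort_values(
        by=["_crit", "coverage", "_width", "lo"],
        ascending=[False, False, True, True],
        kind="stable",
    )
    top = cand.iloc[0]
    return GrayZone(lo=float(top["lo"]), hi=float(top["hi"]))
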