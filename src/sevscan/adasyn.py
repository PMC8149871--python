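"""Adaptive synthetic minority oversampling (ADASYN).

Balances a binary training set by generating synthetic minority examples
along segments between minority neighbours, allocating more synthetic
points to minority examples that sit in majority-dominated neighbourhoods
(the ones that are hard to learn).  The total synthetic budget is
G = (m_majority - m_minority) * beta; per-example quotas g_i follow the
normalised hardness weights r_i = (#majority among the K nearest
neighbours of x_i) / K, rounded by largest remainder so the quotas sum to
G exactly.  Every synthetic point is an exact convex combination
s = a + lambda * (b - a) of two minority parents, and the parentage
(parent indices and lambda) is logged for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["AugmentedDataset", "adasyn", "largest_remainder"]


@dataclass
class AugmentedDataset:
    """Original rows followed by flagged synthetic minority rows."""

    X: np.ndarray
    y: np.ndarray
    synthetic: np.ndarray  # bool mask aligned with rows
    parents: list[tuple[int, int, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_synthetic(self) -> int:
        return int(self.synthetic.sum())


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by ``weights``, sums exactly.

    Floors the proportional shares and distributes the remainder to the
    largest fractional parts; ties broken by lower index.
    """
    weights = np.asarray(weights, dtype=float)
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rest = total - base.sum()
    if rest > 0:
        order = np.lexsort((np.arange(len(quota)), -(quota - base)))
        base[order[:rest]] += 1
    return base


def adasyn(
    X: np.ndarray,
    y: np.ndarray,
    beta: float = 1.0,
    K: int = 5,
    seed: int = 0,
) -> AugmentedDataset:
    """Oversample the minority class of a binary dataset.

    Parameters
    ----------
    X, y:
        Feature matrix (finite values) and binary labels.
    beta:
        Balance fraction in [0, 1]; 1 requests full balance.
    K:
        Neighbourhood size for both the hardness weights and the parent
        pool (Euclidean distance; ties broken by row index).
    seed:
        Seeds parent choice and interpolation; same seed, same output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if K < 1:
        raise ValueError("K must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("adasyn requires exactly two classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    m_s, m_l = counts.min(), counts.max()
    if m_s < 2:
        raise ValueError("minority class must have at least 2 examples")

    meta = {"beta": beta, "K": K, "seed": seed,
            "minority_label": minority, "m_minority": int(m_s),
            "m_majority": int(m_l)}
    G = int(round((m_l - m_s) * beta))
    meta["G"] = G
    if G == 0:
        return AugmentedDataset(
            X=X.copy(), y=y.copy(),
            synthetic=np.zeros(len(y), dtype=bool), meta=meta,
        )

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(y == minority)
    Xm = X[min_idx]

    # hardness: fraction of majority points among the K nearest neighbours
    # (excluding self) in the whole dataset
    k_all = min(K, len(X) - 1)
    tree = cKDTree(X)
    _, nn = tree.query(Xm, k=k_all + 1)
    nn = np.atleast_2d(nn)[:, 1:]  # drop self
    r = np.array([(y[row] == majority).mean() for row in nn])
    if r.sum() > 0:
        weights = r / r.sum()
    else:
        weights = np.full(len(min_idx), 1.0 / len(min_idx))
        meta["uniform_fallback"] = True
    g = largest_remainder(weights, G)

    # parent pool: K nearest minority neighbours of each minority point
    k_min = min(K, len(Xm) - 1)
    tree_m = cKDTree(Xm)
    _, nn_m = tree_m.query(Xm, k=k_min + 1)
    nn_m = np.atleast_2d(nn_m)[:, 1:]

    synth = []
    parents: list[tuple[int, int, float]] = []
    for i, gi in enumerate(g):
        for _ in range(int(gi)):
            z = int(rng.integers(k_min))
            j = int(nn_m[i, z])
            lam = float(rng.random())
            s = Xm[i] + lam * (Xm[j] - Xm[i])
            synth.append(s)
            parents.append((int(min_idx[i]), int(min_idx[j]), lam))

    X_aug = np.vstack([X, np.array(synth)]) if synth else X.copy()
    y_aug = np.concatenate([y, np.full(len(synth), minority, dtype=y.dtype)])
    synthetic = np.concatenate(
        [np.zeros(len(y), dtype=bool), np.ones(len(synth), dtype=bool)]
    )
    meta["n_synthetic"] = len(synth)
    return AugmentedDataset(X=X_aug, y=y_aug, synthetic=synthetic,
                            parents=parents, meta=meta)
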