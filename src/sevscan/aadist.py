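"""Amino-acid substitution distances from physicochemical properties.

A table of numeric per-amino-acid properties (AAindex1 flat file or plain
CSV) is reduced by PCA — keeping the smallest number of components whose
cumulative explained variance reaches a target (99% by default) — and the
pairwise Euclidean distance between the 20 amino acids in that component
space forms a symmetric 20x20 substitution distance matrix.  The distance
between the wild-type and mutant residue is the only feature of a
substitution that varies across mutations at one position.

Properties are standardised (zero mean, unit variance) before PCA because
raw property scales are incommensurate; properties with any missing
amino-acid value are excluded (complete-case policy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "AA_ORDER",
    "PropertyTable",
    "AADistanceMatrix",
    "load_properties",
    "parse_aaindex1",
    "reduce_properties",
    "build_distance_matrix",
    "distance_matrix_from_properties",
]

# Fixed row/column order of every serialized matrix: alphabetical one-letter.
AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")

# AAindex1 data rows list values for A R N D C Q E G H I / L K M F P S T W Y V
_AAINDEX_ROW1 = tuple("ARNDCQEGHI")
_AAINDEX_ROW2 = tuple("LKMFPSTWYV")


@dataclass
class PropertyTable:
    """20-row table of named numeric amino-acid properties.

    ``values`` is indexed by the 20 standard one-letter codes in
    alphabetical order; columns are property names.  ``incomplete`` lists
    properties with at least one missing amino-acid value; those are
    excluded from the complete-case subset used for PCA.
    """

    values: pd.DataFrame
    incomplete: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.values.index) != list(AA_ORDER):
            self.values = self.values.reindex(list(AA_ORDER))
        if self.values.isna().any().any():
            self.incomplete = list(
                self.values.columns[self.values.isna().any(axis=0)]
            )

    @property
    def n_properties(self) -> int:
        return self.values.shape[1]

    def complete_case(self) -> pd.DataFrame:
        """Properties with a value for all 20 amino acids."""
        return self.values.drop(columns=self.incomplete)


@dataclass
class AADistanceMatrix:
    """Symmetric 20x20 Euclidean substitution distance matrix."""

    values: pd.DataFrame  # index/columns = AA_ORDER
    n_components: int
    variance_retained: float

    def __getitem__(self, pair: tuple[str, str]) -> float:
        wt, mut = pair
        return float(self.values.at[wt, mut])

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def parse_aaindex1(text: str) -> PropertyTable:
    """Parse an AAindex1 flat file ('H'/'I' record blocks) into a table.

    Each index contributes one property column named by its accession;
    'NA' values become missing.  An index whose I-block cannot supply all
    20 positions raises a parse error naming the accession.
    """
    columns: dict[str, dict[str, float]] = {}
    accession = None
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("I ") and accession:
            try:
                row1 = lines[i + 1].split()
                row2 = lines[i + 2].split()
                if len(row1) != 10 or len(row2) != 10:
                    raise ValueError("expected 10 values per data row")
                vals: dict[str, float] = {}
                for aa, tok in zip(_AAINDEX_ROW1 + _AAINDEX_ROW2, row1 + row2):
                    vals[aa] = np.nan if tok.upper() == "NA" else float(tok)
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"malformed AAindex1 entry {accession}: {exc}"
                ) from exc
            columns[accession] = vals
            i += 2
        i += 1
    df = pd.DataFrame(columns, index=list(AA_ORDER))
    return PropertyTable(values=df)


def load_properties(source) -> PropertyTable:
    """Load a PropertyTable from an AAindex1 flat file, CSV path, or frame.

    CSV inputs must carry one row per amino acid (one-letter codes in the
    first column or index) and one column per property.  A property row
    missing an amino acid altogether raises a parse error naming it.
    """
    if isinstance(source, PropertyTable):
        return source
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        text = str(source)
        if "\n" not in text:  # a path, not inline content
            with open(source) as fh:
                text = fh.read()
        if text.lstrip().startswith("H ") or "\nI " in text:
            return parse_aaindex1(text)
        import io

        df = pd.read_csv(io.StringIO(text), index_col=0)
    df.index = [str(a).strip().upper() for a in df.index]
    missing = set(AA_ORDER) - set(df.index)
    if missing:
        raise ValueError(
            f"property table lacks amino acids: {sorted(missing)}"
        )
    df = df.loc[list(AA_ORDER)].astype(float)
    return PropertyTable(values=df)


def reduce_properties(
    table: PropertyTable,
    variance_target: float = 0.99,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA-reduce the complete-case property table.

    Returns ``(scores, explained_variance_ratio)`` where ``scores`` is the
    20 x k component score matrix, k being the smallest number of
    components whose cumulative explained variance reaches
    ``variance_target``.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    X = table.complete_case().to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 complete properties for PCA")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        X = (X[:, keep] - mu[keep]) / sd[keep]
    pca = PCA(n_components=min(X.shape) - 1 if X.shape[0] <= X.shape[1] else None,
              svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    if cum[-1] + 1e-12 < variance_target:
        raise ValueError(
            f"variance target {variance_target} unreachable "
            f"(max cumulative {cum[-1]:.6f})"
        )
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return scores[:, :k], ratios[:k]


def build_distance_matrix(
    scores: np.ndarray,
    variance_retained: float | None = None,
) -> AADistanceMatrix:
    """Pairwise Euclidean distances between amino acids in score space."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != 20:
        raise ValueError("expected one score row per amino acid (20 rows)")
    D = squareform(pdist(scores, metric="euclidean"))
    df = pd.DataFrame(D, index=list(AA_ORDER), columns=list(AA_ORDER))
    return AADistanceMatrix(
        values=df,
        n_components=scores.shape[1],
        variance_retained=float(variance_retained)
        if variance_retained is not None else float("nan"),
    )


def distance_matrix_from_properties(
    source,
    variance_target: float = 0.99,
    standardize: bool = True,
) -> AADistanceMatrix:
    """End-to-end: properties -> PCA -> 20x20 distance matrix."""
    table = load_properties(source)
    scores, ratios = reduce_properties(table, variance_target, standardize)
    return build_distance_matrix(scores, variance_retained=float(ratios.sum()))
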