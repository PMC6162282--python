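"""Baseline normalization and heat-map preprocessing for RPPA time series.

The screening pipeline works on fold-changes relative to the pre-treatment
time point: on the linear scale each protein's trajectory is divided by its
baseline intensity, on the log2 scale the baseline is subtracted. A separate
standardization (log2, center, scale per antibody) plus complete-linkage
hierarchical clustering supports heat-map display of RPPA panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import TransformError, ValidationError
from .matrix import NormalizedMatrix, RppaMatrix

__all__ = [
    "normalize_to_baseline",
    "transform_for_clustering",
    "cluster_rows",
    "ClusterResult",
]


def normalize_to_baseline(matrix: RppaMatrix, baseline: str | None = None) -> NormalizedMatrix:
    """Normalize every protein trajectory to its pre-treatment level.

    Linear scale: each row is divided by its value at the baseline time
    point, so the baseline column becomes identically 1 and other columns
    are fold-changes. Log2 scale: the baseline value is subtracted per row,
    so the baseline column becomes 0 and other columns are log2 ratios.

    Parameters
    ----------
    matrix : RppaMatrix
        Input intensities; metadata (cell line, time grid, scale) is preserved.
    baseline : str, optional
        Time-point label to normalize to; defaults to the matrix's own
        baseline annotation.

    Raises
    ------
    ValidationError
        If the baseline label is unknown.
    TransformError
        If a linear-scale protein has baseline value 0 (names the protein).
    """
    baseline = baseline if baseline is not None else matrix.baseline
    if baseline not in matrix.values.columns:
        raise ValidationError(
            f"unknown baseline timepoint {baseline!r}; have {list(matrix.values.columns)}"
        )
    vals = matrix.values.astype(float)
    base = vals[baseline]
    if matrix.scale == "linear":
        zero = base[base == 0]
        if len(zero):
            raise TransformError(
                f"baseline intensity is 0 for protein(s) {list(zero.index)}; "
                "cannot form fold-changes"
            )
        out = vals.div(base, axis=0)
    else:
        out = vals.sub(base, axis=0)
    return NormalizedMatrix(
        cell_line=matrix.cell_line,
        values=out,
        baseline=baseline,
        scale=matrix.scale,
        hours=dict(matrix.hours),
        provenance={
            "transform": "baseline-normalization",
            "baseline": baseline,
            "scale": matrix.scale,
        },
    )


def transform_for_clustering(matrix: RppaMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each antibody for heat-map display.

    Each row is log2 transformed, centered to mean 0 and scaled to sample
    standard deviation 1 (denominator n-1). Rows with zero variance after
    the log transform cannot be scaled; they are emitted as all-zero and
    their identifiers returned as the second element so callers can warn.

    Returns
    -------
    (standardized, zero_variance_ids)
    """
    vals = matrix.values.astype(float)
    if matrix.scale == "linear":
        arr = vals.to_numpy()
        if (arr <= 0).any():
            r, c = map(int, next(zip(*np.where(arr <= 0))))
            raise TransformError(
                f"nonpositive value at protein {vals.index[r]!r}, "
                f"timepoint {vals.columns[c]!r}; log2 undefined"
            )
        logged = np.log2(arr)
    else:
        logged = vals.to_numpy()
    centered = logged - logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[flat] = 1.0  # row stays all-zero after centering
    out = pd.DataFrame(centered / sd, index=vals.index, columns=vals.columns)
    out.loc[flat] = 0.0
    return out, list(vals.index[flat])


@dataclass
class ClusterResult:
    """Full agglomeration history of a hierarchical clustering.

    ``linkage`` is the scipy merge matrix (each row: the two merged cluster
    indices, the merge height, and the new cluster size); ``leaf_order`` is
    the dendrogram leaf ordering as row identifiers; ``row_ids`` the input
    rows in the (lexicographic) order the linkage indices refer to.
    """

    linkage: np.ndarray
    row_ids: list[str]
    leaf_order: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_rows(standardized: pd.DataFrame, axis: str = "rows") -> ClusterResult:
    """Hierarchically cluster antibodies (or samples) of a standardized matrix.

    Uses Euclidean distance with complete agglomeration (the merge height of
    two clusters is the largest pairwise distance between them). Rows are
    sorted lexicographically by identifier before linkage so ties resolve
    deterministically across platforms.

    Parameters
    ----------
    standardized : pandas.DataFrame
        Typically the output of :func:`transform_for_clustering`.
    axis : str
        ``"rows"`` (default: cluster antibodies) or ``"columns"``.
    """
    if axis == "columns":
        standardized = standardized.T
    elif axis != "rows":
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if standardized.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 rows")
    if not np.isfinite(standardized.to_numpy(dtype=float)).all():
        raise ValidationError("clustering input contains non-finite values")
    ordered = standardized.sort_index(key=lambda idx: idx.map(str))
    dists = pdist(ordered.to_numpy(dtype=float), metric="euclidean")
    linkage = hierarchy.linkage(dists, method="complete")
    leaves = hierarchy.leaves_list(linkage)
    row_ids = [str(i) for i in ordered.index]
    return ClusterResult(
        linkage=linkage,
        row_ids=row_ids,
        leaf_order=[row_ids[i] for i in leaves],
    )
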