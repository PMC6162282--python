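"""In-memory containers for RPPA time-series matrices.

An :class:`RppaMatrix` holds one cell line's antibody x time-point intensity
table together with the metadata the pipeline needs: which time point is the
pre-treatment baseline and whether values are on a linear or log2 scale.
The underlying container is a pandas DataFrame (rows = antibodies, columns =
time-point labels in sampling order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import IngestionError, ValidationError

SCALES = ("linear", "log2")


@dataclass
class RppaMatrix:
    """Antibody x time-point intensity table for one cell line.

    Parameters
    ----------
    cell_line : str
        Label of the cell line the lysates came from (e.g. ``"HCT116"``).
    values : pandas.DataFrame
        Rows indexed by antibody identifier, columns by time-point label,
        in sampling order. No missing cells are allowed.
    baseline : str
        Column label of the pre-treatment (0 h, no irradiation) time point.
    scale : str
        ``"linear"`` (raw/normalized intensities, must be > 0) or ``"log2"``.
    hours : dict, optional
        Time-point label -> hours post irradiation annotation.
    """

    cell_line: str
    values: pd.DataFrame
    baseline: str
    scale: str = "linear"
    hours: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.baseline not in self.values.columns:
            raise ValidationError(
                f"baseline timepoint {self.baseline!r} not among columns {list(self.values.columns)}"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise IngestionError(f"duplicate antibody identifiers: {dupes}")
        if self.values.columns.has_duplicates:
            raise IngestionError("duplicate timepoint labels")
        if self.values.isna().any().any():
            cells = [
                (str(r), str(c))
                for r, c in zip(*np.where(self.values.isna().to_numpy()))
            ]
            raise IngestionError(f"missing cells at (row, column) positions {cells[:5]}")
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            r, c = map(int, next(zip(*np.where(self.values.to_numpy() <= 0))))
            raise IngestionError(
                f"nonpositive linear-scale intensity at protein "
                f"{self.values.index[r]!r}, timepoint {self.values.columns[c]!r}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "RppaMatrix":
        """Return a copy carrying new values (same metadata)."""
        return replace(self, values=values, scale=scale or self.scale)

    def row(self, protein_id: str) -> np.ndarray:
        return self.values.loc[protein_id].to_numpy(dtype=float)


@dataclass
class NormalizedMatrix(RppaMatrix):
    """Fold-changes relative to the baseline time point.

    Same shape and metadata as :class:`RppaMatrix`; the baseline column is
    identically 1 on the linear scale (ratios) or 0 on the log2 scale
    (baseline-subtracted). Carries the normalization provenance.
    """

    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        col = self.values[self.baseline].to_numpy(dtype=float)
        ref = 1.0 if self.scale == "linear" else 0.0
        if not np.allclose(col, ref, atol=1e-9):
            raise ValidationError(
                f"baseline column of a normalized matrix must be identically "
                f"{ref} on the {self.scale} scale"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("normalized matrix contains non-finite values")
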