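"""Cross-cell-line regression/FDR/correlation screen.

For every protein, a simple linear regression predicts the normalized
trajectory in the response cell line from the trajectory of the same protein
in the predictor cell line (with intercept, ordinary least squares). A
protein is selected when the slope's two-sided t-test survives a
Benjamini-Hochberg false-discovery-rate threshold (default q < 0.3) and the
Pearson correlation of the two trajectories is strongly positive (default
0.7 < r <= 1). The two filters together define the candidate list passed to
the network-flow stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matrix import NormalizedMatrix

__all__ = [
    "ScreenRecord",
    "ScreenThresholds",
    "fit_protein_regression",
    "adjust_fdr",
    "select_candidates",
    "run_screen",
    "screen_table",
]

FDR_METHOD = "benjamini-hochberg"


@dataclass
class ScreenThresholds:
    """Selection thresholds of the screen.

    ``fdr_max``: BH q-value must be strictly below this (default 0.3).
    ``r_min`` / ``r_max``: Pearson r must satisfy r_min < r <= r_max
    (defaults 0.7 and 1.0 — a strong positive linear relationship).
    """

    fdr_max: float = 0.3
    r_min: float = 0.7
    r_max: float = 1.0

    def __post_init__(self):
        if not 0 < self.fdr_max < 1:
            raise ValidationError(f"fdr_max must lie in (0, 1), got {self.fdr_max}")
        if not -1 <= self.r_min < self.r_max <= 1:
            raise ValidationError(
                f"need -1 <= r_min < r_max <= 1, got r_min={self.r_min}, r_max={self.r_max}"
            )


@dataclass
class ScreenRecord:
    """Per-protein regression and filter outcome.

    ``slope``/``intercept``/``p_slope`` come from OLS of response on
    predictor (two-sided t-test on the slope, n-2 degrees of freedom);
    ``r`` is the Pearson correlation of the paired series; ``q`` the
    BH-adjusted p-value. ``degenerate`` flags zero-variance series, which
    are reported but never selected.
    """

    protein_id: str
    slope: float
    intercept: float
    p_slope: float
    r: float
    q: float = float("nan")
    pass_fdr: bool = False
    pass_r: bool = False
    selected: bool = False
    degenerate: bool = False


def fit_protein_regression(
    protein_id: str, x_series: np.ndarray, y_series: np.ndarray
) -> ScreenRecord:
    """OLS fit of one protein's response trajectory on its predictor trajectory.

    Degenerate input (zero variance in x or y) yields a flagged record with
    ``r`` NaN and ``p_slope`` 1 rather than an error, so protein counts stay
    synchronized across the panel.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(
            f"{protein_id}: series lengths differ ({x.shape} vs {y.shape})"
        )
    if x.ndim != 1 or len(x) < 3:
        raise ValidationError(f"{protein_id}: need >= 3 aligned time points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError(f"{protein_id}: non-finite values in series")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ScreenRecord(
            protein_id=protein_id,
            slope=float("nan"),
            intercept=float("nan"),
            p_slope=1.0,
            r=float("nan"),
            degenerate=True,
        )
    fit = stats.linregress(x, y)
    return ScreenRecord(
        protein_id=protein_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_slope=float(fit.pvalue),
        r=float(fit.rvalue),
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_candidates(
    records: list[ScreenRecord], thresholds: ScreenThresholds | None = None
) -> list[ScreenRecord]:
    """Apply the FDR and correlation filters; returns records in input order.

    Selection requires q < fdr_max and r_min < r <= r_max; degenerate
    records always fail. Records are mutated in place (flags set) and the
    same list is returned for chaining.
    """
    thresholds = thresholds or ScreenThresholds()
    for rec in records:
        if np.isnan(rec.q):
            raise ValidationError(f"{rec.protein_id}: q-value missing; run adjust_fdr first")
        rec.pass_fdr = bool(rec.q < thresholds.fdr_max)
        rec.pass_r = bool(
            not rec.degenerate and thresholds.r_min < rec.r <= thresholds.r_max
        )
        rec.selected = rec.pass_fdr and rec.pass_r
    return records


@dataclass
class ScreenResult:
    """Outcome of a full panel screen."""

    records: list[ScreenRecord]
    thresholds: ScreenThresholds
    predictor_cell_line: str
    response_cell_line: str
    fdr_method: str = FDR_METHOD

    @property
    def n_tested(self) -> int:
        return len(self.records)

    @property
    def selected_ids(self) -> list[str]:
        return [r.protein_id for r in self.records if r.selected]

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)

    def summary(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_selected": self.n_selected,
            "predictor": self.predictor_cell_line,
            "response": self.response_cell_line,
            "thresholds": {
                "fdr_max": self.thresholds.fdr_max,
                "r_min": self.thresholds.r_min,
                "r_max": self.thresholds.r_max,
            },
            "fdr_method": self.fdr_method,
        }


def run_screen(
    predictor: NormalizedMatrix,
    response: NormalizedMatrix,
    thresholds: ScreenThresholds | None = None,
) -> ScreenResult:
    """Screen a whole panel: per-protein OLS, panel-wide BH, then filters.

    The two matrices must share the protein list and time grid; proteins are
    processed in the predictor matrix's row order, and output order matches it.
    """
    thresholds = thresholds or ScreenThresholds()
    if list(predictor.values.index) != list(response.values.index):
        raise ValidationError("predictor and response matrices must share the protein list")
    if list(predictor.values.columns) != list(response.values.columns):
        raise ValidationError("predictor and response matrices must share the time grid")
    records = [
        fit_protein_regression(pid, predictor.row(pid), response.row(pid))
        for pid in predictor.protein_ids
    ]
    q = adjust_fdr([r.p_slope for r in records])
    for rec, qi in zip(records, q):
        rec.q = float(qi)
    select_candidates(records, thresholds)
    return ScreenResult(
        records=records,
        thresholds=thresholds,
        predictor_cell_line=predictor.cell_line,
        response_cell_line=response.cell_line,
    )


def screen_table(result: ScreenResult) -> pd.DataFrame:
    """Flatten a screen result into the output table schema."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in result.records],
            "slope": [r.slope for r in result.records],
            "intercept": [r.intercept for r in result.records],
            "p_slope": [r.p_slope for r in result.records],
            "q": [r.q for r in result.records],
            "r": [r.r for r in result.records],
            "pass_fdr": [r.pass_fdr for r in result.records],
            "pass_r": [r.pass_r for r in result.records],
            "selected": [r.selected for r in result.records],
            "degenerate": [r.degenerate for r in result.records],
        }
    )
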