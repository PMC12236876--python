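"""Pearson correlations between loading measures and clinical measures.

Correlation strength uses fixed magnitude cutpoints common in clinical
biomechanics: |r| >= 0.6 strong, 0.4 <= |r| < 0.6 moderate, |r| < 0.4
weak.  Significance (two-sided p from the t transform with n - 2 degrees
of freedom, alpha = 0.05 by default) is ancillary: the strength class is
the primary result, so no multiple-testing correction is applied.
Missing clinical values are handled pairwise-complete, with n reported
per correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cumulative_load import ParticipantLoadSummary
from .insole_io import CLINICAL_MEASURES

__all__ = [
    "CorrelationResult",
    "strength_label",
    "pearson_with_strength",
    "correlation_table",
    "LOAD_MEASURES",
]

LOAD_MEASURES = ("l_overall", "l_high")


def strength_label(r: float) -> str:
    """Classify |r|: >= 0.6 strong, [0.4, 0.6) moderate, < 0.4 weak."""
    magnitude = abs(r)
    if magnitude >= 0.6:
        return "strong"
    if magnitude >= 0.4:
        return "moderate"
    return "weak"


@dataclass
class CorrelationResult:
    load_measure: str
    clinical_measure: str
    n: int
    r: float
    p: float
    strength: str
    significant: bool


def pearson_with_strength(
    x: "np.ndarray | list[float]",
    y: "np.ndarray | list[float]",
    alpha: float = 0.05,
    load_measure: str = "x",
    clinical_measure: str = "y",
) -> CorrelationResult:
    """Sample Pearson r with two-sided p and the strength class.

    Requires n >= 3 paired finite values and nonzero variance in both
    variables (r is undefined otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    r, p = float(r), float(p)
    return CorrelationResult(
        load_measure=load_measure,
        clinical_measure=clinical_measure,
        n=n,
        r=r,
        p=p,
        strength=strength_label(r),
        significant=p < alpha,
    )


def correlation_table(
    load_summaries: list[ParticipantLoadSummary],
    clinical: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate both load measures against all 13 clinical measures.

    Returns the full 2 x 13 grid as a DataFrame with columns
    (load_measure, clinical_measure, n, r, p, strength, significant),
    using pairwise-complete participants per cell.  Participants with
    undefined normalized loads are excluded up front.
    """
    if clinical.empty:
        raise ValueError("empty clinical table")
    defined = [s for s in load_summaries if s.defined]
    if len(defined) < 3:
        raise ValueError("need >= 3 participants with defined loads")
    loads = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in defined],
            "l_overall": [s.l_overall for s in defined],
            "l_high": [s.l_high for s in defined],
        }
    )
    merged = loads.merge(clinical, on="participant_id", how="inner")
    rows = []
    for load_measure in LOAD_MEASURES:
        for clinical_measure in CLINICAL_MEASURES:
            res = pearson_with_strength(
                merged[load_measure],
                merged[clinical_measure],
                alpha=alpha,
                load_measure=load_measure,
                clinical_measure=clinical_measure,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
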