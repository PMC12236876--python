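"""How many monitoring days are enough?  Day-subsampling reliability.

Re-estimates each participant's per-hour normalized loads from reduced
numbers of monitoring days and compares against the full-dataset
reference.  Day subsets of size k = 1..6 are drawn from each
participant's *first six recorded days*: k=6 is the single first-six-days
subset, k=5 the six leave-one-out subsets, k=1 the six singletons, and
k=2..4 all C(6, k) combinations (the symmetric generalization of the
leave-one-out and singleton schemes).  Error is summarized as the mean
absolute percent error (MAPE) across participants and subsets, with the
Pearson correlation of subset vs full estimates as a companion metric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cumulative_load import (
    CumulativeLoadSummary,
    ParticipantLoadSummary,
    aggregate_participant,
)

__all__ = [
    "SubsamplingResult",
    "subsample_estimates",
    "mape",
    "subsampling_curve",
    "MAX_SUBSAMPLE_DAYS",
]

logger = logging.getLogger(__name__)

MAX_SUBSAMPLE_DAYS = 6
MEASURES = ("l_overall", "l_high")


@dataclass
class KCurvePoint:
    """Subsampling summary for one measure at one subset size k."""

    measure: str
    k: int
    mape_pct: float
    sd_pct: float
    r: float
    n_subsets: int
    n_excluded_zero_ref: int


@dataclass
class SubsamplingResult:
    """MAPE-vs-days curves for both normalized load measures.

    ``estimates[(measure, k)]`` holds the pooled (subset estimate,
    full-data reference) pairs behind each curve point.
    """

    points: list[KCurvePoint] = field(default_factory=list)
    estimates: dict[tuple[str, int], list[tuple[float, float]]] = field(
        default_factory=dict
    )
    short_participants: list[str] = field(default_factory=list)

    def point(self, measure: str, k: int) -> KCurvePoint:
        for p in self.points:
            if p.measure == measure and p.k == k:
                return p
        raise KeyError((measure, k))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "measure": p.measure,
                    "k": p.k,
                    "mape_pct": p.mape_pct,
                    "sd_pct": p.sd_pct,
                    "r": p.r,
                    "n_subsets": p.n_subsets,
                    "n_excluded_zero_ref": p.n_excluded_zero_ref,
                }
                for p in self.points
            ]
        )


def subsample_estimates(
    day_summaries: list[CumulativeLoadSummary],
    k: int,
    participant_id: str = "",
) -> list[ParticipantLoadSummary]:
    """Re-aggregate one participant from every k-day subset.

    ``day_summaries`` are day-level summaries in recording order; only
    the first :data:`MAX_SUBSAMPLE_DAYS` are eligible.  Participants with
    fewer than six recorded days contribute subsets drawn from the days
    they have (flagged by the caller); ``k`` larger than the available
    day count yields an empty list.
    """
    if not 1 <= k <= MAX_SUBSAMPLE_DAYS:
        raise ValueError(f"k must be in 1..{MAX_SUBSAMPLE_DAYS}, got {k}")
    pool = day_summaries[:MAX_SUBSAMPLE_DAYS]
    if k > len(pool):
        return []
    out = []
    for combo in itertools.combinations(range(len(pool)), k):
        subset = [pool[i] for i in combo]
        out.append(aggregate_participant(subset, participant_id=participant_id))
    return out


def mape(estimates: "np.ndarray | list[float]", references) -> float:
    """Mean absolute percent error of estimates against references.

    Pairs where the reference is zero are scored 0% when the estimate is
    also zero (a correct zero) and excluded from the mean otherwise (the
    percent error is undefined); exclusions are logged.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.size == 0 or est.shape != ref.shape:
        raise ValueError("need non-empty, equal-length estimate/reference arrays")
    errors = _percent_errors(est, ref)
    kept = errors[np.isfinite(errors)]
    if kept.size == 0:
        raise ValueError("no pairs with a defined percent error")
    n_excluded = int(errors.size - kept.size)
    if n_excluded:
        logger.info("mape: excluded %d pairs with zero reference", n_excluded)
    return float(kept.mean())


def _percent_errors(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """|est-ref|/ref*100 with the zero-reference convention; NaN = excluded."""
    out = np.full(est.shape, np.nan)
    nonzero = ref != 0
    out[nonzero] = np.abs(est[nonzero] - ref[nonzero]) / ref[nonzero] * 100.0
    both_zero = (ref == 0) & (est == 0)
    out[both_zero] = 0.0
    return out


def subsampling_curve(
    cohort_day_summaries: dict[str, list[CumulativeLoadSummary]],
    full_references: dict[str, ParticipantLoadSummary] | None = None,
) -> SubsamplingResult:
    """Compute MAPE, dispersion and correlation curves for k = 1..6.

    Parameters
    ----------
    cohort_day_summaries:
        Per participant, day-level summaries in recording order (all
        recorded days, not only the first six).
    full_references:
        Optional precomputed full-dataset estimates; recomputed from all
        provided days when omitted.  Participants with undefined
        references (no loading time) are skipped.
    """
    if not any(len(v) >= 2 for v in cohort_day_summaries.values()):
        raise ValueError("need at least one participant with >= 2 recorded days")
    refs: dict[str, ParticipantLoadSummary] = {}
    for pid, days in cohort_day_summaries.items():
        if not days:
            continue
        ref = (
            full_references[pid]
            if full_references is not None
            else aggregate_participant(days, participant_id=pid)
        )
        if ref.defined:
            refs[pid] = ref

    result = SubsamplingResult()
    result.short_participants = sorted(
        pid
        for pid, days in cohort_day_summaries.items()
        if 0 < len(days) < MAX_SUBSAMPLE_DAYS
    )
    if result.short_participants:
        logger.info(
            "subsampling: participants with < %d days: %s",
            MAX_SUBSAMPLE_DAYS,
            result.short_participants,
        )

    for k in range(1, MAX_SUBSAMPLE_DAYS + 1):
        pairs: dict[str, list[tuple[float, float]]] = {m: [] for m in MEASURES}
        for pid, ref in refs.items():
            subsets = subsample_estimates(
                cohort_day_summaries[pid], k, participant_id=pid
            )
            for est in subsets:
                for measure in MEASURES:
                    e = getattr(est, measure) if est.defined else np.nan
                    if not np.isfinite(e):
                        # a subset with zero loading time has undefined
                        # normalized loads; treat its estimate as zero load
                        e = 0.0
                    pairs[measure].append((e, getattr(ref, measure)))
        for measure in MEASURES:
            pe = np.array(pairs[measure])
            result.estimates[(measure, k)] = [tuple(x) for x in pe]
            errors = _percent_errors(pe[:, 0], pe[:, 1])
            kept = errors[np.isfinite(errors)]
            n_excluded = int(errors.size - kept.size)
            def _varies(a: np.ndarray) -> bool:
                # treat 1-ulp ratio round-off as constant: r is undefined
                return np.ptp(a) > 1e-12 * max(1.0, float(np.abs(a).max()))

            if _varies(pe[:, 0]) and _varies(pe[:, 1]):
                r = float(stats.pearsonr(pe[:, 0], pe[:, 1])[0])
            else:
                r = float("nan")
            result.points.append(
                KCurvePoint(
                    measure=measure,
                    k=k,
                    mape_pct=float(kept.mean()) if kept.size else float("nan"),
                    sd_pct=float(kept.std(ddof=1)) if kept.size > 1 else 0.0,
                    r=r,
                    n_subsets=len(pe),
                    n_excluded_zero_ref=n_excluded,
                )
            )
    return result
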