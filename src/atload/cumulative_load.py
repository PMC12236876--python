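"""Cumulative tendon loading metrics: thresholded times and impulses.

Two magnitude thresholds partition real-world loading: an *overall*
threshold of 0.3xBW (the load of the lowest-loading tendon exercise,
seated heel raises — anything above it counts as tendon loading activity)
and a *high-level* threshold of 3.0xBW (approximately the peak Achilles
load of walking — anything above it is attributed to dynamic activity).

For a load series F(t) in xBW sampled at rate ``fs`` the metrics are
rectangle-rule sums over supra-threshold samples (dt = 1/fs):

    T(theta) = sum[F >= theta] * dt           (hours)
    I(theta) = sum[F >= theta] * F * dt       (xBW x hour)

Note the *full* sample value F is accumulated, not the excess F - theta:
the per-hour normalized overall load is then the mean load while loading,
which is the convention consistent with group values near 1xBW per loading
hour for predominantly-walking wear.  Per participant, times and impulses
are summed across all kept recordings and both impulses are divided by the
*total loading time* (time above the overall threshold, not the high-level
time) to give wear-time-normalized loads per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tendon_load import TendonLoadSeries

__all__ = [
    "LoadThresholds",
    "CumulativeLoadSummary",
    "ParticipantLoadSummary",
    "summarize_series",
    "combine_summaries",
    "aggregate_participant",
]

_S_PER_H = 3600.0


@dataclass(frozen=True)
class LoadThresholds:
    """Overall and high-level loading thresholds in xBW."""

    overall: float = 0.3
    high: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.overall < self.high):
            raise ValueError(
                f"need 0 < overall < high, got ({self.overall}, {self.high})"
            )


@dataclass
class CumulativeLoadSummary:
    """Thresholded loading time and impulse for one scope of data.

    Attributes
    ----------
    t_load_h:
        Total loading time: hours with load >= overall threshold.
    i_overall:
        Impulse accumulated over those hours (xBW x hour).
    t_high_h, i_high:
        Same above the high-level threshold (subset of the overall).
    scope:
        "recording", "day", or "participant".
    participant_id:
        Optional provenance tag; aggregation rejects mixed participants.
    """

    t_load_h: float = 0.0
    i_overall: float = 0.0
    t_high_h: float = 0.0
    i_high: float = 0.0
    scope: str = "recording"
    participant_id: str = ""

    def __add__(self, other: "CumulativeLoadSummary") -> "CumulativeLoadSummary":
        return CumulativeLoadSummary(
            t_load_h=self.t_load_h + other.t_load_h,
            i_overall=self.i_overall + other.i_overall,
            t_high_h=self.t_high_h + other.t_high_h,
            i_high=self.i_high + other.i_high,
            scope=self.scope if self.scope == other.scope else "mixed",
            participant_id=self.participant_id or other.participant_id,
        )


@dataclass
class ParticipantLoadSummary:
    """Per-hour normalized loading measures for one participant.

    ``l_overall = I_overall / T_load`` and ``l_high = I_high / T_load``
    (xBW per loading hour).  When the participant accumulated no loading
    time both are undefined (NaN) and ``defined`` is False; such
    participants are excluded from downstream statistics.
    """

    participant_id: str
    l_overall: float
    l_high: float
    t_load_h: float
    n_summaries: int
    defined: bool = True


def summarize_series(
    series: TendonLoadSeries,
    thresholds: LoadThresholds = LoadThresholds(),
    scope: str = "recording",
    participant_id: str = "",
) -> CumulativeLoadSummary:
    """Thresholded loading time/impulse of one load series.

    Comparisons are closed (>=) at the threshold; integration is the
    rectangle rule at the native sample rate, which is exact for the
    masked (piecewise-constant) definition.  An empty series yields the
    all-zero summary.
    """
    f = series.load_bw
    if f.size == 0:
        return CumulativeLoadSummary(scope=scope, participant_id=participant_id)
    dt_h = 1.0 / series.sample_rate_hz / _S_PER_H
    over = f >= thresholds.overall
    high = f >= thresholds.high
    return CumulativeLoadSummary(
        t_load_h=float(over.sum()) * dt_h,
        i_overall=float(f[over].sum()) * dt_h,
        t_high_h=float(high.sum()) * dt_h,
        i_high=float(f[high].sum()) * dt_h,
        scope=scope,
        participant_id=participant_id,
    )


def combine_summaries(
    summaries: list[CumulativeLoadSummary], scope: str
) -> CumulativeLoadSummary:
    """Sum summaries (e.g. sessions into a day) under a new scope label."""
    out = CumulativeLoadSummary(scope=scope)
    for s in summaries:
        out = CumulativeLoadSummary(
            t_load_h=out.t_load_h + s.t_load_h,
            i_overall=out.i_overall + s.i_overall,
            t_high_h=out.t_high_h + s.t_high_h,
            i_high=out.i_high + s.i_high,
            scope=scope,
            participant_id=out.participant_id or s.participant_id,
        )
    return out


def aggregate_participant(
    summaries: list[CumulativeLoadSummary],
    participant_id: str,
) -> ParticipantLoadSummary:
    """Pool summaries of one participant into per-hour normalized loads.

    Times and impulses are summed first; the ratio of pooled sums (not the
    mean of per-day ratios) defines the normalized loads, so days with more
    loading time weigh proportionally more.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    tagged = {s.participant_id for s in summaries if s.participant_id}
    foreign = tagged - {participant_id} if participant_id else set()
    if foreign or len(tagged) > 1:
        raise ValueError(f"summaries from mixed participants: {sorted(tagged)}")
    total = combine_summaries(summaries, scope="participant")
    if total.t_load_h <= 0:
        return ParticipantLoadSummary(
            participant_id=participant_id,
            l_overall=float("nan"),
            l_high=float("nan"),
            t_load_h=0.0,
            n_summaries=len(summaries),
            defined=False,
        )
    return ParticipantLoadSummary(
        participant_id=participant_id,
        l_overall=total.i_overall / total.t_load_h,
        l_high=total.i_high / total.t_load_h,
        t_load_h=total.t_load_h,
        n_summaries=len(summaries),
    )
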