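"""Recording-level quality control before load accumulation.

Three defenses, mirroring how multi-day insole data fail in practice:

1. **Baseline drift correction** — a sensor that loses its zero reads a
   positive force even when unloaded.  Under normal wear every 30 s
   window contains unloaded instants (swing phases, rests), so the
   rolling lower envelope (rolling minimum, then smoothed) of each
   channel tracks the nonphysical offset; it is subtracted wherever it
   exceeds a tolerance, restoring "force is zero whenever unloaded".
2. **Erroneous-recording screen** — sessions that are implausible as
   human wear (never unloaded, negative force rails, or too short to
   judge) are flagged and dropped rather than corrected.
3. **Protocol adherence** — participants whose median daily loading time
   is below a threshold did not follow a full-day wear protocol and are
   excluded from cohort statistics.

Rule thresholds are artifact-level defaults chosen as "physically
implausible under normal wear" bounds, not measured constants; all are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .cumulative_load import LoadThresholds
from .insole_io import InsoleRecording
from .tendon_load import SensorGeometry, estimate_tendon_load

__all__ = [
    "QCReport",
    "ErroneousRules",
    "correct_drift",
    "flag_erroneous",
    "qc_recording",
    "check_adherence",
]

FATAL_FLAGS = ("drift_excessive", "constant_offset", "too_short", "negative_rail")


@dataclass
class QCReport:
    """Outcome of QC for one recording."""

    recording_id: str
    offsets_n: tuple[float, float, float] = (0.0, 0.0, 0.0)
    corrected: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def disposition(self) -> str:
        """"drop" iff at least one fatal flag is set, else "keep"."""
        return "drop" if any(f in FATAL_FLAGS for f in self.flags) else "keep"

    def merged(self, other: "QCReport") -> "QCReport":
        return QCReport(
            recording_id=self.recording_id,
            offsets_n=tuple(
                max(a, b) for a, b in zip(self.offsets_n, other.offsets_n)
            ),
            corrected=self.corrected or other.corrected,
            flags=self.flags + [f for f in other.flags if f not in self.flags],
        )


@dataclass(frozen=True)
class ErroneousRules:
    """Thresholds for the erroneous-recording screen.

    A session is implausible as normal wear when (a) the estimated load
    stays at or above the overall loading threshold for more than
    ``loaded_frac`` of samples *and* no unloaded interval lasts at least
    ``min_unloaded_gap_s`` (no swing or rest phase ever occurs), or (b)
    any channel reads below ``-neg_thresh_bw`` xBW for more than
    ``neg_frac`` of samples, or (c) the session is shorter than
    ``min_duration_s``.
    """

    loaded_frac: float = 0.95
    min_unloaded_gap_s: float = 2.0
    neg_thresh_bw: float = 0.05
    neg_frac: float = 0.01
    min_duration_s: float = 60.0


def _rolling_lower_envelope(x: np.ndarray, window: int) -> np.ndarray:
    """Rolling minimum followed by a same-width moving-average smooth."""
    env = minimum_filter1d(x, size=window, mode="nearest")
    return uniform_filter1d(env, size=window, mode="nearest")


def correct_drift(
    recording: InsoleRecording,
    bw_n: float,
    window_s: float = 30.0,
    tolerance_bw: float = 0.02,
    fatal_drift_bw: float = 0.5,
    fatal_frac: float = 0.5,
) -> tuple[InsoleRecording, QCReport]:
    """Estimate and remove nonphysical baseline drift per channel.

    The per-channel baseline is the smoothed rolling minimum over
    ``window_s``; it is subtracted wherever it exceeds
    ``tolerance_bw * bw_n`` newtons and the output is clipped at >= 0.
    A clean recording (true zeros whenever unloaded) passes through
    unchanged.  The operation is idempotent: the corrected signal's own
    lower envelope is ~0, so a second pass is a no-op.

    Fatal cases: a recording shorter than the window cannot be judged
    (``too_short``, drop); a channel whose baseline exceeds
    ``fatal_drift_bw * bw_n`` for more than ``fatal_frac`` of samples
    never returns near zero (``drift_excessive``, drop).
    """
    report = QCReport(recording_id=recording.session_id)
    if recording.duration_s < window_s:
        report.flags.append("too_short")
        return recording.copy(), report

    window = max(int(round(window_s * recording.sample_rate_hz)), 1)
    tol_n = tolerance_bw * bw_n
    fatal_n = fatal_drift_bw * bw_n
    out = recording.copy()
    offsets = []
    corrected = False
    for channel in ("f_heel", "f_mid", "f_fore"):
        f = getattr(out, channel)
        baseline = _rolling_lower_envelope(f, window)
        offsets.append(float(np.median(baseline)))
        if np.mean(baseline >= fatal_n) > fatal_frac:
            report.flags.append("drift_excessive")
        above = baseline > tol_n
        if above.any():
            corrected = True
            f = f - np.where(above, baseline, 0.0)
            setattr(out, channel, np.maximum(f, 0.0))
    report.offsets_n = tuple(offsets)
    report.corrected = corrected
    if "drift_excessive" in report.flags:
        return recording.copy(), report
    return out, report


def _longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    if mask.size == 0:
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    if edges.size == 0:
        return 0
    starts, ends = edges[0::2], edges[1::2]
    return int((ends - starts).max())


def flag_erroneous(
    recording: InsoleRecording,
    bw_n: float,
    geometry: SensorGeometry = SensorGeometry(),
    rules: ErroneousRules = ErroneousRules(),
    thresholds: LoadThresholds = LoadThresholds(),
) -> QCReport:
    """Screen one recording against the erroneous-recording rules.

    Report-only: the caller decides what to do with the disposition.
    """
    if recording.n_samples == 0:
        raise ValueError("cannot screen an empty recording")
    report = QCReport(recording_id=recording.session_id)
    fs = recording.sample_rate_hz

    if recording.duration_s < rules.min_duration_s:
        report.flags.append("too_short")

    neg_limit = -rules.neg_thresh_bw * bw_n
    neg = (
        (recording.f_heel < neg_limit)
        | (recording.f_mid < neg_limit)
        | (recording.f_fore < neg_limit)
    )
    if neg.mean() > rules.neg_frac:
        report.flags.append("negative_rail")

    load = estimate_tendon_load(recording, geometry, bw_n).load_bw
    loaded = load >= thresholds.overall
    if loaded.mean() > rules.loaded_frac:
        gap = _longest_true_run(~loaded) / fs
        if gap < rules.min_unloaded_gap_s:
            report.flags.append("constant_offset")
    return report


def qc_recording(
    recording: InsoleRecording,
    bw_n: float,
    geometry: SensorGeometry = SensorGeometry(),
    window_s: float = 30.0,
    tolerance_bw: float = 0.02,
    rules: ErroneousRules = ErroneousRules(),
    thresholds: LoadThresholds = LoadThresholds(),
) -> tuple[InsoleRecording, QCReport]:
    """Full per-recording QC: erroneous screen, then drift correction.

    The screen runs on the *raw* recording: a session whose sensor was
    initialized wrong reads as a whole-session offset, which baseline
    subtraction would mask if it ran first.  Only recordings that pass
    the screen are drift-corrected.

    Returns the (possibly corrected) recording and the merged report;
    check ``report.disposition`` before using the recording.
    """
    screen = flag_erroneous(
        recording, bw_n, geometry=geometry, rules=rules, thresholds=thresholds
    )
    if screen.disposition == "drop":
        return recording.copy(), screen
    corrected, drift_report = correct_drift(
        recording, bw_n, window_s=window_s, tolerance_bw=tolerance_bw
    )
    return corrected, screen.merged(drift_report)


def check_adherence(
    daily_loading_hours: "np.ndarray | list[float]",
    min_median_daily_loading_h: float = 4.0,
) -> str:
    """Participant-level protocol adherence: "keep" or "exclude".

    Excludes iff the median daily total loading time falls below the
    threshold, separating token wear (an hour or two of recording a day)
    from genuine full-day monitoring.  A zero threshold keeps everyone.
    """
    daily = np.asarray(daily_loading_hours, dtype=float)
    if daily.size == 0:
        raise ValueError("need at least one day summary")
    return (
        "exclude"
        if float(np.median(daily)) < min_median_daily_loading_h
        else "keep"
    )
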