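"""Synthetic multi-day insole cohorts with analytic ground truth.

The generator emulates an at-home monitoring protocol: each participant
wears a three-pad force-sensing insole through the day, producing one or
more 20 Hz recordings per day containing walking, occasional running and
jumping bouts, quiet rest, and non-wear stretches.  Every bout is built
from a parametric stance waveform for the *tendon load* profile, which is
then back-distributed onto the three pads so that the moment-balance
estimator recovers the constructed load exactly.  This gives every
downstream stage a known answer:

* per-bout loading times and impulses follow analytically from the
  continuous stance waveform (dense quadrature of the closed-form shape,
  independent of the sampled 20 Hz signal path);
* clinical measures are linear functions of a per-participant latent
  high-activity volume plus Gaussian noise, so the population correlation
  with anything driven by that volume has a closed form
  ``r = slope * sd_v / sqrt(slope^2 sd_v^2 + sd_noise^2)``.

Stance shapes are deliberately simple (walking: two-hump raised-cosine
sum; running/jumping: single asymmetric raised cosine).  Only the peak
magnitude and timing matter to threshold-based cumulative metrics, so the
shapes are placeholders for real plantar-force waveforms, not models of
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .cumulative_load import LoadThresholds
from .insole_io import (
    CLINICAL_MEASURES,
    CohortManifest,
    InsoleRecording,
    write_clinical_table,
    write_manifest,
    write_recording,
)
from .tendon_load import GRAVITY_N_PER_KG, SensorGeometry

__all__ = [
    "Bout",
    "ParticipantProfile",
    "GroundTruthSummary",
    "EffectSpec",
    "Artifact",
    "CohortBundle",
    "make_bout",
    "simulate_stance_profile",
    "simulate_day",
    "simulate_cohort",
    "inject_artifacts",
    "write_cohort",
    "DEFAULT_SAMPLE_RATE_HZ",
]

DEFAULT_SAMPLE_RATE_HZ = 20.0

#: Per-cycle start-time jitter (s). Larger than half the 20 Hz sample
#: period so cycle phases decorrelate from the sampling grid even when the
#: cycle period is a multiple of the sample period.
_JITTER_S = 0.03

#: Non-wear bouts at least this long split the day into separate
#: recordings (shoe change / sensor pause); shorter ones are logged zeros.
SESSION_BREAK_S = 1800.0

#: Kind-level defaults: cycle rate (per-foot cycles/min), ground-contact
#: (stance) time within each cycle, and peak tendon load in xBW.
KIND_DEFAULTS: dict[str, dict[str, float]] = {
    "walk": {"cadence_per_min": 53.0, "stance_s": 0.65, "intensity_bw": 2.4},
    "run": {"cadence_per_min": 82.0, "stance_s": 0.28, "intensity_bw": 4.6},
    "jump": {"cadence_per_min": 26.0, "stance_s": 0.50, "intensity_bw": 5.0},
    "rest": {"cadence_per_min": 13.0, "stance_s": 0.80, "intensity_bw": 0.2},
    "nonwear": {"cadence_per_min": 0.0, "stance_s": 0.0, "intensity_bw": 0.0},
}


@dataclass(frozen=True)
class Bout:
    """One scheduled activity interval within a day.

    ``cadence_per_min == 0`` with nonzero intensity means a sustained
    constant load (an isometric-type hold); kind ``nonwear`` means the
    sensor logs zeros (or, with artifacts, drift only).
    """

    kind: str
    duration_s: float
    intensity_bw: float
    cadence_per_min: float
    stance_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KIND_DEFAULTS:
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError(f"bout duration must be > 0, got {self.duration_s}")
        if self.intensity_bw < 0:
            raise ValueError("bout intensity must be >= 0")
        if self.cadence_per_min < 0:
            raise ValueError("cadence must be >= 0")
        if self.cadence_per_min > 0:
            period = 60.0 / self.cadence_per_min
            if self.stance_s <= 0:
                raise ValueError("cyclic bout needs stance_s > 0")
            if self.stance_s + 2 * _JITTER_S > period:
                raise ValueError(
                    f"stance {self.stance_s}s does not fit cycle period "
                    f"{period:.3f}s with jitter"
                )

    @property
    def period_s(self) -> float:
        return 60.0 / self.cadence_per_min if self.cadence_per_min > 0 else 0.0

    @property
    def n_cycles(self) -> int:
        if self.cadence_per_min <= 0:
            return 0
        return int(math.floor(self.duration_s / self.period_s))


def make_bout(
    kind: str,
    duration_s: float,
    intensity_bw: float | None = None,
    cadence_per_min: float | None = None,
    stance_s: float | None = None,
) -> Bout:
    """Construct a bout, filling unspecified fields from kind defaults."""
    d = KIND_DEFAULTS[kind] if kind in KIND_DEFAULTS else None
    if d is None:
        raise ValueError(f"unknown bout kind {kind!r}")
    return Bout(
        kind=kind,
        duration_s=duration_s,
        intensity_bw=d["intensity_bw"] if intensity_bw is None else intensity_bw,
        cadence_per_min=(
            d["cadence_per_min"] if cadence_per_min is None else cadence_per_min
        ),
        stance_s=d["stance_s"] if stance_s is None else stance_s,
    )


@dataclass(frozen=True)
class ParticipantProfile:
    """Static per-participant attributes driving schedules and clinical data."""

    participant_id: str
    mass_kg: float
    height_m: float
    age: float
    visa_a: float
    pas: float
    latent_volume: float  # unitless high-activity driver in [0, 1]
    gravity_n_per_kg: float = GRAVITY_N_PER_KG

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass must be > 0")
        if not 0 <= self.visa_a <= 100:
            raise ValueError("VISA-A must be in [0, 100]")
        if not 1 <= self.pas <= 6:
            raise ValueError("PAS must be in [1, 6]")

    @property
    def bw_n(self) -> float:
        """Body weight in newtons (mass x g)."""
        return self.mass_kg * self.gravity_n_per_kg


@dataclass
class GroundTruthSummary:
    """Analytic loading metrics implied by a schedule (hours, xBW x hour)."""

    t_load_h: float = 0.0
    i_overall: float = 0.0
    t_high_h: float = 0.0
    i_high: float = 0.0

    def __post_init__(self) -> None:
        if min(self.t_load_h, self.i_overall, self.t_high_h, self.i_high) < -1e-12:
            raise ValueError("ground-truth metrics must be >= 0")
        if self.t_high_h > self.t_load_h + 1e-12:
            raise ValueError("high-level time cannot exceed loading time")
        if self.i_high > self.i_overall + 1e-12:
            raise ValueError("high-level impulse cannot exceed overall impulse")

    def __add__(self, other: "GroundTruthSummary") -> "GroundTruthSummary":
        return GroundTruthSummary(
            self.t_load_h + other.t_load_h,
            self.i_overall + other.i_overall,
            self.t_high_h + other.t_high_h,
            self.i_high + other.i_high,
        )

    @property
    def l_overall(self) -> float:
        return self.i_overall / self.t_load_h if self.t_load_h > 0 else float("nan")

    @property
    def l_high(self) -> float:
        return self.i_high / self.t_load_h if self.t_load_h > 0 else float("nan")


# --------------------------------------------------------------------------
# Stance-phase load waveforms
# --------------------------------------------------------------------------

def _raised_cosine(u: np.ndarray, center: float, half_width: float) -> np.ndarray:
    x = (u - center) / half_width
    return np.where(np.abs(x) < 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)


_WALK_HUMPS = ((0.28, 0.20, 0.85), (0.72, 0.20, 1.00))  # (center, half-width, rel amp)
_ASYM_PEAK_U = 0.38  # push-off-skewed single hump for run/jump


def _walk_shape_raw(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u, dtype=float)
    for center, width, amp in _WALK_HUMPS:
        out += amp * _raised_cosine(u, center, width)
    return out


def _walk_norm() -> tuple[float, float]:
    """Max of the raw two-hump shape and the phase where it occurs."""
    uu = np.linspace(0.0, 1.0, 20001)
    vals = _walk_shape_raw(uu)
    k = int(np.argmax(vals))
    return float(vals[k]), float(uu[k])


_WALK_MAX, _WALK_PEAK_U = _walk_norm()


def stance_shape(kind: str, u: np.ndarray) -> np.ndarray:
    """Unit-peak load shape over normalized stance phase u in [0, 1].

    Walking and quiet-rest weight shifts use a two-hump (contact +
    push-off) raised-cosine sum; running and jumping use a single
    asymmetric raised cosine peaking late in stance.
    """
    u = np.asarray(u, dtype=float)
    if kind in ("walk", "rest"):
        return _walk_shape_raw(u) / _WALK_MAX
    if kind in ("run", "jump"):
        a = _ASYM_PEAK_U
        up = 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0, a) / a))
        down = 0.5 * (1.0 + np.cos(np.pi * (np.clip(u, a, 1) - a) / (1 - a)))
        return np.where((u >= 0) & (u <= 1), np.where(u < a, up, down), 0.0)
    raise ValueError(f"no stance shape for kind {kind!r}")


def stance_peak_phase(kind: str) -> float:
    """Normalized phase at which the stance shape attains its peak."""
    if kind in ("walk", "rest"):
        return _WALK_PEAK_U
    if kind in ("run", "jump"):
        return _ASYM_PEAK_U
    raise ValueError(f"no stance shape for kind {kind!r}")


# --------------------------------------------------------------------------
# Load -> pad force allocation
# --------------------------------------------------------------------------

def _allocation_weights(u: np.ndarray) -> np.ndarray:
    """Pad force fractions over stance phase: heel-dominant at contact,
    forefoot-dominant at push-off.  Rows sum to 1, all entries >= 0."""
    u = np.asarray(u, dtype=float)
    w_heel = 0.3 * (1.0 - u)
    w_fore = 0.2 + 0.6 * u
    w_mid = 1.0 - w_heel - w_fore
    return np.stack([w_heel, w_mid, w_fore], axis=-1)


def forces_from_load(
    load_bw: np.ndarray,
    phase_u: np.ndarray,
    geometry: SensorGeometry,
    bw_n: float,
) -> np.ndarray:
    """Distribute a tendon-load profile onto the three pads.

    Solves for nonnegative pad forces whose ankle moment reproduces the
    requested load exactly under the given geometry, with a contact-to-
    push-off center-of-pressure progression.  Returns an (n, 3) array
    (heel, mid, fore) in newtons.
    """
    weights = _allocation_weights(phase_u)
    r_eff = weights @ geometry.pad_arms
    if np.any(r_eff <= 1e-4):
        raise ValueError(
            "sensor geometry incompatible with force allocation "
            "(effective moment arm not positive over stance)"
        )
    moment = np.asarray(load_bw, dtype=float) * bw_n * geometry.r_at
    f_total = moment / r_eff
    return weights * f_total[:, None]


# --------------------------------------------------------------------------
# Stance / bout signal synthesis
# --------------------------------------------------------------------------

def simulate_stance_profile(
    kind: str,
    peak_load_bw: float,
    stance_duration_s: float,
    geometry: SensorGeometry = SensorGeometry(),
    bw_n: float = 700.0,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> InsoleRecording:
    """Synthesize one stance phase as a three-channel force segment.

    The sampling grid is phase-aligned so that one sample lands exactly on
    the waveform peak; applying the moment-balance estimator to the result
    therefore recovers ``peak_load_bw`` exactly (to float precision).

    A zero peak gives all-zero channels.
    """
    if stance_duration_s <= 0:
        raise ValueError("stance_duration_s must be > 0")
    if peak_load_bw < 0:
        raise ValueError("peak_load_bw must be >= 0")
    dt = 1.0 / sample_rate_hz
    t_peak = stance_peak_phase(kind) * stance_duration_s
    t0 = t_peak - math.floor(t_peak / dt) * dt
    t = np.arange(t0, stance_duration_s, dt)
    u = t / stance_duration_s
    load = peak_load_bw * stance_shape(kind, u)
    forces = forces_from_load(load, u, geometry, bw_n)
    return InsoleRecording(
        participant_id="stance",
        day=0,
        session=0,
        sample_rate_hz=sample_rate_hz,
        f_heel=forces[:, 0],
        f_mid=forces[:, 1],
        f_fore=forces[:, 2],
    )


def _bout_load_profile(
    bout: Bout, sample_rate_hz: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled tendon-load profile (xBW) and stance phase for one bout."""
    n = int(round(bout.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    load = np.zeros(n)
    phase = np.full(n, 0.5)
    if bout.kind == "nonwear" or bout.intensity_bw == 0:
        return load, phase
    if bout.cadence_per_min == 0:
        # sustained constant load (isometric-type hold)
        load[:] = bout.intensity_bw
        return load, phase
    n_cycles = bout.n_cycles
    if n_cycles == 0:
        return load, phase
    starts = np.arange(n_cycles) * bout.period_s + rng.uniform(
        -_JITTER_S, _JITTER_S, n_cycles
    )
    np.clip(starts, 0.0, bout.duration_s - bout.stance_s, out=starts)
    idx = np.searchsorted(starts, t, side="right") - 1
    valid = idx >= 0
    rel = t - starts[np.clip(idx, 0, None)]
    in_stance = valid & (rel < bout.stance_s)
    u = np.where(in_stance, rel / bout.stance_s, 0.5)
    load = np.where(in_stance, bout.intensity_bw * stance_shape(bout.kind, u), 0.0)
    return load, u


@lru_cache(maxsize=512)
def _cycle_metrics(
    kind: str,
    intensity_bw: float,
    stance_s: float,
    theta_overall: float,
    theta_high: float,
) -> tuple[float, float, float, float]:
    """Per-cycle (t_over_s, i_over_bws, t_high_s, i_high_bws) by dense
    quadrature of the continuous stance waveform (4096-point midpoint
    rule), independent of the sampled signal path."""
    m = 4096
    uu = (np.arange(m) + 0.5) / m
    g = intensity_bw * stance_shape(kind, uu)
    dt = stance_s / m
    over = g >= theta_overall
    high = g >= theta_high
    return (
        float(over.sum()) * dt,
        float(g[over].sum()) * dt,
        float(high.sum()) * dt,
        float(g[high].sum()) * dt,
    )


def bout_ground_truth(
    bout: Bout, thresholds: LoadThresholds = LoadThresholds()
) -> GroundTruthSummary:
    """Analytic loading metrics of one bout (hours, xBW x hour)."""
    if bout.kind == "nonwear" or bout.intensity_bw == 0:
        return GroundTruthSummary()
    if bout.cadence_per_min == 0:
        g = bout.intensity_bw
        dur_h = bout.duration_s / 3600.0
        over = g >= thresholds.overall
        high = g >= thresholds.high
        return GroundTruthSummary(
            t_load_h=dur_h if over else 0.0,
            i_overall=g * dur_h if over else 0.0,
            t_high_h=dur_h if high else 0.0,
            i_high=g * dur_h if high else 0.0,
        )
    t_o, i_o, t_h, i_h = _cycle_metrics(
        bout.kind,
        float(bout.intensity_bw),
        float(bout.stance_s),
        thresholds.overall,
        thresholds.high,
    )
    k = bout.n_cycles / 3600.0
    return GroundTruthSummary(t_o * k, i_o * k, t_h * k, i_h * k)


# --------------------------------------------------------------------------
# Artifact injection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Artifact:
    """A nonphysical signal defect to superimpose on a clean recording.

    kind "drift": a constant baseline offset of ``offset_bw`` (in xBW of
    induced tendon-load error) appearing at ``onset_s`` and persisting to
    the end of the session — emulating a sensor that lost its zero.

    kind "erroneous": a whole-session constant offset large enough that
    the recording never looks unloaded — emulating incorrect sensor
    initialization or insole misfit.  Such sessions are constructed to be
    caught by the erroneous-recording screen.
    """

    kind: str
    offset_bw: float = 0.1
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("drift", "erroneous"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.offset_bw < 0:
            raise ValueError("offset_bw must be >= 0")


def inject_artifacts(
    recording: InsoleRecording,
    artifacts: Sequence[Artifact],
    geometry: SensorGeometry,
    bw_n: float,
    seed: int = 0,
) -> InsoleRecording:
    """Return a modified copy of ``recording`` with artifacts applied.

    The offset is applied to the forefoot channel scaled by
    ``r_AT / r_fore`` so the induced tendon-load offset equals
    ``offset_bw`` xBW exactly.  The input recording is left untouched.
    An empty artifact list returns an identical copy.
    """
    out = recording.copy()
    for art in artifacts:
        delta_fore = art.offset_bw * bw_n * geometry.r_at / geometry.r_fore
        if art.kind == "erroneous":
            out.f_fore += delta_fore
        else:  # drift
            start = int(round(art.onset_s * out.sample_rate_hz))
            start = min(max(start, 0), out.n_samples)
            out.f_fore[start:] += delta_fore
    return out


# --------------------------------------------------------------------------
# Day and cohort simulation
# --------------------------------------------------------------------------

def simulate_day(
    profile: ParticipantProfile,
    schedule: Sequence[Bout],
    seed: int,
    day_index: int = 1,
    geometry: SensorGeometry = SensorGeometry(),
    artifacts: Sequence[Artifact] = (),
    thresholds: LoadThresholds = LoadThresholds(),
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> tuple[list[InsoleRecording], GroundTruthSummary]:
    """Render one day's bout schedule into 20 Hz insole recordings.

    Non-wear bouts of at least ``SESSION_BREAK_S`` split the day into
    separate recordings (sensor pause at a shoe change); shorter non-wear
    stays inside a session as logged zeros.  The returned ground truth is
    the analytic sum over bouts and is computed independently of the
    sampled signal.  An empty schedule yields no recordings and zero
    ground truth.
    """
    rng = np.random.default_rng(seed)
    sessions: list[list[Bout]] = [[]]
    truth = GroundTruthSummary()
    for bout in schedule:
        truth = truth + bout_ground_truth(bout, thresholds)
        if bout.kind == "nonwear" and bout.duration_s >= SESSION_BREAK_S:
            if sessions[-1]:
                sessions.append([])
            continue
        sessions[-1].append(bout)
    recordings: list[InsoleRecording] = []
    session_idx = 0
    for bouts in sessions:
        if not bouts:
            continue
        session_idx += 1
        loads, phases = [], []
        for bout in bouts:
            load, u = _bout_load_profile(bout, sample_rate_hz, rng)
            loads.append(load)
            phases.append(u)
        load = np.concatenate(loads) if loads else np.zeros(0)
        phase = np.concatenate(phases) if phases else np.zeros(0)
        forces = forces_from_load(load, phase, geometry, profile.bw_n)
        rec = InsoleRecording(
            participant_id=profile.participant_id,
            day=day_index,
            session=session_idx,
            sample_rate_hz=sample_rate_hz,
            f_heel=forces[:, 0],
            f_mid=forces[:, 1],
            f_fore=forces[:, 2],
        )
        if artifacts:
            rec = inject_artifacts(rec, artifacts, geometry, profile.bw_n)
        recordings.append(rec)
    return recordings, truth


# --------------------------------------------------------------------------
# Clinical effect model
# --------------------------------------------------------------------------

#: measure -> (intercept, slope on latent volume, Gaussian noise SD).
#: Magnitudes are plausible for the respective units; slopes/SDs set
#: moderate-to-strong population correlations with the latent volume.
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "moment_isometric": (7.0, 6.0, 1.4),
    "moment_isokinetic_slow": (6.0, 5.0, 1.3),
    "moment_isokinetic_fast": (4.5, 5.0, 1.1),
    "power_isokinetic_slow": (4.0, 4.0, 1.1),
    "power_isokinetic_fast": (9.0, 8.0, 2.2),
    "work_isokinetic_slow": (5.0, 4.0, 1.1),
    "work_isokinetic_fast": (3.0, 3.0, 0.9),
    "heel_raise_height": (3.5, 4.0, 0.9),
    "cmj_height": (4.0, 6.0, 1.5),
    "heel_raise_reps": (8.0, 16.0, 4.5),
    "age": (58.0, -16.0, 7.0),
    "visa_a": (35.0, 45.0, 10.0),
    "pas": (1.6, 3.8, 0.55),
}

_CLINICAL_BOUNDS = {"visa_a": (0.0, 100.0), "pas": (1.0, 6.0), "age": (18.0, 70.0)}


@dataclass(frozen=True)
class EffectSpec:
    """Linear + Gaussian-noise links from latent volume to clinical measures."""

    effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )

    def __post_init__(self) -> None:
        unknown = set(self.effects) - set(CLINICAL_MEASURES)
        if unknown:
            raise ValueError(f"effects for unknown measures: {sorted(unknown)}")
        missing = set(CLINICAL_MEASURES) - set(self.effects)
        if missing:
            raise ValueError(f"missing effects for measures: {sorted(missing)}")

    def implied_r(self, measure: str, volume_sd: float = math.sqrt(1.0 / 12)) -> float:
        """Closed-form population Pearson r between the latent volume and a
        measure, for latent volume ~ U(0, 1) (sd = 1/sqrt(12))."""
        _, slope, sd = self.effects[measure]
        denom = math.sqrt(slope**2 * volume_sd**2 + sd**2)
        return slope * volume_sd / denom if denom > 0 else 0.0

    def scaled_noise(self, factor: float) -> "EffectSpec":
        """Same linear links with all noise SDs multiplied by ``factor``."""
        return EffectSpec(
            {k: (a, b, s * factor) for k, (a, b, s) in self.effects.items()}
        )


def _draw_clinical(
    rng: np.random.Generator, volume: float, spec: EffectSpec
) -> dict[str, float]:
    row: dict[str, float] = {}
    for measure in CLINICAL_MEASURES:
        a, b, sd = spec.effects[measure]
        val = a + b * volume + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        lo_hi = _CLINICAL_BOUNDS.get(measure)
        if lo_hi is not None:
            val = float(np.clip(val, *lo_hi))
        row[measure] = float(val)
    return row


# --------------------------------------------------------------------------
# Schedules
# --------------------------------------------------------------------------

def build_day_schedule(
    rng: np.random.Generator,
    volume: float,
    walk_peak_bw: float,
    base_walk_h: float,
    day_scale: float = 1.0,
) -> list[Bout]:
    """One day of activity for a participant with latent volume in [0, 1].

    Walking dominates and is stable day to day; light ambulation
    (standing shifts, chores) adds loading time at low load, diluting the
    mean load-per-loading-hour below the brisk-walking level; running and
    jumping occur only on stochastic "training days" whose probability
    and dose scale with the latent volume, making high-level load bursty
    across days.  A mid-day non-wear stretch splits the day into two
    recordings.

    ``day_scale`` shrinks every bout duration proportionally (a
    miniature day with the same activity mix), for fast end-to-end runs.
    """
    if day_scale <= 0:
        raise ValueError("day_scale must be > 0")
    walk_h = float(np.clip(rng.normal(base_walk_h, 0.35), 1.2, 6.0))
    light_h = float(np.clip(rng.normal(2.6, 0.4), 1.2, 4.0))
    light_peak = float(np.clip(rng.normal(0.95, 0.08), 0.6, 1.3))
    training = rng.random() < 0.75 * volume
    peak = float(np.clip(walk_peak_bw + rng.normal(0.0, 0.06), 1.6, 2.9))
    sched = [
        make_bout("rest", 900.0),
        make_bout("walk", walk_h * 0.45 * 3600.0, intensity_bw=peak),
        make_bout("walk", light_h * 0.5 * 3600.0, intensity_bw=light_peak,
                  cadence_per_min=50.0, stance_s=0.85),
        make_bout("rest", 600.0),
        make_bout("walk", walk_h * 0.25 * 3600.0, intensity_bw=peak),
    ]
    if training:
        run_min = 10.0 + 25.0 * volume
        jump_min = 1.5 + 3.0 * volume
        run_peak = float(np.clip(4.5 + 0.8 * volume + rng.normal(0, 0.1), 3.4, 5.4))
        jump_peak = float(np.clip(4.8 + 1.2 * volume + rng.normal(0, 0.15), 3.6, 6.2))
        sched += [
            make_bout("run", run_min * 60.0, intensity_bw=run_peak),
            make_bout("rest", 300.0),
            make_bout("jump", jump_min * 60.0, intensity_bw=jump_peak),
        ]
    sched += [
        make_bout("rest", 600.0),
        make_bout("nonwear", 2400.0),  # session break
        make_bout("walk", walk_h * 0.30 * 3600.0, intensity_bw=peak),
        make_bout("walk", light_h * 0.5 * 3600.0, intensity_bw=light_peak,
                  cadence_per_min=50.0, stance_s=0.85),
        make_bout("rest", 900.0),
    ]
    if day_scale != 1.0:
        sched = [
            Bout(
                kind=b.kind,
                duration_s=b.duration_s * day_scale,
                intensity_bw=b.intensity_bw,
                cadence_per_min=b.cadence_per_min,
                stance_s=b.stance_s,
            )
            for b in sched
        ]
    return sched


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """A simulated cohort: profiles, schedules, clinical table, truth.

    Recordings are not materialized up front (a full cohort is tens of
    millions of samples); :meth:`recordings_for` regenerates any day's
    sessions deterministically from stored per-day seeds.
    """

    profiles: list[ParticipantProfile]
    clinical: pd.DataFrame
    schedules: dict[str, dict[int, list[Bout]]]
    day_seeds: dict[tuple[str, int], int]
    day_truth: dict[tuple[str, int], GroundTruthSummary]
    geometry: SensorGeometry
    thresholds: LoadThresholds
    sample_rate_hz: float
    seed: int
    effect_spec: EffectSpec

    def profile(self, participant_id: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def participant_truth(self, participant_id: str) -> GroundTruthSummary:
        total = GroundTruthSummary()
        for day in sorted(self.schedules[participant_id]):
            total = total + self.day_truth[(participant_id, day)]
        return total

    def recordings_for(
        self, participant_id: str, day: int, artifacts: Sequence[Artifact] = ()
    ) -> list[InsoleRecording]:
        profile = self.profile(participant_id)
        recs, _ = simulate_day(
            profile,
            self.schedules[participant_id][day],
            seed=self.day_seeds[(participant_id, day)],
            day_index=day,
            geometry=self.geometry,
            artifacts=artifacts,
            thresholds=self.thresholds,
            sample_rate_hz=self.sample_rate_hz,
        )
        return recs

    def iter_days(
        self,
    ) -> Iterator[tuple[ParticipantProfile, int, list[InsoleRecording]]]:
        for p in self.profiles:
            for day in sorted(self.schedules[p.participant_id]):
                yield p, day, self.recordings_for(p.participant_id, day)


def simulate_cohort(
    n_participants: int = 15,
    n_days: int = 10,
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    geometry: SensorGeometry = SensorGeometry(),
    thresholds: LoadThresholds = LoadThresholds(),
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    volume_range: tuple[float, float] = (0.0, 1.0),
    day_scale: float = 1.0,
) -> CohortBundle:
    """Simulate a monitoring cohort with known ground truth.

    Defaults emulate the study design this package targets: 15
    participants monitored ~10 days each, full-day wear with a couple of
    hours of daily tendon loading, and clinical measures linearly linked
    (plus Gaussian noise) to each participant's latent activity volume.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    spec = effect_spec if effect_spec is not None else EffectSpec()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_participants + 1)
    cohort_rng = np.random.default_rng(children[0])

    lo, hi = volume_range
    volumes = cohort_rng.uniform(lo, hi, n_participants)
    masses = np.clip(cohort_rng.normal(90.0, 20.0, n_participants), 55.0, 140.0)
    heights = np.clip(cohort_rng.normal(1.72, 0.10, n_participants), 1.50, 1.95)

    profiles: list[ParticipantProfile] = []
    clinical_rows: list[dict[str, float | str]] = []
    schedules: dict[str, dict[int, list[Bout]]] = {}
    day_seeds: dict[tuple[str, int], int] = {}
    day_truth: dict[tuple[str, int], GroundTruthSummary] = {}

    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        sub = children[i + 1].spawn(n_days + 1)
        trait_rng = np.random.default_rng(sub[0])
        volume = float(volumes[i])
        clin = _draw_clinical(trait_rng, volume, spec)
        profiles.append(
            ParticipantProfile(
                participant_id=pid,
                mass_kg=float(masses[i]),
                height_m=float(heights[i]),
                age=clin["age"],
                visa_a=clin["visa_a"],
                pas=clin["pas"],
                latent_volume=volume,
            )
        )
        clinical_rows.append(
            {
                "participant_id": pid,
                "mass_kg": float(masses[i]),
                "height_m": float(heights[i]),
                **clin,
            }
        )
        walk_peak = float(np.clip(2.0 + 0.8 * trait_rng.random(), 1.6, 2.9))
        base_walk_h = 3.0 + 1.0 * volume
        schedules[pid] = {}
        for day in range(1, n_days + 1):
            day_ss = sub[day]
            day_rng = np.random.default_rng(day_ss)
            sched = build_day_schedule(
                day_rng, volume, walk_peak, base_walk_h, day_scale=day_scale
            )
            schedules[pid][day] = sched
            day_seeds[(pid, day)] = int(day_ss.generate_state(1)[0] % (2**31))
            truth = GroundTruthSummary()
            for bout in sched:
                truth = truth + bout_ground_truth(bout, thresholds)
            day_truth[(pid, day)] = truth

    clinical = pd.DataFrame(clinical_rows)
    return CohortBundle(
        profiles=profiles,
        clinical=clinical,
        schedules=schedules,
        day_seeds=day_seeds,
        day_truth=day_truth,
        geometry=geometry,
        thresholds=thresholds,
        sample_rate_hz=sample_rate_hz,
        seed=seed,
        effect_spec=spec,
    )


def write_cohort(bundle: CohortBundle, outdir: Path | str) -> tuple[Path, Path]:
    """Write a cohort to disk: session CSVs, manifest, clinical table.

    Returns (manifest_path, clinical_path).  Intended for modest cohorts;
    large cohorts are better consumed in memory via :meth:`CohortBundle
    .iter_days`.
    """
    outdir = Path(outdir)
    sessions_dir = outdir / "sessions"
    sessions_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for profile, day, recordings in bundle.iter_days():
        for rec in recordings:
            fname = f"{rec.session_id}.csv"
            write_recording(rec, sessions_dir / fname)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "day": rec.day,
                    "session": rec.session,
                    "path": f"sessions/{fname}",
                    "date": f"2025-03-{rec.day:02d}",
                }
            )
    manifest = CohortManifest(pd.DataFrame(rows, columns=list(CohortManifest.COLUMNS)))
    manifest_path = outdir / "manifest.csv"
    clinical_path = outdir / "clinical.csv"
    write_manifest(manifest, manifest_path)
    write_clinical_table(bundle.clinical, clinical_path)
    return manifest_path, clinical_path
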