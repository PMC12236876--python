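"""Achilles tendon load estimation by ankle moment balance.

Each insole pad force ``F_i`` (assumed perpendicular to the sole, applied
at a fixed per-pad center of pressure) produces a moment about the ankle
joint with signed lever arm ``r_i`` (anterior positive, so the heel pad arm
is negative).  The net plantarflexion moment is

    M_PF = F_heel * r_heel + F_mid * r_mid + F_fore * r_fore

and the Achilles tendon load follows by dividing by the tendon moment arm
``r_AT`` (default 5 cm) and normalizing by body weight:

    F_AT = max(M_PF / r_AT, 0) / BW        (unit: xBW)

Dorsiflexion moments (heel-dominant loading) give a negative M_PF; the
tendon cannot transmit a compressive push, so these samples are clamped to
zero tendon load.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .insole_io import InsoleRecording

__all__ = ["SensorGeometry", "TendonLoadSeries", "estimate_tendon_load"]

#: Gravitational acceleration used to convert body mass to body weight.
GRAVITY_N_PER_KG = 9.81


@dataclass(frozen=True)
class SensorGeometry:
    """Signed pad moment arms about the ankle and the tendon moment arm.

    Defaults are nominal mid-size values; real pads scale with shoe size,
    so :meth:`scaled` applies a common size factor to the pad arms.

    Parameters
    ----------
    r_heel, r_mid, r_fore:
        Pad lever arms in meters, anterior positive (``r_heel < 0``).
    r_at:
        Achilles tendon moment arm in meters (default 0.05).
    """

    r_heel: float = -0.06
    r_mid: float = 0.04
    r_fore: float = 0.11
    r_at: float = 0.05

    def __post_init__(self) -> None:
        if self.r_at <= 0:
            raise ValueError(f"r_at must be > 0, got {self.r_at}")
        if not (self.r_fore > self.r_mid > self.r_heel):
            raise ValueError(
                "moment arms must satisfy r_fore > r_mid > r_heel, got "
                f"({self.r_heel}, {self.r_mid}, {self.r_fore})"
            )

    @property
    def pad_arms(self) -> np.ndarray:
        return np.array([self.r_heel, self.r_mid, self.r_fore])

    def scaled(self, size_factor: float) -> "SensorGeometry":
        """Scale the three pad arms (not r_AT) by a shoe-size factor."""
        if size_factor <= 0:
            raise ValueError("size_factor must be > 0")
        return replace(
            self,
            r_heel=self.r_heel * size_factor,
            r_mid=self.r_mid * size_factor,
            r_fore=self.r_fore * size_factor,
        )


@dataclass
class TendonLoadSeries:
    """Per-sample Achilles tendon load in body weights (xBW)."""

    load_bw: np.ndarray
    sample_rate_hz: float
    source: str = ""

    def __post_init__(self) -> None:
        self.load_bw = np.asarray(self.load_bw, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.load_bw)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


def plantarflexion_moment(
    recording: InsoleRecording, geometry: SensorGeometry
) -> np.ndarray:
    """Net ankle plantarflexion moment M_PF in N*m (signed, unclamped)."""
    return recording.channels() @ geometry.pad_arms


def estimate_tendon_load(
    recording: InsoleRecording,
    geometry: SensorGeometry,
    bw_n: float,
) -> TendonLoadSeries:
    """Estimate the body-weight-normalized Achilles tendon load series.

    Parameters
    ----------
    recording:
        A post-QC insole session (forces in newtons).
    geometry:
        Pad and tendon moment arms.
    bw_n:
        Participant body weight in newtons.

    Raises
    ------
    ValueError
        If ``bw_n <= 0`` or any force sample is non-finite (the message
        names the first offending sample index).
    """
    if bw_n <= 0:
        raise ValueError(f"bw_n must be > 0, got {bw_n}")
    forces = recording.channels()
    finite = np.isfinite(forces).all(axis=1)
    if not finite.all():
        idx = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite force at sample {idx}")
    m_pf = forces @ geometry.pad_arms
    f_at = np.maximum(m_pf / geometry.r_at, 0.0) / bw_n
    return TendonLoadSeries(
        load_bw=f_at,
        sample_rate_hz=recording.sample_rate_hz,
        source=recording.session_id,
    )
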