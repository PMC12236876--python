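"""Reading and writing insole session recordings and cohort tables.

A *session* is one continuous logging bout of a three-pad force-sensing
insole (heel, midfoot, forefoot pads) sampled at a fixed rate, nominally
20 Hz.  Sessions are stored in a small self-describing CSV dialect::

    participant_id,day,session,sample_rate_hz
    P01,1,1,20
    time_s,f_heel_n,f_mid_n,f_fore_n
    0.00,0,0,312.5
    ...

The explicit time column is redundant with the sample rate but is kept so
logger gaps (dropped packets, pauses) are detectable at parse time rather
than silently absorbed.

Cohort-level inputs are a session *manifest* (one row per session file) and
a *clinical table* (one row per participant carrying body size, survey
scores and the plantar-flexor function measures used for correlation).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InsoleRecording",
    "CohortManifest",
    "FormatError",
    "CLINICAL_MEASURES",
    "CLINICAL_ID_COLUMNS",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "read_clinical_table",
    "write_clinical_table",
    "read_cohort_tables",
]

_FORCE_COLUMNS = ("f_heel_n", "f_mid_n", "f_fore_n")
_HEADER_KEYS = ("participant_id", "day", "session", "sample_rate_hz")

#: Canonical clinical-table measure columns: seven dynamometer capacity
#: measures (normalized by body height x weight), three motion-capture
#: dynamic-function measures, and three survey measures.
CLINICAL_MEASURES = (
    "moment_isometric",       # peak plantar flexor moment, isometric (%HxW)
    "moment_isokinetic_slow",  # peak moment at 30 deg/s (%HxW)
    "moment_isokinetic_fast",  # peak moment at 150 deg/s (%HxW)
    "power_isokinetic_slow",   # peak power at 30 deg/s (%HxW x rad/s)
    "power_isokinetic_fast",   # peak power at 150 deg/s (%HxW x rad/s)
    "work_isokinetic_slow",    # mechanical work per contraction at 30 deg/s
    "work_isokinetic_fast",    # mechanical work per contraction at 150 deg/s
    "heel_raise_height",       # double-leg heel raise height (%BH)
    "cmj_height",              # single-leg countermovement jump height (%BH)
    "heel_raise_reps",         # single-leg incline heel raise repetitions
    "age",                     # years
    "visa_a",                  # VISA-A symptom score, 0-100
    "pas",                     # Physical Activity Scale, 1-6
)

CLINICAL_ID_COLUMNS = ("participant_id", "mass_kg", "height_m")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class InsoleRecording:
    """One insole logging session: three plantar force channels in newtons."""

    participant_id: str
    day: int
    session: int
    sample_rate_hz: float
    f_heel: np.ndarray
    f_mid: np.ndarray
    f_fore: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        self.f_heel = np.asarray(self.f_heel, dtype=float)
        self.f_mid = np.asarray(self.f_mid, dtype=float)
        self.f_fore = np.asarray(self.f_fore, dtype=float)
        n = len(self.f_heel)
        if len(self.f_mid) != n or len(self.f_fore) != n:
            raise ValueError("force channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.f_heel)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def session_id(self) -> str:
        return f"{self.participant_id}-d{self.day:02d}-s{self.session:02d}"

    def channels(self) -> np.ndarray:
        """Stack channels as an (n, 3) array in heel, mid, fore order."""
        return np.column_stack([self.f_heel, self.f_mid, self.f_fore])

    def copy(self) -> "InsoleRecording":
        return replace(
            self,
            f_heel=self.f_heel.copy(),
            f_mid=self.f_mid.copy(),
            f_fore=self.f_fore.copy(),
        )


@dataclass
class CohortManifest:
    """Index of every session file in a cohort."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("participant_id", "day", "session", "path", "date")

    def __post_init__(self) -> None:
        if self.table.empty and len(self.table.columns) == 0:
            self.table = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        keys = self.table[["participant_id", "day", "session"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate manifest entry: {dup}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def participants(self) -> list[str]:
        return sorted(self.table["participant_id"].unique())

    def sessions_for(self, participant_id: str) -> pd.DataFrame:
        rows = self.table[self.table["participant_id"] == participant_id]
        return rows.sort_values(["day", "session"])

    def resolve_paths(self, root: Path | str | None = None) -> None:
        """Raise ``FormatError`` if any listed session file is missing."""
        base = Path(root) if root is not None else Path(".")
        for p in self.table["path"]:
            full = Path(p) if Path(p).is_absolute() else base / p
            if not full.exists():
                raise FormatError(f"manifest references missing file: {full}")


def _fmt(x: float) -> str:
    """Serialize a numeric field with 6 significant digits, no exponent drift."""
    return format(float(x), ".6g")


def write_recording(recording: InsoleRecording, path: Path | str) -> None:
    """Write a session in the dialect above (deterministic byte output)."""
    dt = 1.0 / recording.sample_rate_hz
    lines = [
        ",".join(_HEADER_KEYS),
        f"{recording.participant_id},{recording.day},{recording.session},"
        f"{_fmt(recording.sample_rate_hz)}",
        "time_s,f_heel_n,f_mid_n,f_fore_n",
    ]
    t = np.arange(recording.n_samples) * dt
    for i in range(recording.n_samples):
        lines.append(
            f"{_fmt(t[i])},{_fmt(recording.f_heel[i])},"
            f"{_fmt(recording.f_mid[i])},{_fmt(recording.f_fore[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_recording(path: Path | str) -> InsoleRecording:
    """Parse a session file, rejecting malformed input rather than coercing.

    Raises
    ------
    FormatError
        On a missing column, a non-numeric cell, or a non-uniform implied
        timestep; the message names the offending line number (1-based).
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: expected 3 header lines, got {len(lines)}")
    if tuple(lines[0].strip().split(",")) != _HEADER_KEYS:
        raise FormatError(f"{path}: line 1: bad header keys {lines[0]!r}")
    vals = lines[1].strip().split(",")
    if len(vals) != len(_HEADER_KEYS):
        raise FormatError(f"{path}: line 2: expected {len(_HEADER_KEYS)} header values")
    participant_id = vals[0]
    try:
        day, session = int(vals[1]), int(vals[2])
        rate = float(vals[3])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2: non-numeric header value ({exc})") from exc

    cols = tuple(lines[2].strip().split(","))
    expected = ("time_s",) + _FORCE_COLUMNS
    if cols != expected:
        missing = set(expected) - set(cols)
        raise FormatError(
            f"{path}: line 3: bad column header {cols!r}"
            + (f" (missing {sorted(missing)})" if missing else "")
        )

    try:
        body = pd.read_csv(
            io.StringIO(text), skiprows=2, dtype=float, na_filter=False
        )
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data cell ({exc})") from exc

    t = body["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.flatnonzero(np.abs(dt - 1.0 / rate) > 0.5 / rate)
        if bad.size:
            # +5: 3 header lines + 1-based indexing + diff offset
            raise FormatError(
                f"{path}: line {bad[0] + 5}: non-uniform timestep "
                f"{dt[bad[0]]:.4f} s (expected {1.0 / rate:.4f} s)"
            )
    return InsoleRecording(
        participant_id=participant_id,
        day=day,
        session=session,
        sample_rate_hz=rate,
        f_heel=body["f_heel_n"].to_numpy(),
        f_mid=body["f_mid_n"].to_numpy(),
        f_fore=body["f_fore_n"].to_numpy(),
    )


def write_manifest(manifest: CohortManifest, path: Path | str) -> None:
    manifest.table.to_csv(path, index=False)


def read_manifest(path: Path | str, check_paths: bool = True) -> CohortManifest:
    table = pd.read_csv(path, dtype={"participant_id": str, "path": str})
    manifest = CohortManifest(table)
    if check_paths:
        manifest.resolve_paths(root=Path(path).parent)
    return manifest


def write_clinical_table(clinical: pd.DataFrame, path: Path | str) -> None:
    clinical.to_csv(path, index=False, float_format="%.6g")


def read_clinical_table(path: Path | str) -> pd.DataFrame:
    """Load and validate the per-participant clinical table.

    One row per participant.  Unknown columns are dropped with a warning;
    missing values are permitted (empty cells) and handled downstream by
    pairwise-complete correlation.  Range checks: mass > 0, VISA-A in
    [0, 100], PAS in [1, 6].
    """
    table = pd.read_csv(path, dtype={"participant_id": str})
    required = set(CLINICAL_ID_COLUMNS) | set(CLINICAL_MEASURES)
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    unknown = [c for c in table.columns if c not in required]
    if unknown:
        warnings.warn(f"clinical table: ignoring unknown columns {unknown}")
        table = table.drop(columns=unknown)
    if table["participant_id"].duplicated().any():
        dup = table["participant_id"][table["participant_id"].duplicated()].iloc[0]
        raise FormatError(f"clinical table: duplicate participant id {dup!r}")
    if (table["mass_kg"].dropna() <= 0).any():
        raise FormatError("clinical table: non-positive body mass")
    visa = table["visa_a"].dropna()
    if ((visa < 0) | (visa > 100)).any():
        bad = visa[(visa < 0) | (visa > 100)].iloc[0]
        raise FormatError(f"clinical table: VISA-A out of range 0-100: {bad}")
    pas = table["pas"].dropna()
    if ((pas < 1) | (pas > 6)).any():
        bad = pas[(pas < 1) | (pas > 6)].iloc[0]
        raise FormatError(f"clinical table: PAS out of range 1-6: {bad}")
    return table.reset_index(drop=True)


def read_cohort_tables(
    manifest_path: Path | str, clinical_path: Path | str
) -> tuple[CohortManifest, pd.DataFrame]:
    """Load the session manifest and clinical table for one cohort."""
    return read_manifest(manifest_path), read_clinical_table(clinical_path)
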