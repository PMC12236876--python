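import numpy as np
import pytest

from atload import InsoleRecording, SensorGeometry, TendonLoadSeries
from atload.pipeline import analyze_cohort
from atload.synthetic_data import simulate_cohort

BW_N = 660.0


def make_series(values, rate=20.0, source="test"):
    return TendonLoadSeries(np.asarray(values, dtype=float), rate, source)


def make_recording(heel, mid, fore, rate=20.0, pid="T01", day=1, session=1):
    return InsoleRecording(
        participant_id=pid,
        day=day,
        session=session,
        sample_rate_hz=rate,
        f_heel=np.asarray(heel, dtype=float),
        f_mid=np.asarray(mid, dtype=float),
        f_fore=np.asarray(fore, dtype=float),
    )


@pytest.fixture
def geometry():
    return SensorGeometry()


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale synthetic cohort (15 participants x 10 days) passed
    through the full QC + estimation + summarization pipeline once."""
    bundle = simulate_cohort(seed=2025)
    analysis = analyze_cohort(bundle, qc_enabled=True)
    return bundle, analysis
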