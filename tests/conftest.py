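from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vaxwatch.preprocessing import HourlySeries, STATUS_MISSING, STATUS_OBSERVED


ORIGIN = pd.Timestamp("2021-08-09 10:30")  # a Monday morning


def make_series(
    values,
    start: int = 0,
    origin: pd.Timestamp = ORIGIN,
    participant_id: str = "P00000",
    channel: str = "heart_rate",
) -> HourlySeries:
    """HourlySeries from a value list; NaN entries become missing cells."""
    values = np.asarray(values, dtype=float)
    status = np.where(np.isnan(values), STATUS_MISSING, STATUS_OBSERVED).astype(np.int8)
    return HourlySeries(participant_id, channel, origin, start, values, status)


@pytest.fixture
def rng():
    return np.random.default_rng(20210909)


@pytest.fixture(scope="session")
def small_pipeline_run(tmp_path_factory):
    """One full pipeline run on a small synthetic cohort, shared by tests."""
    import vaxwatch as vw
    from vaxwatch.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(
        simulation=vw.SimulationConfig(n_participants=8, gap_rate=0.3),
        out_dir=str(out),
        seed=42,
    )
    report = run_pipeline(config)
    return config, report, out
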