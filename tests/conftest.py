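import numpy as np
import pandas as pd
import pytest

from smlmclust import FieldBounds, LocalizationTable


def make_table(
    x, y, uncertainty=20.0, frame=None, intensity=500.0,
    frame_interval_ms=33.0, field_bounds=None,
):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    df = pd.DataFrame(
        {
            "frame": np.arange(1, n + 1) if frame is None else np.asarray(frame, int),
            "x": x,
            "y": y,
            "uncertainty": np.broadcast_to(np.asarray(uncertainty, float), n).copy(),
            "intensity": np.broadcast_to(np.asarray(intensity, float), n).copy(),
        }
    )
    return LocalizationTable(
        df=df, frame_interval_ms=frame_interval_ms, field_bounds=field_bounds
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_field():
    return FieldBounds(0.0, 0.0, 4000.0, 4000.0)
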