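import numpy as np
import pytest

from eogsemg import (GenConfig, make_schedule, synthesize,
                     calibrate_thresholds)


CAL_LABELS = ("right", "left", "right_blink", "left_blink",
              "bite", "normal_blink")


def make_calibration(config=None, repeats=3):
    """Calibration recording + fitted thresholds for a given generator config."""
    cfg = config or GenConfig(seed=42)
    sched = make_schedule(CAL_LABELS, repeats=repeats, interval=3.0)
    rec, truth = synthesize(sched, cfg)
    return calibrate_thresholds(rec, truth), rec, truth


@pytest.fixture(scope="session")
def default_calibration():
    """Thresholds for the default synthetic user (shared across tests)."""
    cal, _, _ = make_calibration(GenConfig(seed=42))
    return cal


@pytest.fixture
def clean_config():
    """Noise-free, drift-free generator configuration."""
    return GenConfig(seed=0, drift_rate=0.0, drift_walk_sigma=0.0,
                     line_noise_amp=0.0, white_noise_sigma=0.0)
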