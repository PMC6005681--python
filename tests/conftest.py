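import numpy as np
import pandas as pd
import pytest

from amdetect.synthetic import (
    BehavioralSession, UnitRecording, default_config, draw_tuning,
    generate_session, generate_unit,
)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def ctl_session(config):
    return generate_session(config, "a00", "ctl", 256.0, n_trials=300, seed=11)


@pytest.fixture(scope="session")
def ctl_unit(config, ctl_session):
    rng = np.random.default_rng(5)
    tuning = draw_tuning(config.tuning["ctl"], 256.0, rng)
    return generate_unit(config, ctl_session, tuning, seed=7, unit_id="u0")


def make_unit_from_counts(go_counts_by_depth, nogo_counts, duration=1.0,
                          rate_hz=256.0, seed=0, responses=None):
    """Build a UnitRecording whose per-trial spike counts are exactly the
    given integers (spikes placed uniformly at random in the window)."""
    rng = np.random.default_rng(seed)
    rows, spikes = [], []
    for depth, counts in go_counts_by_depth.items():
        for c in counts:
            rows.append({"type": "go", "depth_db": float(depth)})
            spikes.append(np.sort(rng.uniform(0, duration, int(c))))
    for c in nogo_counts:
        rows.append({"type": "nogo", "depth_db": np.nan})
        spikes.append(np.sort(rng.uniform(0, duration, int(c))))
    trials = pd.DataFrame(rows)
    trials["trial"] = np.arange(len(trials))
    if responses is None:
        trials["response"] = "spout"
        trials["outcome"] = np.where(trials["type"] == "go", "hit", "fa")
    else:
        trials["response"] = responses
        trials["outcome"] = np.where(
            trials["response"] == "spout",
            np.where(trials["type"] == "go", "hit", "fa"),
            np.where(trials["type"] == "go", "miss", "cr"),
        )
    return UnitRecording(
        unit_id="toy", animal_id="a", hearing_status="ctl", rate_hz=rate_hz,
        isolation="multi", spikes=spikes, trials=trials, am_duration_s=duration,
    )


def make_session_from_outcomes(go_outcomes_by_depth, n_fa, n_cr,
                               rate_hz=256.0) -> BehavioralSession:
    """Session with exact per-depth hit/miss and Nogo fa/cr counts."""
    rows = []
    for depth, (n_hit, n_miss) in go_outcomes_by_depth.items():
        rows += [{"type": "go", "depth_db": float(depth), "response": "spout",
                  "outcome": "hit"}] * n_hit
        rows += [{"type": "go", "depth_db": float(depth), "response": "repoke",
                  "outcome": "miss"}] * n_miss
    rows += [{"type": "nogo", "depth_db": np.nan, "response": "spout",
              "outcome": "fa"}] * n_fa
    rows += [{"type": "nogo", "depth_db": np.nan, "response": "repoke",
              "outcome": "cr"}] * n_cr
    trials = pd.DataFrame(rows)
    trials["trial"] = np.arange(len(trials))
    trials["latency_s"] = 0.5
    trials["level_db_spl"] = 45.0
    return BehavioralSession(
        animal_id="a", hearing_status="ctl", rate_hz=rate_hz, trials=trials,
        level_db_spl=45.0, seed=0, session_id="a-toy",
    )
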