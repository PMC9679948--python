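import numpy as np
import pandas as pd
import pytest

from keytype.synthetic_cohort import CohortConfig, simulate_cohort


def events_frame(rows):
    """Build a canonical event frame from (subject, t_ms, action, key_class[, token]) tuples."""
    recs = []
    for r in rows:
        subject, t, action, key_class = r[:4]
        token = r[4] if len(r) > 4 else ""
        recs.append(
            {
                "subject_id": subject,
                "timestamp_ms": int(t),
                "action": action,
                "key_class": key_class,
                "key_token": token,
            }
        )
    return pd.DataFrame(recs)


def key_instances(specs, subject="S0"):
    """Events from (press_s, release_s, key_class) triples (seconds), one token each."""
    rows = []
    for i, (press, release, cls) in enumerate(specs):
        tok = f"t{i}"
        rows.append((subject, round(press * 1000), "press", cls, tok))
        if release is not None:
            rows.append((subject, round(release * 1000), "release", cls, tok))
    df = events_frame(rows).sort_values("timestamp_ms", kind="stable").reset_index(drop=True)
    df["session_id"] = 0
    return df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort reused by pipeline-level tests."""
    config = CohortConfig(
        n_subjects=24,
        events_per_day_mean=120.0,
        events_per_day_sd=30.0,
        typing_days="windows_only",
    )
    return simulate_cohort(config, seed=11)
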