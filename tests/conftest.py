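"""Shared fixtures: one small simulated study reused across the suite.

Stream durations are kept short (a few seconds per challenge) so the
whole-suite cohort generation stays fast; structural properties do not
depend on duration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import tabletbio as tb


SMALL_CFG = dict(
    n_participants=5,
    n_reference=8,
    rocket_duration=5.0,
    connect_duration=7.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = tb.simulate_cohort_records(tb.SimulationConfig(**SMALL_CFG))
    return cohort, truth


@pytest.fixture(scope="session")
def small_reference():
    cfg = tb.SimulationConfig(**{**SMALL_CFG, "n_participants": 8})
    cohort, truth = tb.simulate_cohort_records(cfg, prefix="r", seed_offset=1)
    return cohort, truth


@pytest.fixture(scope="session")
def connect_scores(small_cohort, small_reference):
    """Multimodal Connect construct scores of the small cohort, projected
    through a reference-fitted PCA."""
    cohort, _ = small_cohort
    reference, _ = small_reference
    model, scores = tb.build_constructs(
        reference.challenges, cohort.challenges, "Connect", "multimodal"
    )
    return model, scores


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_cohort):
    cohort, truth = small_cohort
    path = tmp_path_factory.mktemp("cohort") / "c"
    tb.write_cohort(cohort, path)
    return path


def random_gaze_trace(rng: np.random.Generator, n: int = 60) -> pd.DataFrame:
    """A random (not physiologic) gaze trace for oracle-equivalence tests:
    irregular timestamps, wildly varying angular steps."""
    dt = rng.uniform(0.005, 0.08, size=n - 1)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    theta = np.cumsum(rng.uniform(-8, 8, size=(n, 2)), axis=0)
    ax, el = np.radians(theta[:, 0]), np.radians(theta[:, 1])
    dirs = np.column_stack(
        [np.sin(ax) * np.cos(el), np.sin(el), np.cos(ax) * np.cos(el)]
    )
    return pd.DataFrame({"t": t, "dx": dirs[:, 0], "dy": dirs[:, 1], "dz": dirs[:, 2]})
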