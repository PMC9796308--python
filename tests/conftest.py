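"""Shared fixtures: simulated datasets are generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from switchbf import classify, generate
from switchbf.design import ResponseMapping


def make_sequence_only_sessions(n_sessions: int, seed: int) -> pd.DataFrame:
    """Error-free classified sessions (structure only, RT constant)."""
    rng = np.random.default_rng(seed)
    frames = []
    for pid in range(n_sessions):
        mapping = ResponseMapping.standard(pid % 8 + 1)
        df = generate._session_structure(pid, "pro", mapping, rng)
        df["correct"] = True
        df["rt_ms"] = 500.0
        frames.append(df)
    return classify.apply_trial_exclusions(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def sequence_sessions_500() -> pd.DataFrame:
    return make_sequence_only_sessions(500, seed=20240601)


def simulate_classified(n_per_group: int, params: generate.GenerativeParams,
                        seed: int) -> pd.DataFrame:
    trials, _ = generate.simulate_group(n_per_group, params, rng=seed)
    return classify.apply_trial_exclusions(trials)


@pytest.fixture(scope="session")
def slope_only_indices():
    """Indices from 500 participants with only the congruency slope active."""
    from switchbf.indices import compute_participant_indices

    params = generate.GenerativeParams(bi_cost=0.0, crs_cost=0.0, fwi_group_d=0.0)
    return compute_participant_indices(simulate_classified(250, params, seed=101))


@pytest.fixture(scope="session")
def bi_only_indices():
    from switchbf.indices import compute_participant_indices

    params = generate.GenerativeParams(
        congruency_slope=0.0, crs_cost=0.0, error_slope_per_competitor=0.0,
        fwi_group_d=0.0,
    )
    return compute_participant_indices(simulate_classified(250, params, seed=102))


@pytest.fixture(scope="session")
def crs_only_indices():
    from switchbf.indices import compute_participant_indices

    params = generate.GenerativeParams(
        congruency_slope=0.0, bi_cost=0.0, error_slope_per_competitor=0.0,
        fwi_group_d=0.0,
    )
    return compute_participant_indices(simulate_classified(250, params, seed=103))


@pytest.fixture(scope="session")
def null_indices():
    """Indices from 500 participants with every effect parameter at zero."""
    from switchbf.indices import compute_participant_indices

    params = generate.GenerativeParams(
        congruency_slope=0.0, bi_cost=0.0, crs_cost=0.0,
        error_slope_per_competitor=0.0, fwi_group_d=0.0,
    )
    return compute_participant_indices(simulate_classified(250, params, seed=104))
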