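"""Index arithmetic, cell averaging, MAD exclusion and questionnaire scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchbf import indices
from switchbf.indices import (
    ExclusionConfig,
    apply_participant_exclusions,
    bi_index,
    cronbach_alpha,
    crs_index,
    linear_congruency_index,
    mad_exclusion,
    per_task_condition_means,
    score_questionnaires,
)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


# ---------------------------------------------------------------------------
# contrast and difference indices
# ---------------------------------------------------------------------------

def test_linear_congruency_hand_computed_example():
    assert linear_congruency_index([500.0, 520.0, 540.0, 560.0]) == pytest.approx(200.0)


def test_linear_congruency_zero_for_equal_means():
    assert linear_congruency_index([512.0] * 4) == 0.0


@settings(max_examples=50, derandomize=True)
@given(m=st.lists(finite, min_size=4, max_size=4), c=finite)
def test_linear_congruency_translation_invariance(m, c):
    base = linear_congruency_index(m)
    shifted = linear_congruency_index([x + c for x in m])
    assert shifted == pytest.approx(base, abs=1e-6 * (1 + abs(c)))


def test_missing_level_gives_missing_index():
    assert np.isnan(linear_congruency_index([500.0, np.nan, 540.0, 560.0]))
    with pytest.raises(ValueError):
        linear_congruency_index([1.0, 2.0, 3.0])


def test_difference_indices():
    assert bi_index(550.0, 525.0) == 25.0
    assert crs_index(530.0, 500.0) == 30.0
    assert bi_index(500.0, 500.0) == 0.0


# ---------------------------------------------------------------------------
# per-task-then-average cell means
# ---------------------------------------------------------------------------

def _toy_classified(rows):
    df = pd.DataFrame(rows)
    defaults = {
        "participant": 1, "group": "pro", "correct": True, "excluded": False,
        "excl_rt_bounds": False, "bi_label": "CBA", "crs_label": "ineligible",
        "crs_valid": False, "n_competitors": 0, "n_competitors_prev": 1,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return df


def test_equal_task_weighting_not_trial_weighting():
    # 10 trials at 400 on task A, 30 trials at 600 on task B: the condition
    # mean weights tasks equally -> 500, not the trial-weighted 550
    rows = [{"task": "colour", "rt_ms": 400.0} for _ in range(10)]
    rows += [{"task": "shape", "rt_ms": 600.0} for _ in range(30)]
    cells = per_task_condition_means(_toy_classified(rows), "competitors", "rt")
    assert cells.by_condition["mean"].item() == pytest.approx(500.0)


def test_single_task_condition_mean_is_that_tasks_mean():
    rows = [{"task": "vertical", "rt_ms": v} for v in (400.0, 500.0, 600.0)]
    cells = per_task_condition_means(_toy_classified(rows), "competitors", "rt")
    assert cells.by_condition["mean"].item() == pytest.approx(500.0)


def test_error_proportion_cell():
    rows = [{"task": "colour", "rt_ms": 500.0, "correct": i >= 2} for i in range(10)]
    cells = per_task_condition_means(_toy_classified(rows), "competitors", "pe")
    assert cells.by_condition["mean"].item() == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# MAD exclusion
# ---------------------------------------------------------------------------

def test_mad_excludes_only_the_planted_outlier():
    values = list(range(1, 11)) + [100]
    keep = mad_exclusion(values, k=2.5)
    assert keep.sum() == 10
    assert not keep[-1]


def test_mad_keeps_everything_when_all_values_equal():
    with pytest.warns(UserWarning):
        keep = mad_exclusion([7.0] * 5)
    assert keep.all()


def test_mad_removes_exactly_planted_outliers_in_a_tight_cluster():
    # cluster spread stays well inside 2.5 scaled MADs (max deviation 10,
    # bound 2.5 * 1.4826 * 5 = 18.5); the planted values are far outside
    cluster = np.linspace(790.0, 810.0, 60)
    planted = np.array([2000.0, 100.0])
    keep = mad_exclusion(np.concatenate([cluster, planted]), k=2.5)
    assert keep[:60].all()
    assert not keep[60:].any()


@settings(max_examples=40, derandomize=True)
@given(
    values=st.lists(st.integers(-1000, 1000), min_size=5, max_size=40),
    a=st.floats(0.1, 50.0), b=st.floats(-1e3, 1e3, allow_nan=False),
)
def test_mad_mask_is_affine_equivariant(values, a, b):
    x = np.asarray(values, dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        np.testing.assert_array_equal(
            mad_exclusion(x), mad_exclusion(a * x + b)
        )


def test_mad_needs_three_values():
    with pytest.raises(ValueError):
        mad_exclusion([1.0, 2.0])


# ---------------------------------------------------------------------------
# questionnaires
# ---------------------------------------------------------------------------

def _questionnaire_frame(n=40, seed=0):
    rng = np.random.default_rng(seed)
    data = {"participant": np.arange(n), "group": ["pro", "anti"] * (n // 2)}
    base = rng.integers(2, 6, size=n)
    for i in range(1, 6):
        data[f"fwi_{i}"] = np.clip(base + rng.integers(-1, 2, size=n), 1, 7)
    for name in ("tired", "bored", "alert", "energetic"):
        data[f"fatigue_{name}"] = rng.integers(1, 8, size=n)
    for i in range(1, 24):
        data[f"loc_{i}"] = rng.integers(0, 2, size=n)
    return pd.DataFrame(data)


def test_composite_scores():
    df = _questionnaire_frame(4)
    for i in range(1, 6):
        df[f"fwi_{i}"] = 7
    df.loc[:, ["fatigue_tired", "fatigue_bored"]] = 7
    df.loc[:, ["fatigue_alert", "fatigue_energetic"]] = 1
    for i in range(1, 24):
        df[f"loc_{i}"] = 1
    scored, _ = score_questionnaires(df)
    assert (scored["fwi"] == 7).all()
    assert (scored["fatigue"] == 7).all()  # alert/energetic reverse-coded as 8 - x
    assert (scored["loc"] == 23).all()


def test_out_of_range_items_raise():
    df = _questionnaire_frame(6)
    df.loc[0, "fwi_3"] = 9
    with pytest.raises(ValueError):
        score_questionnaires(df)
    df = _questionnaire_frame(6)
    df.loc[2, "loc_5"] = 2
    with pytest.raises(ValueError):
        score_questionnaires(df)


def test_cronbach_alpha_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    df = _questionnaire_frame(60, seed=2)
    items = df[[f"fwi_{i}" for i in range(1, 6)]].astype(float)
    ours = cronbach_alpha(items)
    theirs = pg.cronbach_alpha(data=items)[0]
    assert ours == pytest.approx(theirs, rel=1e-9)


# ---------------------------------------------------------------------------
# participant-level exclusion cascade
# ---------------------------------------------------------------------------

def _indices_frame(n=30, seed=1):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "participant": np.arange(n),
        "group": ["pro"] * (n // 2) + ["anti"] * (n - n // 2),
        # deterministic tight clusters: nothing is a 2.5-MAD outlier
        "overall_rt": np.tile(np.linspace(880.0, 920.0, n // 2), 2)[:n],
        "overall_pe": np.tile(np.linspace(0.08, 0.12, n // 2), 2)[:n],
        "n_trials": 448,
    })
    for col in indices.INDEX_COLUMNS:
        df[col] = rng.normal(size=n)
        df[f"{col}_min_cond_n"] = 40
        df[f"{col}_min_taskcond_n"] = 9
    return df


def test_clean_dataset_passes_through_unchanged():
    df = _indices_frame()
    report, kept = apply_participant_exclusions(df)
    assert len(kept) == len(df)
    assert report.reasons == {}


def test_error_cap_applies_before_mad():
    df = _indices_frame()
    df.loc[0, "overall_pe"] = 0.45
    report, kept = apply_participant_exclusions(df)
    assert report.reasons[0] == ["errorCapOver40"]
    assert 0 not in kept["participant"].to_numpy()


def test_extreme_overall_rt_is_mad_excluded_within_group():
    df = _indices_frame()
    df.loc[3, "overall_rt"] = 3000.0
    report, kept = apply_participant_exclusions(df)
    assert "madRt" in report.reasons[3]
    assert 3 not in kept["participant"].to_numpy()


def test_sparse_cell_triggers_min_trials_rule():
    df = _indices_frame()
    df.loc[5, "crs_rt_min_taskcond_n"] = 4
    df.loc[6, "bi_pe_min_cond_n"] = 19
    report, kept = apply_participant_exclusions(df)
    assert report.reasons[5] == ["minTrials"]
    assert report.reasons[6] == ["minTrials"]


def test_offset_delay_filter_direction_is_configurable():
    df = _indices_frame()
    meta = pd.DataFrame({
        "participant": df["participant"],
        "practice_passed": True,
        # even participants have small offset delays, odd ones large;
        # the SD measure sits exactly on its threshold (never triggers)
        "offset_delay_mean_ms": np.where(df["participant"] % 2 == 0, 20.0, 40.0),
        "offset_delay_sd_ms": 36.0,
    })
    cfg = ExclusionConfig(offset_delay_filter=True, offset_delay_comparator="above")
    report, kept = apply_participant_exclusions(df, meta, cfg)
    assert report.reasons[1] == ["offsetDelay"]
    assert 2 not in report.reasons
    assert report.offset_delay_comparator == "above"
    cfg_below = ExclusionConfig(
        offset_delay_filter=True, offset_delay_comparator="below"
    )
    report_b, _ = apply_participant_exclusions(df, meta, cfg_below)
    assert report_b.reasons[2] == ["offsetDelay"]
    assert 1 not in report_b.reasons
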