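"""Trial-level classification and exclusion for the four-task switching paradigm.

Every analysed trial N is annotated with:

* its number of **competitor S-R sets** (0..3): irrelevant dimensions whose
  activated rule points at the key that is *not* the correct response;
* a **backward-inhibition** sequence label: ``ABA`` when the cued task equals
  the task of trial N-2 (the set abandoned on trial N-1 returns), ``CBA``
  otherwise; trials with fewer than two same-block predecessors stay
  ``unclassified``;
* a **competitor-rule-suppression** label, defined only on response
  alternations (correct key of N differs from N-1): ``CRSplus`` when the rule
  that is relevant on trial N was activated -- and, with two shared keys,
  therefore competing -- on trial N-1, ``CRSminus`` when that dimension's
  feature changed (its activated rule on N-1 was compatible);
* control flags for **competitor-rule priming** (an irrelevant dimension's
  competitor rule from N-1 is re-activated on N) and **competitor-remains-
  competitor** (the same rule competes on both trials), which invalidate a
  trial for the CRS cells;
* exclusion flags: first four trials of each block, the two trials following
  an error, full stimulus repetitions (all four features repeat; the
  feature-binding confound), and RT outside 100..3000 ms (RT analyses only).

All sequential definitions operate strictly within a block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (
    DIMENSIONS,
    N_MAPPINGS,
    ResponseMapping,
    Stimulus,
    correct_response,
)

RT_MIN_MS = 100.0
RT_MAX_MS = 3000.0
FIRST_TRIALS_REMOVED = 4
POST_ERROR_LAGS = 2

BI_ABA = "ABA"
BI_CBA = "CBA"
BI_UNCLASSIFIED = "unclassified"

CRS_PLUS = "CRSplus"
CRS_MINUS = "CRSminus"
CRS_INELIGIBLE = "ineligible"

#: previous-trial competitor counts attainable in *both* CRS conditions:
#: CRS+ implies at least one competitor on trial N-1 (the re-used rule
#: itself) and CRS- at most two (the now-relevant dimension was
#: compatible), so equating the degree of previous-trial interference
#: restricts both cells to this common range
CRS_PREV_INTERFERENCE_RANGE = (1, 2)


class InvalidSequenceError(ValueError):
    """Raised when a task sequence violates the 100%-switch constraint."""


class OrderingError(ValueError):
    """Raised when a trial table is not ordered by participant, block, trial."""


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def count_competitors(stimulus: Stimulus, task: str, mapping: ResponseMapping) -> int:
    """Number of irrelevant dimensions whose activated rule competes.

    A rule competes when the key it dictates differs from the correct
    response of the trial.  With four binary dimensions the count is 0..3.
    """
    target = correct_response(stimulus, task, mapping)
    return sum(
        1
        for dim in DIMENSIONS
        if dim != task and mapping.key_for(dim, stimulus.feature(dim)) != target
    )


def classify_bi(task_n2: str, task_n1: str, task_n: str) -> str:
    """Label a within-block task triplet as ABA or CBA.

    ABA means the task of trial N returns to the task of trial N-2, i.e. a
    set that was just abandoned (and presumably inhibited) must be
    re-engaged.  Requires a 100%-switch sequence.
    """
    if task_n == task_n1 or task_n1 == task_n2:
        raise InvalidSequenceError("consecutive trials share a task")
    return BI_ABA if task_n == task_n2 else BI_CBA


def classify_crs(
    prev_stimulus: Stimulus,
    prev_task: str,
    stimulus: Stimulus,
    task: str,
    mapping: ResponseMapping,
) -> tuple[str, dict[str, bool]]:
    """CRS condition of trial N given its within-block predecessor.

    Returns the label and the control flags ``crp`` (competitor-rule
    priming) and ``crc`` (competitor remains competitor); a labelled trial
    enters the CRS cells only when both flags are False.
    """
    if task == prev_task:
        raise InvalidSequenceError("consecutive trials share a task")
    prev_key = correct_response(prev_stimulus, prev_task, mapping)
    key = correct_response(stimulus, task, mapping)
    alternation = key != prev_key

    flags = {"crp": False, "crc": False}
    for dim in DIMENSIONS:
        if dim in (task, prev_task):
            continue
        repeats = stimulus.feature(dim) == prev_stimulus.feature(dim)
        rule_key_prev = mapping.key_for(dim, prev_stimulus.feature(dim))
        competed_prev = rule_key_prev != prev_key
        if repeats and competed_prev:
            flags["crp"] = True
            if mapping.key_for(dim, stimulus.feature(dim)) != key:
                flags["crc"] = True

    if not alternation:
        return CRS_INELIGIBLE, flags
    if stimulus.feature(task) == prev_stimulus.feature(task):
        # the now-relevant rule was activated on N-1; with two shared keys
        # and a response alternation it necessarily competed there
        return CRS_PLUS, flags
    return CRS_MINUS, flags


# ---------------------------------------------------------------------------
# vectorised pipeline
# ---------------------------------------------------------------------------

_FLIP_TABLE = np.array(
    [ResponseMapping.standard(i).flips for i in range(1, N_MAPPINGS + 1)],
    dtype=np.int8,
)

_TASK_CODES = {dim: i for i, dim in enumerate(DIMENSIONS)}


def _require_ordered(df: pd.DataFrame) -> None:
    key = df[["participant", "block", "trial"]]
    if not key.equals(key.sort_values(["participant", "block", "trial"], kind="stable")):
        raise OrderingError("trials must be ordered by participant, block, trial")


def classify_structure(df: pd.DataFrame) -> pd.DataFrame:
    """Annotate a trial table with its sequence-structural columns.

    Expects columns participant, block, trial, task, the four feature
    columns and mapping.  Adds correct_key, n_competitors,
    n_competitors_prev, bi_label, response_alternation, crs_label,
    crp_flag, crc_flag, excl_first_four, excl_full_repetition.  These depend
    only on the generated sequence and stimuli, never on behaviour, so the
    synthetic-data generator runs this *before* drawing RTs and errors.
    """
    _require_ordered(df)
    out = df.copy()
    n = len(out)

    feats = out[list(DIMENSIONS)].to_numpy(dtype=np.int8)  # (n, 4)
    task_code = out["task"].map(_TASK_CODES).to_numpy()
    if np.isnan(task_code.astype(float)).any():
        bad = sorted(set(out["task"]) - set(DIMENSIONS))
        raise InvalidSequenceError(f"unknown task dimension(s): {bad}")
    task_code = task_code.astype(np.int64)
    flips = _FLIP_TABLE[out["mapping"].to_numpy(dtype=np.int64) - 1]  # (n, 4)

    keys = feats ^ flips  # key dictated by every dimension's activated rule
    correct_key = np.take_along_axis(keys, task_code[:, None], axis=1)[:, 0]
    # the relevant dimension's own rule equals the correct key, so it never
    # contributes to the competitor count
    n_comp = (keys != correct_key[:, None]).sum(axis=1).astype(np.int8)

    part = out["participant"].to_numpy()
    block = out["block"].to_numpy()
    trial = out["trial"].to_numpy()

    def lagged(k: int) -> np.ndarray:
        """True where the row k back is the k-th within-block predecessor."""
        ok = np.zeros(n, dtype=bool)
        if n > k:
            ok[k:] = (
                (part[k:] == part[:-k])
                & (block[k:] == block[:-k])
                & (trial[k:] == trial[:-k] + k)
            )
        return ok

    has_prev = lagged(1)
    has_prev2 = lagged(2)

    def shifted(arr: np.ndarray, k: int, fill) -> np.ndarray:
        res = np.empty(n, dtype=arr.dtype if arr.dtype != np.int8 else np.int64)
        res[:] = fill
        if n > k:
            res[k:] = arr[:-k]
        return res

    task_prev = shifted(task_code, 1, -1)
    task_prev2 = shifted(task_code, 2, -1)
    if np.any(has_prev & (task_code == task_prev)):
        raise InvalidSequenceError("task repeats on consecutive within-block trials")

    bi = np.where(task_code == task_prev2, BI_ABA, BI_CBA)
    bi_label = np.where(has_prev & has_prev2, bi, BI_UNCLASSIFIED)

    correct_key_prev = shifted(correct_key.astype(np.int64), 1, -1)
    alternation = has_prev & (correct_key != correct_key_prev)

    feats_prev = np.full_like(feats, -1)
    keys_prev = np.full_like(keys, -1)
    if n > 1:
        feats_prev[1:] = feats[:-1]
        keys_prev[1:] = keys[:-1]

    feat_on_task = feats[np.arange(n), task_code]
    feat_prev_on_task = feats_prev[np.arange(n), task_code]
    rule_repeat = has_prev & (feat_on_task == feat_prev_on_task)

    crs_label = np.full(n, CRS_INELIGIBLE, dtype=object)
    crs_label[alternation & rule_repeat] = CRS_PLUS
    crs_label[alternation & ~rule_repeat] = CRS_MINUS

    dims = np.arange(4)[None, :]
    irrelevant_both = (dims != task_code[:, None]) & (dims != task_prev[:, None])
    repeats = feats == feats_prev
    competed_prev = keys_prev != correct_key_prev[:, None]
    competes_now = keys != correct_key[:, None]
    primed = repeats & competed_prev & irrelevant_both
    crp = has_prev & primed.any(axis=1)
    crc = has_prev & (primed & competes_now).any(axis=1)

    full_rep = has_prev & repeats.all(axis=1)

    n_comp_prev = shifted(n_comp.astype(np.int64), 1, -1)

    out["correct_key"] = correct_key.astype(np.int8)
    out["n_competitors"] = n_comp
    out["n_competitors_prev"] = np.where(has_prev, n_comp_prev, -1).astype(np.int8)
    out["bi_label"] = bi_label
    out["response_alternation"] = alternation
    out["crs_label"] = crs_label
    out["crp_flag"] = crp
    out["crc_flag"] = crc
    out["excl_first_four"] = trial <= FIRST_TRIALS_REMOVED
    out["excl_full_repetition"] = full_rep
    return out


def apply_trial_exclusions(df: pd.DataFrame) -> pd.DataFrame:
    """Full trial-level classification of an observed/simulated trial table.

    Adds behavioural exclusion flags on top of :func:`classify_structure`:
    the two within-block trials following an error (``excl_post_error``),
    RT outside the 100..3000 ms window (``excl_rt_bounds``; RT analyses
    only), and the combined ``excluded`` flag (first-four, post-error or
    full stimulus repetition) that removes a trial from every analysis.
    ``crs_valid`` marks trials that survive into the CRS cells.  The
    operation is idempotent.
    """
    out = classify_structure(df)
    n = len(out)

    part = out["participant"].to_numpy()
    block = out["block"].to_numpy()
    trial = out["trial"].to_numpy()
    error = ~out["correct"].to_numpy(dtype=bool)

    post_error = np.zeros(n, dtype=bool)
    for k in range(1, POST_ERROR_LAGS + 1):
        if n > k:
            lagged = (
                (part[k:] == part[:-k])
                & (block[k:] == block[:-k])
                & (trial[k:] == trial[:-k] + k)
            )
            post_error[k:] |= lagged & error[:-k]

    rt = out["rt_ms"].to_numpy(dtype=float)
    out["excl_post_error"] = post_error
    out["excl_rt_bounds"] = (rt < RT_MIN_MS) | (rt > RT_MAX_MS)
    out["excluded"] = (
        out["excl_first_four"] | out["excl_post_error"] | out["excl_full_repetition"]
    )
    lo, hi = CRS_PREV_INTERFERENCE_RANGE
    out["crs_valid"] = (
        (out["crs_label"] != CRS_INELIGIBLE)
        & ~out["excluded"]
        & ~out["crp_flag"]
        & ~out["crc_flag"]
        & out["n_competitors_prev"].between(lo, hi)
    )
    return out
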