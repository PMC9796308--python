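"""Per-participant cognitive indices, questionnaire composites and
participant-level exclusion.

Three indices are computed from the classified trial table, each in RT
(correct, in-bounds, non-excluded trials) and PE (error proportion among
non-excluded trials):

* **linear congruency**: cell means per number of competitor S-R sets
  (0..3) combined with the linear contrast weights (-3, -1, 1, 3);
* **backward inhibition**: mean(ABA) - mean(CBA);
* **competitor rule suppression**: mean(CRS+) - mean(CRS-) over valid CRS
  trials.  The two cells are equated for the degree of interference: valid
  trials are restricted to the previous-trial competitor counts attainable
  in both conditions (1..2), and means are computed within strata of the
  current trial's competitor count, averaged with equal weights over strata
  populated in both conditions.

Because the random task sequence can over-represent some tasks in some
conditions and spatial tasks are faster than object tasks, every cell mean
is first computed per task and then averaged across tasks with equal
weights.

Participant-level exclusion follows the study's order: incomplete data and
the practice gate, the 40% error cap (computed on all trials, before any
robust statistics), a 2.5-MAD rule on overall RT and overall PE within each
experimental group, minimum-trial rules (>= 20 trials per condition and
>= 5 per task per condition for every computed index), and an optional
offset-delay filter on recorded timing metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import BI_ABA, BI_CBA, CRS_MINUS, CRS_PLUS

LINEAR_CONTRAST_WEIGHTS = (-3.0, -1.0, 1.0, 3.0)
MAD_CONSISTENCY = 1.4826  # normal-consistency constant for the MAD

INDEX_COLUMNS = ("lin_cong_rt", "lin_cong_pe", "bi_rt", "bi_pe", "crs_rt", "crs_pe")


class DegenerateInputError(ValueError):
    """Raised when an analysis input is degenerate (e.g. empty group)."""


# ---------------------------------------------------------------------------
# elementary index arithmetic
# ---------------------------------------------------------------------------

def linear_congruency_index(means_by_level) -> float:
    """Linear-contrast congruency index over competitor levels 0..3.

    ``sum(w_i * m_i)`` with weights (-3, -1, 1, 3); returns NaN when any
    level mean is missing.
    """
    m = np.asarray(means_by_level, dtype=float)
    if m.shape != (4,):
        raise ValueError("expected exactly four level means (0..3 competitors)")
    if np.isnan(m).any():
        return float("nan")
    return float(np.dot(LINEAR_CONTRAST_WEIGHTS, m))


def bi_index(mean_aba: float, mean_cba: float) -> float:
    """Backward-inhibition cost: ABA minus CBA."""
    return float(mean_aba - mean_cba)


def crs_index(mean_crs_plus: float, mean_crs_minus: float) -> float:
    """Competitor-rule-suppression cost: CRS+ minus CRS-."""
    return float(mean_crs_plus - mean_crs_minus)


def mad_exclusion(values, k: float = 2.5) -> np.ndarray:
    """Robust outlier mask: keep x with |x - median| <= k * scaled MAD.

    The MAD is scaled by the 1.4826 normal-consistency constant.  With a
    zero MAD only exact-median values are retained and a warning is
    emitted.  Returns a boolean inclusion mask.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * MAD_CONSISTENCY
    if mad == 0.0:
        warnings.warn("MAD is zero; only exact-median values are retained")
        return x == med
    return np.abs(x - med) <= k * mad


# ---------------------------------------------------------------------------
# cell means
# ---------------------------------------------------------------------------

def _rt_mask(df: pd.DataFrame) -> pd.Series:
    return df["correct"] & ~df["excluded"] & ~df["excl_rt_bounds"]


def _pe_mask(df: pd.DataFrame) -> pd.Series:
    return ~df["excluded"]


@dataclass
class ConditionCellMeans:
    """Cell means for one conditioning variable.

    ``per_task`` holds one row per (participant, task, condition) with the
    cell mean and trial count; ``by_condition`` averages across tasks with
    equal weights, one row per (participant, condition).
    """

    measure: str
    per_task: pd.DataFrame
    by_condition: pd.DataFrame


def per_task_condition_means(
    df: pd.DataFrame, conditioning: str, measure: str = "rt"
) -> ConditionCellMeans:
    """Per-task-then-task-averaged cell means for one index family.

    ``conditioning`` is one of ``competitors`` (levels 0..3), ``bi``
    (ABA/CBA) or ``crs`` (CRS+/CRS-, stratification *not* applied here --
    the stratified path lives in :func:`compute_participant_indices`).
    ``measure`` is ``rt`` (mean RT of correct in-bounds trials) or ``pe``
    (error proportion among included trials).
    """
    if measure not in ("rt", "pe"):
        raise ValueError("measure must be 'rt' or 'pe'")
    cond_col, sub = _condition_subset(df, conditioning)
    mask = _rt_mask(sub) if measure == "rt" else _pe_mask(sub)
    sub = sub[mask]
    value = sub["rt_ms"] if measure == "rt" else (~sub["correct"]).astype(float)
    work = pd.DataFrame(
        {
            "participant": sub["participant"].to_numpy(),
            "task": sub["task"].to_numpy(),
            "condition": sub[cond_col].to_numpy(),
            "value": value.to_numpy(dtype=float),
        }
    )
    per_task = (
        work.groupby(["participant", "task", "condition"], observed=True)["value"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    by_condition = (
        per_task.groupby(["participant", "condition"], observed=True)
        .agg(mean=("mean", "mean"), n=("n", "sum"))
        .reset_index()
    )
    return ConditionCellMeans(measure, per_task, by_condition)


def _condition_subset(df: pd.DataFrame, conditioning: str):
    if conditioning == "competitors":
        return "n_competitors", df
    if conditioning == "bi":
        return "bi_label", df[df["bi_label"].isin([BI_ABA, BI_CBA])]
    if conditioning == "crs":
        return "crs_label", df[df["crs_valid"]]
    raise ValueError("conditioning must be 'competitors', 'bi' or 'crs'")


def _crs_stratified(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Equated CRS cell means per participant.

    Returns one row per participant with columns ``plus``, ``minus``,
    ``n_plus``, ``n_minus`` (trial counts inside retained strata) and
    ``min_taskcond_n``.  Valid CRS trials already share the common range of
    previous-trial interference; the current trial's interference is
    equated here by computing cell means within strata of ``n_competitors``
    and averaging with equal weights over strata populated in both
    conditions.
    """
    sub = df[df["crs_valid"]]
    mask = _rt_mask(sub) if measure == "rt" else _pe_mask(sub)
    sub = sub[mask]
    if sub.empty:
        return pd.DataFrame(
            columns=["plus", "minus", "n_plus", "n_minus", "min_taskcond_n"]
        )
    value = sub["rt_ms"] if measure == "rt" else (~sub["correct"]).astype(float)
    work = pd.DataFrame(
        {
            "participant": sub["participant"].to_numpy(),
            "stratum_n": sub["n_competitors"].to_numpy(),
            "label": sub["crs_label"].to_numpy(),
            "task": sub["task"].to_numpy(),
            "value": value.to_numpy(dtype=float),
        }
    )
    keys = ["participant", "stratum_n", "label"]
    per_task = (
        work.groupby(keys + ["task"], observed=True)["value"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    per_stratum = (
        per_task.groupby(keys, observed=True)
        .agg(mean=("mean", "mean"), n=("n", "sum"))
        .reset_index()
    )
    wide = per_stratum.pivot_table(
        index=["participant", "stratum_n"],
        columns="label",
        values=["mean", "n"],
        aggfunc="first",
    )
    for col in [("mean", CRS_PLUS), ("mean", CRS_MINUS), ("n", CRS_PLUS), ("n", CRS_MINUS)]:
        if col not in wide.columns:
            wide[col] = np.nan
    matched = wide[
        wide[("mean", CRS_PLUS)].notna() & wide[("mean", CRS_MINUS)].notna()
    ]
    agg = matched.groupby("participant").agg(
        plus=(("mean", CRS_PLUS), "mean"),
        minus=(("mean", CRS_MINUS), "mean"),
        n_plus=(("n", CRS_PLUS), "sum"),
        n_minus=(("n", CRS_MINUS), "sum"),
    )
    # task-level counts (pooled over retained strata) for the min-trials rule
    retained = matched.index.to_frame(index=False)
    tagged = per_task.merge(retained, on=["participant", "stratum_n"])
    taskcond = tagged.groupby(["participant", "label", "task"], observed=True)["n"].sum()
    agg["min_taskcond_n"] = taskcond.groupby("participant").min()
    return agg


def crs_condition_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Valid CRS trial counts per participant per condition.

    Counts non-excluded valid CRS trials inside strata populated in both
    conditions -- the per-participant trial budget of the CRS index.
    """
    sub = df[df["crs_valid"] & _pe_mask(df)]
    counts = (
        sub.groupby(
            ["participant", "n_competitors", "crs_label"], observed=True
        )
        .size()
        .unstack("crs_label", fill_value=0)
    )
    for col in (CRS_PLUS, CRS_MINUS):
        if col not in counts.columns:
            counts[col] = 0
    matched = counts[(counts[CRS_PLUS] > 0) & (counts[CRS_MINUS] > 0)]
    out = matched.groupby("participant")[[CRS_PLUS, CRS_MINUS]].sum()
    return out.rename(columns={CRS_PLUS: "n_plus", CRS_MINUS: "n_minus"})


# ---------------------------------------------------------------------------
# per-participant indices
# ---------------------------------------------------------------------------

def compute_participant_indices(df: pd.DataFrame) -> pd.DataFrame:
    """All six cognitive indices plus overall performance, per participant.

    Expects a fully classified trial table (see
    :func:`switchbf.classify.apply_trial_exclusions`).  Returns one row per
    participant with the index values, overall RT/PE, and the cell-count
    columns consumed by the minimum-trial exclusion rules.  Indices whose
    cells are empty come out as NaN.
    """
    meta = df.groupby("participant").agg(group=("group", "first"))
    overall_rt = df[_rt_mask(df)].groupby("participant")["rt_ms"].mean()
    overall_pe = (
        (~df["correct"]).astype(float).groupby(df["participant"]).mean()
    )  # on all trials, before any removal
    n_trials = df.groupby("participant").size()

    out = meta
    out["overall_rt"] = overall_rt
    out["overall_pe"] = overall_pe
    out["n_trials"] = n_trials

    for measure in ("rt", "pe"):
        cong = per_task_condition_means(df, "competitors", measure)
        wide = cong.by_condition.pivot_table(
            index="participant", columns="condition", values="mean", aggfunc="first"
        ).reindex(columns=[0, 1, 2, 3])
        vals = wide.to_numpy(dtype=float)
        idx = np.where(
            np.isnan(vals).any(axis=1),
            np.nan,
            vals @ np.asarray(LINEAR_CONTRAST_WEIGHTS),
        )
        out[f"lin_cong_{measure}"] = pd.Series(idx, index=wide.index)
        counts = cong.by_condition.pivot_table(
            index="participant", columns="condition", values="n", aggfunc="first"
        ).reindex(columns=[0, 1, 2, 3])
        out[f"lin_cong_{measure}_min_cond_n"] = counts.min(axis=1).fillna(0)
        tc = cong.per_task.groupby(["participant"])["n"].min()
        n_cells = cong.per_task.groupby(["participant"]).size()
        tc = tc.where(n_cells >= 16, 0)  # a missing task x level cell counts as 0
        out[f"lin_cong_{measure}_min_taskcond_n"] = tc

        bi = per_task_condition_means(df, "bi", measure)
        bwide = bi.by_condition.pivot_table(
            index="participant", columns="condition", values="mean", aggfunc="first"
        ).reindex(columns=[BI_ABA, BI_CBA])
        out[f"bi_{measure}"] = bwide[BI_ABA] - bwide[BI_CBA]
        bcounts = bi.by_condition.pivot_table(
            index="participant", columns="condition", values="n", aggfunc="first"
        ).reindex(columns=[BI_ABA, BI_CBA])
        out[f"bi_{measure}_min_cond_n"] = bcounts.min(axis=1).fillna(0)
        btc = bi.per_task.groupby(["participant"])["n"].min()
        b_cells = bi.per_task.groupby(["participant"]).size()
        out[f"bi_{measure}_min_taskcond_n"] = btc.where(b_cells >= 8, 0)

        crs = _crs_stratified(df, measure)
        out[f"crs_{measure}"] = crs["plus"] - crs["minus"]
        out[f"crs_{measure}_min_cond_n"] = crs[["n_plus", "n_minus"]].min(axis=1)
        out[f"crs_{measure}_min_taskcond_n"] = crs["min_taskcond_n"]

    count_cols = [c for c in out.columns if c.endswith("_n") and c != "n_trials"]
    out[count_cols] = out[count_cols].fillna(0).astype(int)
    return out.reset_index()


# ---------------------------------------------------------------------------
# questionnaires
# ---------------------------------------------------------------------------

def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha of a set of item columns."""
    k = items.shape[1]
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0.0:  # constant total score: reliability undefined
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_questionnaires(participants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Questionnaire composites and scale reliabilities.

    * ``fwi``: mean of the five free-will-inventory subscale items (1..7);
    * ``fatigue``: mean of the four fatigue items after reverse-coding the
      ``alert`` and ``energetic`` items as 8 - rating, so that high scores
      mean more fatigue;
    * ``loc``: number of internal locus-of-control choices (0..23).

    Returns the participant table with composite columns added, and a dict
    of Cronbach's alpha per scale.
    """
    fwi_cols = [f"fwi_{i}" for i in range(1, 6)]
    fat_cols = [f"fatigue_{name}" for name in ("tired", "bored", "alert", "energetic")]
    loc_cols = [f"loc_{i}" for i in range(1, 24)]
    for col in fwi_cols + fat_cols:
        vals = participants[col]
        if not vals.between(1, 7).all():
            raise ValueError(f"{col}: ratings must be within 1..7")
    for col in loc_cols:
        if not participants[col].isin([0, 1]).all():
            raise ValueError(f"{col}: choices must be 0 (external) or 1 (internal)")

    out = participants.copy()
    fat = out[fat_cols].copy()
    fat[["fatigue_alert", "fatigue_energetic"]] = (
        8 - fat[["fatigue_alert", "fatigue_energetic"]]
    )
    out["fwi"] = out[fwi_cols].mean(axis=1)
    out["fatigue"] = fat.mean(axis=1)
    out["loc"] = out[loc_cols].sum(axis=1)
    alphas = {
        "fwi": cronbach_alpha(out[fwi_cols]),
        "fatigue": cronbach_alpha(fat),
        "loc": cronbach_alpha(out[loc_cols]),
    }
    return out, alphas


# ---------------------------------------------------------------------------
# participant-level exclusion
# ---------------------------------------------------------------------------

@dataclass
class ExclusionConfig:
    error_cap: float = 0.40
    mad_k: float = 2.5
    min_per_condition: int = 20
    min_per_task_condition: int = 5
    expected_n_trials: int = 448
    apply_practice_gate: bool = True
    offset_delay_filter: bool = False
    offset_delay_comparator: str = "above"  # 'above' or 'below'
    offset_delay_mean_ms: float = 30.0
    offset_delay_sd_ms: float = 36.0


@dataclass
class ExclusionReport:
    """Participant-level exclusion outcome."""

    reasons: dict = field(default_factory=dict)  # participant -> sorted reasons
    group_counts: dict = field(default_factory=dict)  # group -> reason -> count
    n_before: dict = field(default_factory=dict)
    n_after: dict = field(default_factory=dict)
    offset_delay_comparator: str | None = None

    def to_dict(self) -> dict:
        return {
            "reasons": {str(k): v for k, v in self.reasons.items()},
            "group_counts": self.group_counts,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "offset_delay_comparator": self.offset_delay_comparator,
        }


def apply_participant_exclusions(
    indices: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    config: ExclusionConfig | None = None,
) -> tuple[ExclusionReport, pd.DataFrame]:
    """Apply the participant-level exclusion cascade.

    ``indices`` is the output of :func:`compute_participant_indices`;
    ``participants`` optionally supplies the practice gate, offset-delay
    metadata and questionnaire completeness.  Exclusion reasons follow the
    study's order: incomplete data / practice gate, error cap (before any
    MAD), MAD on overall RT and PE within group, minimum-trial rules, then
    the optional offset-delay filter.  Returns the report and the filtered
    index table.
    """
    cfg = config or ExclusionConfig()
    df = indices.set_index("participant")
    reasons: dict[object, set[str]] = {p: set() for p in df.index}

    meta = None
    if participants is not None:
        meta = participants.set_index("participant").reindex(df.index)
        if cfg.apply_practice_gate and "practice_passed" in meta.columns:
            for p in df.index[~meta["practice_passed"].fillna(False).astype(bool)]:
                reasons[p].add("practiceGate")

    incomplete = df["n_trials"] < cfg.expected_n_trials
    if meta is not None:
        incomplete |= meta.isna().any(axis=1)
    for p in df.index[incomplete]:
        reasons[p].add("incompleteData")

    over_cap = df["overall_pe"] > cfg.error_cap
    for p in df.index[over_cap]:
        reasons[p].add("errorCapOver40")

    # MAD within group, among participants surviving the earlier steps
    eligible = df.index[[not reasons[p] for p in df.index]]
    for group, sub in df.loc[eligible].groupby("group"):
        if len(sub) < 3:
            continue
        for col, reason in (("overall_rt", "madRt"), ("overall_pe", "madPe")):
            keep = mad_exclusion(sub[col].to_numpy(), k=cfg.mad_k)
            for p in sub.index[~keep]:
                reasons[p].add(reason)

    cond_cols = [c for c in df.columns if c.endswith("_min_cond_n")]
    taskcond_cols = [c for c in df.columns if c.endswith("_min_taskcond_n")]
    too_few = (df[cond_cols] < cfg.min_per_condition).any(axis=1) | (
        df[taskcond_cols] < cfg.min_per_task_condition
    ).any(axis=1)
    too_few |= df[list(INDEX_COLUMNS)].isna().any(axis=1)
    for p in df.index[too_few]:
        reasons[p].add("minTrials")

    report = ExclusionReport()
    if cfg.offset_delay_filter and meta is not None:
        report.offset_delay_comparator = cfg.offset_delay_comparator
        mean_d = meta["offset_delay_mean_ms"]
        sd_d = meta["offset_delay_sd_ms"]
        if cfg.offset_delay_comparator == "above":
            bad = (mean_d > cfg.offset_delay_mean_ms) | (sd_d > cfg.offset_delay_sd_ms)
        elif cfg.offset_delay_comparator == "below":
            bad = (mean_d < cfg.offset_delay_mean_ms) | (sd_d < cfg.offset_delay_sd_ms)
        else:
            raise ValueError("offset_delay_comparator must be 'above' or 'below'")
        for p in df.index[bad.fillna(False)]:
            reasons[p].add("offsetDelay")

    excluded = {p for p, r in reasons.items() if r}
    report.reasons = {p: sorted(r) for p, r in reasons.items() if r}
    for group, sub in df.groupby("group"):
        report.n_before[group] = int(len(sub))
        report.n_after[group] = int(sum(p not in excluded for p in sub.index))
        counts: dict[str, int] = {}
        for p in sub.index:
            for r in reasons[p]:
                counts[r] = counts.get(r, 0) + 1
        report.group_counts[group] = counts

    kept = df.loc[[p for p in df.index if p not in excluded]].reset_index()
    if kept.empty or kept["group"].nunique() < df["group"].nunique():
        raise DegenerateInputError("a group is empty after participant exclusion")
    return report, kept
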