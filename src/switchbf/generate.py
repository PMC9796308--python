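"""Generative model for synthetic task-switching sessions and questionnaires.

The generator emulates the experiment's design: two groups (pro/anti free
will) of participants, each completing 7 blocks x 64 trials of four-task
cued switching with a 100%-switch task sequence, uniformly drawn stimuli
and one of 8 counterbalanced response mappings, followed by a 5-item free
will inventory (FWI) subscale, 4 fatigue ratings and the 23-item locus of
control scale.

Reaction times follow an additive linear model with ex-Gaussian noise:

    rt = base
         - spatial_advantage * 1[spatial task]
         + congruency_slope * n_competitors
         + bi_cost * 1[ABA]
         + crs_cost * 1[CRS+]
         + participant intercept
         + Normal(0, sigma) + Exponential(tau)

Errors are Bernoulli with probability base_error_rate +
error_slope_per_competitor * n_competitors.  Effect-parameter defaults are
set to the magnitudes the study reported for its cognitive indices
(congruency index ~338 ms and ~.17 PE, backward inhibition ~26 ms,
competitor-rule suppression ~28 ms), so that data simulated with the
defaults look like the study's task data; group differences on the
cognitive indices default to zero (the study's observed outcome), while
the free-will manipulation check defaults to its observed d = 0.70.

Every stochastic operation takes an explicit seed or Generator; there is no
hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import classify as _classify
from .design import (
    DIMENSIONS,
    N_MAPPINGS,
    SPATIAL_DIMENSIONS,
    InvalidDesignError,
    ResponseMapping,
)

N_BLOCKS = 7
TRIALS_PER_BLOCK = 64
N_TASKS = 4

GROUPS = ("pro", "anti")

#: Cohen-d -> parameter-shift conversion scales: Monte-Carlo calibrated
#: standard deviations of each per-participant RT index under the default
#: noise parameters (see docs/methods.md).
DEFAULT_INDEX_SD_RT: dict[str, float] = {
    "lin_cong_rt": 85.0,
    "bi_rt": 14.5,
    "crs_rt": 42.0,
}

# latent/item parameters of the questionnaire generator, calibrated so the
# composite scores match the study's reported means, SDs and reliabilities
FWI_PRO_MEAN = 4.65
FWI_COMPOSITE_SD = 1.20
FWI_LATENT_SD = 1.10
FWI_ITEM_NOISE_SD = 0.90
FATIGUE_MEAN = 3.0
FATIGUE_LATENT_SD = 0.90
FATIGUE_ITEM_NOISE_SD = 0.85
LOC_LATENT_MEAN = -0.334  # logit(9.6 / 23)
LOC_LATENT_SD = 0.60

FWI_N_ITEMS = 5
FATIGUE_ITEMS = ("tired", "bored", "alert", "energetic")
LOC_N_ITEMS = 23


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth parameters of the synthetic experiment.

    Units are milliseconds for RT parameters and probabilities for error
    parameters.  ``group_effect_sizes`` maps an RT index name
    (``lin_cong_rt``, ``bi_rt``, ``crs_rt``) to a standardized mean
    difference (Cohen's d) applied to the *anti* group by shifting the
    corresponding effect parameter; ``index_sd_rt`` holds the per-index
    scale constants used for that conversion.  ``fwi_group_d`` shifts the
    anti group's latent free-will belief.
    """

    base_rt: float = 800.0
    spatial_task_advantage: float = 50.0
    congruency_slope: float = 34.0
    bi_cost: float = 26.0
    crs_cost: float = 28.0
    participant_sd_intercept: float = 100.0
    sigma: float = 50.0
    tau: float = 100.0
    base_error_rate: float = 0.08
    error_slope_per_competitor: float = 0.017
    group_effect_sizes: Mapping[str, float] = field(default_factory=dict)
    index_sd_rt: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_SD_RT)
    )
    fwi_group_d: float = 0.70
    practice_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be a probability")
        if not 0.0 <= self.practice_fail_rate <= 1.0:
            raise ValueError("practice_fail_rate must be a probability")
        if self.sigma < 0 or self.tau < 0 or self.participant_sd_intercept < 0:
            raise ValueError("noise scales must be non-negative")
        unknown = set(self.group_effect_sizes) - set(DEFAULT_INDEX_SD_RT)
        if unknown:
            raise ValueError(f"unknown group-effect index names: {sorted(unknown)}")

    def for_group(self, group: str) -> "GenerativeParams":
        """Parameters effective for one experimental group.

        The anti group's effect parameters are shifted by
        d * index SD (divided by 10 for the congruency slope, whose index
        is the linear contrast with weight-sum 10).
        """
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if group == "pro" or not self.group_effect_sizes:
            return self
        d = self.group_effect_sizes
        sd = self.index_sd_rt
        return replace(
            self,
            congruency_slope=self.congruency_slope
            + d.get("lin_cong_rt", 0.0) * sd["lin_cong_rt"] / 10.0,
            bi_cost=self.bi_cost + d.get("bi_rt", 0.0) * sd["bi_rt"],
            crs_cost=self.crs_cost + d.get("crs_rt", 0.0) * sd["crs_rt"],
        )


def generate_task_sequence(
    n_blocks: int = N_BLOCKS,
    trials_per_block: int = TRIALS_PER_BLOCK,
    n_tasks: int = N_TASKS,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random task sequence under the 100%-switch constraint.

    Returns task codes 0..n_tasks-1 of length n_blocks * trials_per_block.
    Each successor is drawn uniformly among the n_tasks - 1 other tasks, so
    no two consecutive trials share a task anywhere in the sequence.
    """
    if n_tasks < 2:
        raise InvalidDesignError("need at least 2 tasks for a 100%-switch design")
    if n_blocks < 1 or trials_per_block < 1:
        raise InvalidDesignError("n_blocks and trials_per_block must be >= 1")
    rng = np.random.default_rng(rng)
    n = n_blocks * trials_per_block
    steps = rng.integers(1, n_tasks, size=n)
    steps[0] = rng.integers(0, n_tasks)
    return np.cumsum(steps) % n_tasks


def simulate_trial(
    n_competitors: int,
    bi_is_aba: bool,
    crs_is_plus: bool,
    task: str,
    params: GenerativeParams,
    participant_intercept: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, bool]:
    """Draw one trial's (rt, correct) given its structural features."""
    if not 0 <= n_competitors <= 3:
        raise ValueError("n_competitors must be in 0..3")
    rng = np.random.default_rng(rng)
    mu = (
        params.base_rt
        - params.spatial_task_advantage * (task in SPATIAL_DIMENSIONS)
        + params.congruency_slope * n_competitors
        + params.bi_cost * bi_is_aba
        + params.crs_cost * crs_is_plus
        + participant_intercept
    )
    if mu <= 0:
        raise ValueError("parameters imply a non-positive mean RT")
    rt = mu + (rng.standard_normal() * params.sigma if params.sigma else 0.0)
    rt += rng.exponential(params.tau) if params.tau else 0.0
    p_err = min(
        1.0,
        max(0.0, params.base_error_rate + params.error_slope_per_competitor * n_competitors),
    )
    correct = rng.random() >= p_err
    return float(rt), bool(correct)


def _session_structure(
    participant: object,
    group: str,
    mapping: ResponseMapping,
    rng: np.random.Generator,
) -> pd.DataFrame:
    tasks = generate_task_sequence(rng=rng)
    n = tasks.size
    feats = rng.integers(0, 2, size=(n, 4), dtype=np.int8)
    df = pd.DataFrame(
        {
            "participant": participant,
            "group": group,
            "mapping": mapping.mapping_id,
            "block": np.repeat(np.arange(1, N_BLOCKS + 1), TRIALS_PER_BLOCK),
            "trial": np.tile(np.arange(1, TRIALS_PER_BLOCK + 1), N_BLOCKS),
            "task": np.asarray(DIMENSIONS, dtype=object)[tasks],
        }
    )
    for j, dim in enumerate(DIMENSIONS):
        df[dim] = feats[:, j]
    return _classify.classify_structure(df)


def simulate_participant(
    participant: object,
    group: str,
    mapping: ResponseMapping,
    params: GenerativeParams,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One full synthetic session (7 x 64 trials) as a long-format table.

    The trial's structural features (competitor count, backward-inhibition
    label, CRS label) are computed by the classification pipeline *before*
    RTs and errors are drawn, so the generative effect parameters act on
    exactly the features the analysis will condition on.
    """
    rng = np.random.default_rng(rng)
    eff = params.for_group(group)
    df = _session_structure(participant, group, mapping, rng)

    is_spatial = df["task"].isin(SPATIAL_DIMENSIONS).to_numpy()
    n_comp = df["n_competitors"].to_numpy()
    aba = (df["bi_label"] == _classify.BI_ABA).to_numpy()
    crs_plus = (df["crs_label"] == _classify.CRS_PLUS).to_numpy()

    intercept = rng.normal(0.0, eff.participant_sd_intercept)
    mu = (
        eff.base_rt
        - eff.spatial_task_advantage * is_spatial
        + eff.congruency_slope * n_comp
        + eff.bi_cost * aba
        + eff.crs_cost * crs_plus
        + intercept
    )
    if np.any(mu <= 0):
        raise ValueError("parameters imply a non-positive mean RT")
    n = len(df)
    rt = mu + rng.standard_normal(n) * eff.sigma + rng.exponential(eff.tau, size=n)

    p_err = np.clip(
        eff.base_error_rate + eff.error_slope_per_competitor * n_comp, 0.0, 1.0
    )
    error = rng.random(n) < p_err
    df["response_key"] = (df["correct_key"].to_numpy() ^ error.astype(np.int8)).astype(
        np.int8
    )
    df["correct"] = ~error
    df["rt_ms"] = rt
    return df


def _questionnaire_items(
    group: str, params: GenerativeParams, rng: np.random.Generator
) -> dict[str, float]:
    def likert(latent: float, noise_sd: float, size: int) -> np.ndarray:
        raw = latent + rng.normal(0.0, noise_sd, size=size)
        return np.clip(np.rint(raw), 1, 7).astype(int)

    fwi_mean = FWI_PRO_MEAN
    if group == "anti":
        fwi_mean -= params.fwi_group_d * FWI_COMPOSITE_SD
    fwi = likert(rng.normal(fwi_mean, FWI_LATENT_SD), FWI_ITEM_NOISE_SD, FWI_N_ITEMS)

    fatigue_latent = rng.normal(FATIGUE_MEAN, FATIGUE_LATENT_SD)
    fat_raw = fatigue_latent + rng.normal(0.0, FATIGUE_ITEM_NOISE_SD, size=4)
    # alert / energetic are worded against fatigue: generate them reversed
    fat_raw[2:] = 8.0 - fat_raw[2:]
    fatigue = np.clip(np.rint(fat_raw), 1, 7).astype(int)

    theta = rng.normal(LOC_LATENT_MEAN, LOC_LATENT_SD)
    p_internal = 1.0 / (1.0 + np.exp(-theta))
    loc = (rng.random(LOC_N_ITEMS) < p_internal).astype(int)

    items: dict[str, float] = {}
    for i, v in enumerate(fwi, start=1):
        items[f"fwi_{i}"] = v
    for name, v in zip(FATIGUE_ITEMS, fatigue):
        items[f"fatigue_{name}"] = v
    for i, v in enumerate(loc, start=1):
        items[f"loc_{i}"] = v
    return items


def simulate_group(
    n_per_group: int,
    params: GenerativeParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate both experimental groups.

    Returns ``(trials, participants)``: a long-format trial table and a
    per-participant table with mapping condition, practice-gate outcome,
    offset-delay metadata and raw questionnaire items.  The 8 response
    mappings are counterbalanced within each group.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    params = params or GenerativeParams()
    rng = np.random.default_rng(rng)

    trial_frames = []
    part_rows = []
    pid = 0
    for group in GROUPS:
        for i in range(n_per_group):
            pid += 1
            mapping = ResponseMapping.standard(i % N_MAPPINGS + 1)
            trial_frames.append(
                simulate_participant(pid, group, mapping, params, rng)
            )
            row: dict[str, object] = {
                "participant": pid,
                "group": group,
                "mapping": mapping.mapping_id,
                "practice_passed": bool(rng.random() >= params.practice_fail_rate),
                "offset_delay_mean_ms": float(rng.normal(15.0, 5.0)),
                "offset_delay_sd_ms": float(rng.normal(18.0, 6.0)),
            }
            row.update(_questionnaire_items(group, params, rng))
            part_rows.append(row)

    trials = pd.concat(trial_frames, ignore_index=True)
    participants = pd.DataFrame(part_rows)
    return trials, participants
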