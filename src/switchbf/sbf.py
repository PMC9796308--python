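"""Monte-Carlo operating characteristics of a Sequential Bayes Factor design.

A Sequential Bayes Factor (SBF) sampling plan accrues participants from a
minimum group size, recomputes a default-prior Bayes factor after every
look, and stops as soon as the factor crosses an upper (evidence for H1) or
lower (evidence for H0) boundary, or when a maximum group size is reached.
Terminal studies that never cross a boundary are judged by conventional
evidence thresholds (BF10 > 3 / < 1/3) at the maximum n.

The simulator draws the two groups from Normal(d, 1) and Normal(0, 1) --
the standard design-analysis data model -- and classifies each simulated
study into one of five terminal states:

``hitUpper``, ``hitLower``, ``maxNevidenceH1``, ``maxNinconclusive``,
``maxNevidenceH0``.

The default design mirrors the study's sampling plan: n from 60 to 100 per
group, boundaries 10 and 1/10, Cauchy scale 1, one participant per group
per look.  The hypothesis tested is directional (the replication predicted
the direction of the group difference), so the default Bayes factor is
one-sided; set ``sided='two'`` for the symmetric prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.interpolate import CubicSpline

from .bayes import GREATER, TWO_SIDED, jzs_bf_from_t

#: above this many simultaneous BF evaluations the directional Bayes factor
#: is interpolated from a dense log-BF(t) spline per look (the function is
#: smooth and monotone in t, so 1e-7-level interpolation error is easy)
_SPLINE_THRESHOLD = 200
_SPLINE_POINTS = 80

TERMINAL_CATEGORIES = (
    "hitUpper",
    "hitLower",
    "maxNevidenceH1",
    "maxNinconclusive",
    "maxNevidenceH0",
)


@dataclass(frozen=True)
class SBFDesign:
    """A sequential Bayes factor sampling plan."""

    n_min: int = 60
    n_max: int = 100
    upper_boundary: float = 10.0
    lower_boundary: float = 0.1
    step_per_look: int = 1
    cauchy_scale: float = 1.0
    evidence_thresholds: tuple[float, float] = (3.0, 1.0 / 3.0)
    true_effect_d: float = 0.0
    sided: str = "one"

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_boundary < 1.0 < self.upper_boundary:
            raise ValueError("boundaries must satisfy 0 < lower < 1 < upper")
        if not 2 <= self.n_min <= self.n_max:
            raise ValueError("need 2 <= n_min <= n_max")
        if self.step_per_look < 1:
            raise ValueError("step_per_look must be >= 1")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")

    @property
    def looks(self) -> np.ndarray:
        """Per-group sample sizes at which the BF is (re)computed."""
        ns = np.arange(self.n_min, self.n_max + 1, self.step_per_look)
        if ns[-1] != self.n_max:
            ns = np.append(ns, self.n_max)
        return ns

    @property
    def direction(self) -> str:
        return GREATER if self.sided == "one" else TWO_SIDED


@dataclass(frozen=True)
class SBFOutcome:
    """Terminal state of one simulated sequential study."""

    terminal: str
    stop_n: int
    final_bf: float
    trajectory: tuple[tuple[int, float], ...]


@dataclass(frozen=True)
class DesignAnalysisResult:
    """Monte-Carlo operating characteristics of an SBF design."""

    design: SBFDesign
    n_sims: int
    seed: object
    proportions: dict = field(default_factory=dict)
    mean_stop_n: float = float("nan")

    @property
    def evidence_h1_total(self) -> float:
        """Boundary hits plus BF > 3 at maximum n."""
        return self.proportions["hitUpper"] + self.proportions["maxNevidenceH1"]

    @property
    def evidence_h0_total(self) -> float:
        """Boundary hits plus BF < 1/3 at maximum n."""
        return self.proportions["hitLower"] + self.proportions["maxNevidenceH0"]

    def to_dict(self) -> dict:
        return {
            "n_sims": self.n_sims,
            "true_effect_d": self.design.true_effect_d,
            "sided": self.design.sided,
            "proportions": dict(self.proportions),
            "evidence_h1_total": self.evidence_h1_total,
            "evidence_h0_total": self.evidence_h0_total,
            "mean_stop_n": self.mean_stop_n,
        }


def classify_terminal(final_bf: float, design: SBFDesign, at_max_n: bool) -> str:
    """Terminal category of a study given its final Bayes factor."""
    if final_bf <= 0:
        raise ValueError("final_bf must be positive")
    if final_bf > design.upper_boundary:
        return "hitUpper"
    if final_bf < design.lower_boundary:
        return "hitLower"
    if not at_max_n:
        raise ValueError("a study between the boundaries must be at n_max")
    hi, lo = design.evidence_thresholds
    if final_bf > hi:
        return "maxNevidenceH1"
    if final_bf < lo:
        return "maxNevidenceH0"
    return "maxNinconclusive"


def _bf_batch(t: np.ndarray, n: int, design: SBFDesign) -> np.ndarray:
    """Bayes factors for many studies at one look.

    The two-sided factor is elementary and evaluated directly.  The
    directional factor needs the noncentral-t density; for large batches
    log BF10 is interpolated in t from an 80-node cubic spline instead.
    """
    def log_bf(tt: np.ndarray) -> np.ndarray:
        return jzs_bf_from_t(
            tt, n, n, cauchy_scale=design.cauchy_scale,
            direction=design.direction, log=True,
        )

    if design.direction == TWO_SIDED or t.size <= _SPLINE_THRESHOLD:
        return np.exp(log_bf(t))
    grid = np.linspace(t.min() - 0.05, t.max() + 0.05, _SPLINE_POINTS)
    spline = CubicSpline(grid, log_bf(grid))
    return np.exp(spline(t))


def _simulate_batch(
    design: SBFDesign, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised simulation of many sequential studies.

    Returns (terminal category index, stop n, final BF) arrays.  Data are
    drawn once up to n_max per group; looks reuse incremental sufficient
    statistics, and Bayes factors are evaluated only for still-active
    studies at each look.
    """
    looks = design.looks
    n_max = design.n_max
    x = rng.standard_normal((n_sims, n_max)) + design.true_effect_d
    y = rng.standard_normal((n_sims, n_max))

    cx, cy = np.cumsum(x, axis=1), np.cumsum(y, axis=1)
    cx2, cy2 = np.cumsum(x * x, axis=1), np.cumsum(y * y, axis=1)

    stop_n = np.full(n_sims, n_max, dtype=int)
    final_bf = np.full(n_sims, np.nan)
    terminal = np.full(n_sims, -1, dtype=int)
    active = np.ones(n_sims, dtype=bool)

    for n in looks:
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mx, my = cx[idx, n - 1] / n, cy[idx, n - 1] / n
        ssx = cx2[idx, n - 1] - n * mx * mx
        ssy = cy2[idx, n - 1] - n * my * my
        sp2 = (ssx + ssy) / (2 * n - 2)
        t = (mx - my) / np.sqrt(sp2 * 2.0 / n)
        bf = np.atleast_1d(_bf_batch(t, n, design))
        crossed = (bf > design.upper_boundary) | (bf < design.lower_boundary)
        done = crossed | (n == n_max)
        sel = idx[done]
        stop_n[sel] = n
        final_bf[sel] = bf[done]
        terminal[sel] = np.where(
            bf[done] > design.upper_boundary,
            TERMINAL_CATEGORIES.index("hitUpper"),
            np.where(
                bf[done] < design.lower_boundary,
                TERMINAL_CATEGORIES.index("hitLower"),
                np.where(
                    bf[done] > design.evidence_thresholds[0],
                    TERMINAL_CATEGORIES.index("maxNevidenceH1"),
                    np.where(
                        bf[done] < design.evidence_thresholds[1],
                        TERMINAL_CATEGORIES.index("maxNevidenceH0"),
                        TERMINAL_CATEGORIES.index("maxNinconclusive"),
                    ),
                ),
            ),
        )
        active[sel] = False
    return terminal, stop_n, final_bf


def simulate_one_study(
    design: SBFDesign, rng: np.random.Generator | int | None = None
) -> SBFOutcome:
    """Run a single sequential study and record its full BF trajectory."""
    rng = np.random.default_rng(rng)
    x = rng.standard_normal(design.n_max) + design.true_effect_d
    y = rng.standard_normal(design.n_max)
    trajectory: list[tuple[int, float]] = []
    for n in design.looks:
        xs, ys = x[:n], y[:n]
        sp2 = (xs.var(ddof=1) * (n - 1) + ys.var(ddof=1) * (n - 1)) / (2 * n - 2)
        t = (xs.mean() - ys.mean()) / np.sqrt(sp2 * 2.0 / n)
        bf = float(
            jzs_bf_from_t(
                t, n, n, cauchy_scale=design.cauchy_scale, direction=design.direction
            )
        )
        trajectory.append((int(n), bf))
        if bf > design.upper_boundary or bf < design.lower_boundary:
            return SBFOutcome(
                terminal=classify_terminal(bf, design, at_max_n=False),
                stop_n=int(n),
                final_bf=bf,
                trajectory=tuple(trajectory),
            )
    return SBFOutcome(
        terminal=classify_terminal(bf, design, at_max_n=True),
        stop_n=int(design.n_max),
        final_bf=bf,
        trajectory=tuple(trajectory),
    )


def run_design_analysis(
    design: SBFDesign,
    n_sims: int,
    rng: np.random.Generator | int | None = None,
) -> DesignAnalysisResult:
    """Monte-Carlo design analysis: terminal proportions and stopping n."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    seed = rng if not isinstance(rng, np.random.Generator) else None
    rng = np.random.default_rng(rng)
    terminal, stop_n, _ = _simulate_batch(design, n_sims, rng)
    props = {
        cat: float(np.mean(terminal == i)) for i, cat in enumerate(TERMINAL_CATEGORIES)
    }
    return DesignAnalysisResult(
        design=design,
        n_sims=n_sims,
        seed=seed,
        proportions=props,
        mean_stop_n=float(stop_n.mean()),
    )
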