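"""Default-prior (JZS) Bayes factors, evidence categories, effect sizes and
noncentral-t power.

The Bayes factor for a t-test places a Cauchy prior with scale ``r`` on the
standardized effect size under H1 (the Jeffreys-Zellner-Siow default) and a
point mass at zero under H0, so

    BF10 = integral p(t | delta) Cauchy(delta; 0, r) d delta / p(t | 0),

where p(t | delta) is the noncentral-t density with noncentrality
delta * sqrt(N_eff) (N_eff = n for one sample, n1*n2/(n1+n2) for two).  The
two-sided factor is evaluated through the equivalent normal-scale-mixture
(inverse-gamma g) representation with fixed-order Gauss-Legendre quadrature
in log space, which needs only elementary functions and vectorises over
many t values -- the property the sequential-design simulator relies on.
Directional ("one-sided") factors truncate the Cauchy prior to one sign and
integrate the noncentral-t likelihood directly; the half-Cauchy substitution
delta = r * tan(pi u / 2) absorbs the prior density exactly.

Correlation Bayes factors use the exact sampling density of Pearson's r
under a stretched-beta prior on the population correlation (width 1 makes
the prior uniform on (-1, 1)).

Evidence labels follow the conventional categories: anecdotal (BF in
(1/3, 3)), substantial (3..10 or 1/10..1/3), strong (10..30), very strong
(30..100) and decisive (beyond 100 or 1/100), with boundary values assigned
to the weaker category.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, special, stats

TWO_SIDED = "two-sided"
GREATER = "greater"
LESS = "less"
_DIRECTIONS = (TWO_SIDED, GREATER, LESS)

_GAUSS_NODES = 300


class DegenerateInputError(ValueError):
    """Raised when a sample has no variance (or a correlation no spread)."""


@dataclass(frozen=True)
class BayesFactorResult:
    """Outcome of one Bayes-factor comparison."""

    bf10: float
    evidence: str
    direction: str
    effect_d: float | None
    eta_partial: float | None
    n1: int
    n2: int | None = None
    statistic: float | None = None

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@lru_cache(maxsize=4)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    # map from (-1, 1) to (0, 1)
    return 0.5 * (x + 1.0), 0.5 * w


def _two_sided_log_bf(t: np.ndarray, n_eff: float, df: float, r: float) -> np.ndarray:
    u, w = _leggauss(_GAUSS_NODES)
    g = u / (1.0 - u)
    log_jac = -2.0 * np.log1p(-u)
    # inverse-gamma(1/2, 1/2) mixing density of g
    log_prior = -0.5 * np.log(2.0 * np.pi) - 1.5 * np.log(g) - 0.5 / g
    c = 1.0 + n_eff * g * r * r
    t2 = np.atleast_1d(t)[:, None] ** 2
    log_like = -0.5 * np.log(c) - 0.5 * (df + 1.0) * np.log1p(t2 / (c * df))
    log_num = special.logsumexp(
        log_like + log_prior + log_jac + np.log(w), axis=1
    )
    log_den = -0.5 * (df + 1.0) * np.log1p(np.atleast_1d(t) ** 2 / df)
    return log_num - log_den


def _one_sided_log_bf(t: np.ndarray, n_eff: float, df: float, r: float) -> np.ndarray:
    # delta = r * tan(pi u / 2), u in (0, 1): the substitution's Jacobian
    # cancels the half-Cauchy prior density exactly
    u, w = _leggauss(_GAUSS_NODES)
    ncp = r * np.tan(0.5 * np.pi * u) * np.sqrt(n_eff)
    tt = np.atleast_1d(t)[:, None]
    with np.errstate(all="ignore"):
        log_like = stats.nct.logpdf(tt, df, ncp[None, :])
    # scipy yields NaN for extreme noncentralities, where the density is
    # vanishingly small: treat those nodes as contributing nothing
    log_like = np.where(np.isnan(log_like), -np.inf, log_like)
    log_num = special.logsumexp(log_like + np.log(w), axis=1)
    log_den = stats.t.logpdf(np.atleast_1d(t), df)
    return log_num - log_den


def jzs_bf_from_t(
    t,
    n1: int,
    n2: int | None = None,
    cauchy_scale: float = 1.0,
    direction: str = TWO_SIDED,
    log: bool = False,
):
    """JZS Bayes factor BF10 from a t statistic.

    Vectorised over ``t``.  ``n2=None`` selects the one-sample test.
    ``direction='greater'`` tests delta > 0 (positive t favours H1),
    ``'less'`` its mirror image.  ``log=True`` returns ln BF10 (the
    directional factor underflows for strongly opposing t otherwise).
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be positive")
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        n_eff, df = float(n1), float(n1 - 1)
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        n_eff, df = n1 * n2 / (n1 + n2), float(n1 + n2 - 2)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if direction == TWO_SIDED:
        log_bf = _two_sided_log_bf(t_arr, n_eff, df, cauchy_scale)
    elif direction == GREATER:
        log_bf = _one_sided_log_bf(t_arr, n_eff, df, cauchy_scale)
    else:
        log_bf = _one_sided_log_bf(-t_arr, n_eff, df, cauchy_scale)
    out = log_bf if log else np.exp(log_bf)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def evidence_category(bf10: float) -> str:
    """Conventional evidence label for a Bayes factor.

    Boundary values fall in the weaker category; BF10 = 1 is 'anecdotal'
    with no direction.
    """
    if not np.isfinite(bf10) and not np.isposinf(bf10):
        raise ValueError("bf10 must be a positive number")
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 == 1.0:
        return "anecdotal"
    side = "H1" if bf10 > 1.0 else "H0"
    b = bf10 if bf10 > 1.0 else 1.0 / bf10
    if b <= 3.0:
        label = "anecdotal"
    elif b <= 10.0:
        label = "substantial"
    elif b <= 30.0:
        label = "strong"
    elif b <= 100.0:
        label = "very strong"
    else:
        label = "decisive"
    return f"{side}: {label}"


def effect_sizes(t: float, n1: int, n2: int) -> tuple[float, float]:
    """(Cohen's d, partial eta squared) from a two-sample t statistic."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    eta = t * t / (t * t + n1 + n2 - 2)
    return float(d), float(eta)


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per sample")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise DegenerateInputError("both samples have zero variance")
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), n1, n2


def jzs_bf_two_sample(
    x, y, cauchy_scale: float = 1.0, direction: str = TWO_SIDED
) -> BayesFactorResult:
    """Default-prior Bayesian independent-samples t-test."""
    t, n1, n2 = _two_sample_t(x, y)
    bf = jzs_bf_from_t(t, n1, n2, cauchy_scale=cauchy_scale, direction=direction)
    d, eta = effect_sizes(t, n1, n2)
    return BayesFactorResult(
        bf10=bf,
        evidence=evidence_category(bf),
        direction=direction,
        effect_d=d,
        eta_partial=eta,
        n1=n1,
        n2=n2,
        statistic=t,
    )


def jzs_bf_one_sample(
    x, cauchy_scale: float = 1.0, direction: str = TWO_SIDED
) -> BayesFactorResult:
    """Default-prior Bayesian one-sample t-test against a zero mean."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("sample has zero variance")
    t = float(x.mean() / (sd / np.sqrt(n)))
    bf = jzs_bf_from_t(t, n, cauchy_scale=cauchy_scale, direction=direction)
    d = float(x.mean() / sd)
    eta = float(t * t / (t * t + n - 1))
    return BayesFactorResult(
        bf10=bf,
        evidence=evidence_category(bf),
        direction=direction,
        effect_d=d,
        eta_partial=eta,
        n1=n,
        statistic=t,
    )


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _log_r_density(r: float, rho, n: int) -> np.ndarray:
    """Exact log sampling density of Pearson's r given population rho."""
    rho = np.asarray(rho, dtype=float)
    return (
        np.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * np.log(2.0 * np.pi)
        - special.gammaln(n - 0.5)
        + 0.5 * (n - 1) * np.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-r * r)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (rho * r + 1.0)))
    )


def correlation_bf_from_r(r: float, n: int, kappa: float = 1.0) -> float:
    """BF10 for a Pearson correlation under a stretched-beta(1/kappa) prior.

    ``kappa=1`` is the default uniform prior on (-1, 1).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    a = 1.0 / kappa
    log_f0 = _log_r_density(r, 0.0, n)

    def integrand(rho: float) -> float:
        log_prior = stats.beta.logpdf(0.5 * (rho + 1.0), a, a) - np.log(2.0)
        return float(np.exp(_log_r_density(r, rho, n) + log_prior - log_f0))

    num, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
    return float(num)


def bayes_correlation_bf(x, y, kappa: float = 1.0) -> BayesFactorResult:
    """Default Bayesian test for a Pearson correlation between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std(ddof=1) == 0.0 or y.std(ddof=1) == 0.0:
        raise DegenerateInputError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        bf = np.inf
        return BayesFactorResult(
            bf10=bf,
            evidence="H1: decisive",
            direction=TWO_SIDED,
            effect_d=r,
            eta_partial=None,
            n1=n,
        )
    bf = correlation_bf_from_r(r, n, kappa=kappa)
    return BayesFactorResult(
        bf10=bf,
        evidence=evidence_category(bf),
        direction=TWO_SIDED,
        effect_d=r,
        eta_partial=None,
        n1=n,
    )


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def power_ttest(
    d: float, n_per_group: int, alpha: float = 0.05, sided: str = "one"
) -> float:
    """Exact power of an independent-samples t-test via the noncentral t."""
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    if sided == "one":
        t_crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(t_crit, df, ncp))
    if sided == "two":
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))
    raise ValueError("sided must be 'one' or 'two'")
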