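"""Independent numerical oracles used only by the test suite.

These deliberately take different computational routes from the package:
the t-test Bayes factor is integrated over the effect-size prior with
adaptive quadrature of the noncentral-t likelihood (the package integrates
over the normal-mixture scale with fixed Gauss-Legendre nodes), and the
correlation Bayes factor uses a dense Simpson rule (the package uses
adaptive quadrature).
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from switchbf.bayes import _log_r_density


def jzs_bf_quad(t: float, n1: int, n2: int | None = None,
                cauchy_scale: float = 1.0, direction: str = "two-sided") -> float:
    """Brute-force JZS Bayes factor by adaptive quadrature over delta."""
    if n2 is None:
        n_eff, df = float(n1), n1 - 1
    else:
        n_eff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2

    def integrand(delta: float) -> float:
        like = stats.nct.pdf(t, df, delta * np.sqrt(n_eff))
        if not np.isfinite(like):  # scipy NaN at extreme noncentrality
            return 0.0
        return like * stats.cauchy.pdf(delta, scale=cauchy_scale)

    if direction == "two-sided":
        lo, _ = integrate.quad(integrand, -np.inf, 0, limit=400)
        hi, _ = integrate.quad(integrand, 0, np.inf, limit=400)
        num = lo + hi
    elif direction == "greater":
        hi, _ = integrate.quad(integrand, 0, np.inf, limit=400)
        num = 2.0 * hi
    else:
        raise ValueError(direction)
    return num / stats.t.pdf(t, df)


def correlation_bf_simpson(r: float, n: int, kappa: float = 1.0,
                           n_grid: int = 20001) -> float:
    """Correlation Bayes factor by a dense Simpson rule over rho."""
    a = 1.0 / kappa
    rho = np.linspace(-1.0 + 1e-9, 1.0 - 1e-9, n_grid)
    log_prior = stats.beta.logpdf(0.5 * (rho + 1.0), a, a) - np.log(2.0)
    log_f0 = _log_r_density(r, 0.0, n)
    vals = np.exp(_log_r_density(r, rho, n) + log_prior - log_f0)
    return float(integrate.simpson(vals, x=rho))
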