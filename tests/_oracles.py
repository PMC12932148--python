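"""Independent numerical oracles for the Bayesian estimators.

These deliberately avoid the closed forms used by the implementation:
the IC oracle is plain Monte-Carlo over the posterior Beta marginals, and
the EBGM05 oracle integrates the posterior density by adaptive quadrature
(including the mixture weights, which it recomputes by integrating the
Poisson-gamma marginals numerically) and inverts the CDF by bisection.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from pvsignal.contingency import ContingencyTable
from pvsignal.signals import GpsPrior, IcPriors


def ic_mc_oracle(
    t: ContingencyTable,
    priors: IcPriors = IcPriors(),
    n_draws: int = 10**6,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo posterior mean of IC and its standard error."""
    rng = rng or np.random.default_rng(0)
    a, n = t.a, t.n
    p = priors
    row = a + t.b + p.alpha1
    col = a + t.c + p.beta1
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (row * col)
    p11 = rng.beta(a + p.gamma11, n - a + gamma - p.gamma11, n_draws)
    px = rng.beta(row, n - (a + t.b) + p.alpha - p.alpha1, n_draws)
    py = rng.beta(col, n - (a + t.c) + p.beta - p.beta1, n_draws)
    draws = np.log2(p11 / (px * py))
    return float(draws.mean()), float(draws.std() / np.sqrt(n_draws))


def ebgm05_quadrature_oracle(
    t: ContingencyTable,
    prior: GpsPrior,
    quantile: float = 0.05,
) -> float:
    """Posterior 5th percentile by quadrature of the unnormalised density.

    density(lam) ∝ pi * Pois(a | lam*E) Gamma(lam; a1, b1)
                 + (1-pi) * Pois(a | lam*E) Gamma(lam; a2, b2)
    """
    a, e = t.a, t.expected

    def comp(lam, shape, rate):
        return (stats.poisson.pmf(a, lam * e)
                * stats.gamma.pdf(lam, shape, scale=1.0 / rate))

    def dens(lam):
        return (prior.pi * comp(lam, prior.alpha1, prior.beta1)
                + (1 - prior.pi) * comp(lam, prior.alpha2, prior.beta2))

    # generous support bracket from the posterior component quantiles
    comps = [(prior.alpha1 + a, prior.beta1 + e),
             (prior.alpha2 + a, prior.beta2 + e)]
    hi = max(stats.gamma.ppf(1 - 1e-12, s, scale=1.0 / r) for s, r in comps)
    total, _ = integrate.quad(dens, 0, hi, limit=400)

    def cdf(x):
        val, _ = integrate.quad(dens, 0, x, limit=400)
        return val / total

    lo_x, hi_x = 0.0, hi
    for _ in range(200):
        mid = 0.5 * (lo_x + hi_x)
        if cdf(mid) < quantile:
            lo_x = mid
        else:
            hi_x = mid
        # relative stopping rule: the quantile can be many orders of
        # magnitude below 1 for zero-count tables
        if lo_x > 0 and (hi_x - lo_x) < 1e-7 * lo_x:
            break
    return 0.5 * (lo_x + hi_x)


def type7_quantile_oracle(values, q: float) -> float:
    """Sort-based linear-interpolation quantile (no numpy percentile)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
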