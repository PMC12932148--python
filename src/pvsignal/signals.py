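"""Disproportionality estimators and signal classification.

Four estimators per 2x2 table, the standard battery of spontaneous-report
signal screening:

ROR
    Reporting odds ratio (a*d)/(b*c) with a Wald 95% CI on the log scale;
    zero cells trigger the Haldane-Anscombe +0.5 correction of all four
    cells (flagged on the result).
PRR
    Proportional reporting ratio [a/(a+b)] / [c/(c+d)] with the
    Yates-corrected Pearson chi-square, classified by the MHRA composite
    rule (a >= 3, PRR >= 2, chi2 >= 4).
BCPNN IC
    Information component log2 P(drug, event)/(P(drug)P(event)) under the
    Bayesian confidence propagation neural network model. The posterior of
    (p11, px, py) is three Beta distributions; the IC point estimate is the
    exact posterior mean E[log2(p11/(px*py))] computed with digamma
    functions, its variance the trigamma analogue, and IC025 = E - 2*sqrt(V).
    Hyperparameters: alpha1 = beta1 = gamma11 = 1, alpha = beta = 2, with
    gamma calibrated so the prior IC expectation is zero.
MGPS EBGM
    DuMouchel's empirical-Bayes gamma-Poisson shrinker. The count a is
    Poisson(lambda * E) with E = (a+b)(a+c)/N; lambda has a two-component
    gamma mixture prior whose hyperparameters maximise the marginal
    negative-binomial mixture likelihood across all tables of a level.
    EBGM is the geometric posterior mean 2**E[log2 lambda | a]; EBGM05 the
    5th posterior percentile.

The classification thresholds (and every constant above) are exposed in
:class:`SignalCriteria` / :class:`IcPriors` / the fit start point, because
published analyses vary in these choices and reproducing one requires
pinning them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .contingency import ContingencyTable

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# frequentist estimators

class RorEstimate(NamedTuple):
    ror: float
    lo: float
    hi: float
    corrected: bool  # Haldane-Anscombe +0.5 applied


def ror_estimate(t: ContingencyTable, z: float = 1.96) -> RorEstimate:
    """Reporting odds ratio with Wald 95% CI.

    Any zero cell switches to the Haldane-Anscombe corrected table
    (all cells +0.5), flagged via ``corrected``.
    """
    a, b, c, d = (float(x) for x in t.cells())
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorEstimate(
        ror, ror * math.exp(-z * se), ror * math.exp(z * se), corrected)


class PrrEstimate(NamedTuple):
    prr: float
    chi2: float
    defined: bool  # False when a margin is zero


def prr_estimate(t: ContingencyTable) -> PrrEstimate:
    """Proportional reporting ratio and Yates-corrected chi-square.

    chi2 is sum((|O-E|-0.5)^2 / E) over the four cells, with the correction
    clamped at zero when |O-E| < 0.5 (degenerate near-null tables).
    Zero-margin tables return NaN PRR flagged undefined.
    """
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return PrrEstimate(float("nan"), 0.0, False)
    prr = (a / r1) / (c / r2) if c > 0 else float("inf")
    dev = max(abs(a * d - b * c) / n - 0.5, 0.0)
    chi2 = (dev * dev) * n * n * n / (r1 * r2 * c1 * c2)
    return PrrEstimate(prr, chi2, True)


# ---------------------------------------------------------------------------
# BCPNN information component

@dataclass(frozen=True)
class IcPriors:
    """BCPNN hyperparameters; defaults reproduce the data-calibrated prior
    with E(IC) = 0 a priori."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


class IcEstimate(NamedTuple):
    ic: float
    ic025: float
    var: float


def ic_bate(t: ContingencyTable, priors: IcPriors = IcPriors()) -> IcEstimate:
    """Information component: exact posterior mean and variance.

    Under the model the posterior components are independent:
    p11 ~ Beta(a+g11, N-a+g-g11), px ~ Beta(a+b+a1, N-(a+b)+alpha-a1),
    py ~ Beta(a+c+b1, N-(a+c)+beta-b1), with the joint-cell prior scale
    g = g11*(N+alpha)*(N+beta)/((a+b+a1)*(a+c+b1)) so the prior IC
    expectation is zero. E[log p] of a Beta(u, v) is psi(u) - psi(u+v) and
    its variance psi'(u) - psi'(u+v), giving closed forms in digamma /
    trigamma; IC025 = E(IC) - 2*sqrt(V(IC)).
    """
    a = float(t.a)
    n = float(t.n)
    if n <= 0:
        raise ValueError("empty table")
    p = priors
    row = t.a + t.b + p.alpha1
    col = t.a + t.c + p.beta1
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (row * col)
    u11 = a + p.gamma11
    ex = (
        special.psi(u11) - special.psi(n + gamma)
        - special.psi(row) + special.psi(n + p.alpha)
        - special.psi(col) + special.psi(n + p.beta)
    ) / LN2
    var = (
        special.polygamma(1, u11) - special.polygamma(1, n + gamma)
        + special.polygamma(1, row) - special.polygamma(1, n + p.alpha)
        + special.polygamma(1, col) - special.polygamma(1, n + p.beta)
    ) / (LN2 * LN2)
    return IcEstimate(ex, ex - 2.0 * math.sqrt(var), var)


# ---------------------------------------------------------------------------
# MGPS / EBGM

@dataclass(frozen=True)
class GpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate."""

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    pi: float = 1.0 / 3.0
    converged: bool = True
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not (0.0 < self.pi < 1.0):
            raise ValueError("mixture weight pi must lie in (0, 1)")

    @property
    def prior_mean(self) -> float:
        return self.pi * self.alpha1 / self.beta1 + (1 - self.pi) * self.alpha2 / self.beta2


DUMOUCHEL_START = GpsPrior()


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(alpha, rate beta)
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


def gps_marginal_loglik(
    prior: GpsPrior, a: np.ndarray, e: np.ndarray
) -> float:
    """Marginal log-likelihood of observed counts under the mixture prior."""
    l1 = _nb_logpmf(a, e, prior.alpha1, prior.beta1) + math.log(prior.pi)
    l2 = _nb_logpmf(a, e, prior.alpha2, prior.beta2) + math.log(1 - prior.pi)
    return float(np.logaddexp(l1, l2).sum())


def fit_gps_prior(
    tables: Sequence[ContingencyTable],
    start: GpsPrior = DUMOUCHEL_START,
    tol: float = 1e-6,
) -> GpsPrior:
    """Empirical-Bayes fit of the gamma-mixture hyperparameters.

    Maximises the negative-binomial mixture marginal likelihood of the
    observed a-counts given expected counts E, by quasi-Newton search in
    (log alpha1, log beta1, log alpha2, log beta2, logit pi) started at the
    DuMouchel defaults. Optimiser failure falls back to the start values
    with ``converged=False``.
    """
    if len(tables) < 10:
        raise ValueError(
            f"empirical-Bayes fitting needs >= 10 tables, got {len(tables)}")
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    return fit_gps_prior_counts(a, e, start=start, tol=tol)


def fit_gps_prior_counts(
    a: np.ndarray,
    e: np.ndarray,
    start: GpsPrior = DUMOUCHEL_START,
    tol: float = 1e-6,
) -> GpsPrior:
    """Hyperparameter fit from raw (observed, expected) count arrays."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]

    def unpack(x: np.ndarray) -> GpsPrior:
        return GpsPrior(
            alpha1=math.exp(x[0]), beta1=math.exp(x[1]),
            alpha2=math.exp(x[2]), beta2=math.exp(x[3]),
            pi=1.0 / (1.0 + math.exp(-x[4])))

    def nll(x: np.ndarray) -> float:
        try:
            prior = unpack(x)
            l1 = _nb_logpmf(a, e, prior.alpha1, prior.beta1) \
                + math.log(prior.pi)
            l2 = _nb_logpmf(a, e, prior.alpha2, prior.beta2) \
                + math.log(1 - prior.pi)
            # log-pmf values above 0 signal numerical breakdown of the
            # negative-binomial evaluation (extreme shapes): reject
            if (not np.all(np.isfinite(np.minimum(l1, l2)))
                    or float(np.max(np.maximum(l1, l2))) > 1e-8):
                return float("inf")
            return -float(np.logaddexp(l1, l2).sum())
        except (OverflowError, ValueError):
            return float("inf")

    x0 = np.array([
        math.log(start.alpha1), math.log(start.beta1),
        math.log(start.alpha2), math.log(start.beta2),
        math.log(start.pi / (1 - start.pi)),
    ])
    # keep the search inside the numerically reliable hyperparameter range
    log_lim = math.log(1e8)
    bounds = [(-log_lim, log_lim)] * 4 + [(-20.0, 20.0)]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": tol, "maxiter": 500})
    if not res.success or not np.isfinite(res.fun):
        return replace(start, converged=False,
                       log_likelihood=-nll(x0))
    fitted = unpack(res.x)
    return replace(fitted, converged=True, log_likelihood=float(-res.fun))


class EbgmEstimate(NamedTuple):
    ebgm: float
    ebgm05: float
    defined: bool


def _posterior_mix(t: ContingencyTable, prior: GpsPrior):
    """Posterior over lambda: weights and gamma (shape, rate) components."""
    a = float(t.a)
    e = t.expected
    l1 = _nb_logpmf(np.array(a), np.array(e), prior.alpha1, prior.beta1) \
        + math.log(prior.pi)
    l2 = _nb_logpmf(np.array(a), np.array(e), prior.alpha2, prior.beta2) \
        + math.log(1 - prior.pi)
    q = float(special.expit(float(l1) - float(l2)))
    return q, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e)


def ebgm(t: ContingencyTable, prior: GpsPrior, quantile: float = 0.05) -> EbgmEstimate:
    """EBGM (geometric posterior mean) and EBGM05 (posterior 5th percentile).

    The posterior is a two-gamma mixture; the quantile is located by Brent
    root-finding on the mixture CDF to ~1e-10 relative precision. E = 0
    tables are flagged undefined.
    """
    if t.expected == 0:
        return EbgmEstimate(float("nan"), float("nan"), False)
    q, (s1, r1), (s2, r2) = _posterior_mix(t, prior)
    mean_log = (
        q * (special.psi(s1) - math.log(r1))
        + (1 - q) * (special.psi(s2) - math.log(r2)))
    gm = math.exp(mean_log)

    g1 = stats.gamma(s1, scale=1.0 / r1)
    g2 = stats.gamma(s2, scale=1.0 / r2)

    def cdf(x: float) -> float:
        return q * g1.cdf(x) + (1 - q) * g2.cdf(x)

    # the mixture quantile lies between the component quantiles; when one
    # component carries ~all posterior weight the bracket degenerates to a
    # point and rounding can flip an endpoint sign, so fall back to the
    # endpoint nearer the root in that case
    q1, q2 = sorted((g1.ppf(quantile), g2.ppf(quantile)))
    if math.isclose(q1, q2, rel_tol=1e-12) or q < 1e-12:
        qv = g2.ppf(quantile) if q < 0.5 else g1.ppf(quantile)
    elif q > 1 - 1e-12:
        qv = g1.ppf(quantile)
    else:
        try:
            qv = optimize.brentq(
                lambda x: cdf(x) - quantile, q1, q2,
                xtol=1e-14, rtol=4e-15, maxiter=200)
        except ValueError:
            qv = min((q1, q2), key=lambda x: abs(cdf(x) - quantile))
    return EbgmEstimate(gm, qv, True)


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class SignalCriteria:
    """Positive-signal thresholds per method (boundaries as documented)."""

    min_count: int = 3          # a >= 3 gates ROR and PRR
    ror_lo_gt: float = 1.0      # ROR CI lower bound strictly above
    prr_ge: float = 2.0         # PRR >= (inclusive)
    chi2_ge: float = 4.0        # chi-square >= (inclusive)
    ic025_gt: float = 0.0       # IC025 strictly above
    ebgm05_gt: float = 2.0      # EBGM05 strictly above
    composite: str = "any"      # 'any' or 'all' of the four methods

    def __post_init__(self) -> None:
        if self.composite not in ("any", "all"):
            raise ValueError("composite must be 'any' or 'all'")


@dataclass
class SignalResult:
    """All four estimators plus flags for one term."""

    term: str
    level: str
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    ror_corrected: bool
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: dict = field(default_factory=dict)


def classify(result: SignalResult, criteria: SignalCriteria = SignalCriteria()) -> dict:
    """Per-method positivity flags plus the composite flag."""
    gate = result.a >= criteria.min_count
    flags = {
        "ROR": bool(gate and result.ror_lo > criteria.ror_lo_gt),
        "PRR": bool(
            gate
            and not math.isnan(result.prr)
            and result.prr >= criteria.prr_ge
            and result.chi2 >= criteria.chi2_ge),
        "BCPNN": bool(result.ic025 > criteria.ic025_gt),
        "MGPS": bool(
            not math.isnan(result.ebgm05)
            and result.ebgm05 > criteria.ebgm05_gt),
    }
    per_method = [flags["ROR"], flags["PRR"], flags["BCPNN"], flags["MGPS"]]
    flags["composite"] = (
        any(per_method) if criteria.composite == "any" else all(per_method))
    return flags


def compute_signals(
    tables: Sequence[ContingencyTable],
    prior: GpsPrior | None = None,
    criteria: SignalCriteria = SignalCriteria(),
    ic_priors: IcPriors = IcPriors(),
) -> list[SignalResult]:
    """All four estimators for every table, with classification flags.

    When ``prior`` is None the MGPS hyperparameters are fitted to the
    supplied tables first (requires >= 10 of them).
    """
    if prior is None:
        prior = fit_gps_prior(tables)
    out = []
    for t in tables:
        r = ror_estimate(t)
        p = prr_estimate(t)
        i = ic_bate(t, ic_priors)
        g = ebgm(t, prior)
        res = SignalResult(
            term=t.term, level=t.level, a=t.a,
            ror=r.ror, ror_lo=r.lo, ror_hi=r.hi, ror_corrected=r.corrected,
            prr=p.prr, chi2=p.chi2, ic=i.ic, ic025=i.ic025,
            ebgm=g.ebgm, ebgm05=g.ebgm05)
        res.flags = classify(res, criteria)
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# model / results facade

class DisproportionalityModel:
    """Disproportionality screen for one target drug at one MedDRA level.

    Parameters
    ----------
    tables
        The 2x2 tables, one per term (see :func:`contingency.build_tables`).
    ic_priors, criteria
        Hyperparameters and flagging thresholds; defaults are the
        conventional published choices.

    ``fit()`` estimates the MGPS prior across the tables (unless one is
    supplied) and evaluates all four estimators per term.
    """

    def __init__(
        self,
        tables: Sequence[ContingencyTable],
        ic_priors: IcPriors = IcPriors(),
        criteria: SignalCriteria = SignalCriteria(),
    ) -> None:
        if not tables:
            raise ValueError("no contingency tables supplied")
        levels = {t.level for t in tables}
        if len(levels) != 1:
            raise ValueError(f"mixed table levels: {sorted(levels)}")
        self.tables = list(tables)
        self.level = levels.pop()
        self.ic_priors = ic_priors
        self.criteria = criteria

    @classmethod
    def from_corpus(cls, corpus, target_caseids, level="PT", **kw):
        from .contingency import build_tables

        return cls(build_tables(corpus, target_caseids, level), **kw)

    def fit(self, prior: GpsPrior | None = None) -> "DisproportionalityResults":
        if prior is None:
            if len(self.tables) >= 10:
                prior = fit_gps_prior(self.tables)
            else:
                # too few terms for empirical-Bayes fitting: fall back to
                # the DuMouchel default prior, flagged unconverged
                prior = replace(DUMOUCHEL_START, converged=False)
        results = compute_signals(
            self.tables, prior=prior, criteria=self.criteria,
            ic_priors=self.ic_priors)
        return DisproportionalityResults(self, results, prior)


class DisproportionalityResults:
    """Fitted signal screen: per-term estimates, flags and export helpers."""

    def __init__(self, model, results: list[SignalResult], prior: GpsPrior):
        self.model = model
        self.results = results
        self.prior = prior

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "term": r.term, "level": r.level, "a": r.a,
                "ror": r.ror, "ror_lo": r.ror_lo, "ror_hi": r.ror_hi,
                "prr": r.prr, "chi2": r.chi2,
                "ic": r.ic, "ic025": r.ic025,
                "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                "flag_ror": r.flags["ROR"], "flag_prr": r.flags["PRR"],
                "flag_bcpnn": r.flags["BCPNN"], "flag_mgps": r.flags["MGPS"],
                "flag_composite": r.flags["composite"],
            })
        return pd.DataFrame(rows)

    def report_frame(self) -> pd.DataFrame:
        """Publication-style table: term, case reports, ROR (95% CI),
        PRR (95% CI), IC (IC025), EBGM (EBGM05)."""
        rows = []
        for r in self.results:
            rows.append({
                ("System organ class (SOC)" if r.level == "SOC"
                 else "Preferred term (PT)"): r.term,
                "Case reports": r.a,
                "ROR (95% CI)": f"{r.ror:.3f} ({r.ror_lo:.3f}-{r.ror_hi:.3f})",
                "PRR (95% CI)": f"{r.prr:.3f} (chi2 {r.chi2:.1f})",
                "IC (IC025)": f"{r.ic:.3f} ({r.ic025:.3f})",
                "EBGM (EBGM05)": f"{r.ebgm:.3f} ({r.ebgm05:.3f})",
            })
        return pd.DataFrame(rows)

    def positive(self, method: str = "composite") -> list[SignalResult]:
        key = {"composite": "composite", "ror": "ROR", "prr": "PRR",
               "bcpnn": "BCPNN", "mgps": "MGPS"}[method.lower()]
        return [r for r in self.results if r.flags[key]]

    def summary(self) -> str:
        n_pos = len(self.positive())
        lines = [
            f"Disproportionality screen ({self.model.level} level)",
            f"  terms evaluated : {len(self.results)}",
            f"  positive ({self.model.criteria.composite}-method) : {n_pos}",
            (f"  MGPS prior      : a1={self.prior.alpha1:.3g} "
             f"b1={self.prior.beta1:.3g} a2={self.prior.alpha2:.3g} "
             f"b2={self.prior.beta2:.3g} pi={self.prior.pi:.3g} "
             f"(converged={self.prior.converged})"),
            "",
            self.report_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def to_delimited(self, path, sep: str = "\t") -> None:
        self.report_frame().to_csv(path, sep=sep, index=False)
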