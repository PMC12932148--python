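"""Time-to-onset analysis: binning, quantiles and Weibull modelling.

Onset is the interval in whole days from the earliest therapy start of the
primary-suspect drug to the event date; day 0 means the event was reported
on the day treatment began ("immediate"). Cases with missing, partial or
negative intervals are excluded and tallied by reason — the strict default
policy accepts only full-precision (yyyymmdd) dates on both ends.

The Weibull model
-----------------
Onset times are modelled as Weibull(shape k, scale lam):
S(t) = exp(-(t/lam)^k). A shape below 1 indicates an early-failure hazard
(events cluster just after initiation, the typical spontaneous-report
pattern); shape 1 is memoryless; above 1 the hazard rises with time.
Maximum likelihood uses Newton iteration on the profile shape equation

    1/k = sum(x^k log x)/sum(x^k) - mean(log x),   lam = (mean(x^k))^(1/k)

to a tolerance of 1e-10. Day-0 observations have zero Weibull density, so a
zero-handling policy applies first: ``shift_half_day`` (default) moves them
to 0.5 d, ``drop_zeros`` removes them; the policy used is recorded on the
fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .curation import CaseCorpus
from .faers_io import parse_date

#: §-style onset bins: label, lower day, upper day (inclusive)
ONSET_BINS: list[tuple[str, int, float]] = [
    ("immediate (0 d)", 0, 0),
    ("1 d", 1, 1),
    ("2 d", 2, 2),
    ("3 d", 3, 3),
    ("4-30 d", 4, 30),
    ("31-60 d", 31, 60),
    ("61-90 d", 61, 90),
    ("91-120 d", 91, 120),
    ("121-150 d", 121, 150),
    ("151-180 d", 151, 180),
    ("181-365 d", 181, 365),
    (">365 d", 366, math.inf),
]

ZERO_POLICIES = ("shift_half_day", "drop_zeros")


@dataclass
class ExclusionReport:
    n_input: int = 0
    n_used: int = 0
    reasons: dict = field(default_factory=dict)  # reason -> count


def onset_days_from_dates(event_dt: str, start_dt: str) -> tuple[int | None, str]:
    """Whole-day interval between two yyyymmdd strings, or (None, reason).

    Reasons: 'missing' (either date absent/unparseable), 'partial' (either
    date at month/year precision), 'negative' (event precedes start).
    """
    ev = parse_date(event_dt)
    st = parse_date(start_dt)
    if ev.precision == "missing" or st.precision == "missing":
        return None, "missing"
    if not (ev.is_full and st.is_full):
        return None, "partial"
    days = (ev.date - st.date).days
    if days < 0:
        return None, "negative"
    return days, "ok"


def collect_onsets(corpus: CaseCorpus) -> tuple[pd.DataFrame, ExclusionReport]:
    """Per-case onset samples from a curated corpus.

    Returns a ``(caseid, onset_days)`` frame for usable cases plus the
    exclusion tally over reasons missing/partial/negative.
    """
    report = ExclusionReport(n_input=corpus.n_cases)
    rows = []
    for row in corpus.cases.itertuples(index=False):
        days, reason = onset_days_from_dates(row.event_dt, row.start_dt)
        if days is None:
            report.reasons[reason] = report.reasons.get(reason, 0) + 1
        else:
            rows.append((row.caseid, days))
    samples = pd.DataFrame(rows, columns=["caseid", "onset_days"])
    report.n_used = len(samples)
    return samples, report


def bin_onsets(days: Sequence[int]) -> pd.DataFrame:
    """Frequency table over the standard onset bins.

    Returns columns (bin, count, percent) with percentages of n rounded
    half-up to 2 decimals, plus a final cumulative row for <= 30 days.
    """
    arr = np.asarray(list(days), dtype=float)
    if arr.size == 0:
        raise ValueError("no onset samples to bin")
    n = arr.size
    rows = []
    for label, lo, hi in ONSET_BINS:
        count = int(((arr >= lo) & (arr <= hi)).sum())
        rows.append({"bin": label, "count": count,
                     "percent": round_half_up(100.0 * count / n)})
    cum30 = int((arr <= 30).sum())
    rows.append({"bin": "cumulative <=30 d", "count": cum30,
                 "percent": round_half_up(100.0 * cum30 / n)})
    return pd.DataFrame(rows)


def median_iqr(days: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles with linear interpolation (quantile type 7)."""
    arr = np.asarray(list(days), dtype=float)
    if arr.size == 0:
        raise ValueError("no onset samples")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def cumulative_incidence(days: Sequence[int]) -> pd.DataFrame:
    """Empirical CDF over observed days: (day, cumulative fraction)."""
    arr = np.asarray(list(days), dtype=float)
    if arr.size == 0:
        raise ValueError("no onset samples")
    uniq, counts = np.unique(arr, return_counts=True)
    frac = np.cumsum(counts) / arr.size
    return pd.DataFrame({"day": uniq, "cumulative_fraction": frac})


# ---------------------------------------------------------------------------
# Weibull MLE

@dataclass(frozen=True)
class WeibullFit:
    shape: float
    scale: float
    log_likelihood: float
    n_used: int
    zero_handling: str
    n_iterations: int = 0

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-np.power(t / self.scale, self.shape))

    def cdf(self, t):
        return 1.0 - self.survival(t)


def _apply_zero_policy(arr: np.ndarray, policy: str) -> np.ndarray:
    if policy not in ZERO_POLICIES:
        raise ValueError(f"unknown zero policy {policy!r}; use one of {ZERO_POLICIES}")
    if policy == "shift_half_day":
        out = arr.astype(float).copy()
        out[out == 0] = 0.5
        return out
    out = arr[arr > 0].astype(float)
    if out.size == 0:
        raise ValueError("all onsets are zero days; nothing left under drop_zeros")
    return out


def weibull_fit(
    days: Sequence[float],
    zero_policy: str = "shift_half_day",
    tol: float = 1e-10,
    max_iter: int = 200,
) -> WeibullFit:
    """Maximum-likelihood Weibull fit of onset days.

    Newton iteration on the profile shape equation
    g(k) = sum(x^k ln x)/sum(x^k) - 1/k - mean(ln x) = 0, started at the
    moment-matched k0 = pi / (sd(ln x) * sqrt(6)); the scale follows in
    closed form. Requires >= 10 positive values after the zero policy.
    """
    x = _apply_zero_policy(np.asarray(list(days), dtype=float), zero_policy)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("onset days must be finite and nonnegative")
    if x.size < 10:
        raise ValueError(f"need >= 10 positive onset values, got {x.size}")
    logx = np.log(x)
    mlog = logx.mean()
    slog = logx.std()
    if slog == 0:
        raise ValueError("degenerate sample: all onset values identical")

    k = math.pi / (slog * math.sqrt(6.0))

    def g_and_grad(k: float) -> tuple[float, float]:
        w = np.exp(k * logx)          # x^k
        sw = w.sum()
        swl = (w * logx).sum()
        swl2 = (w * logx * logx).sum()
        ratio = swl / sw
        g = ratio - 1.0 / k - mlog
        dg = swl2 / sw - ratio * ratio + 1.0 / (k * k)
        return g, dg

    it = 0
    for it in range(1, max_iter + 1):
        g, dg = g_and_grad(k)
        step = g / dg
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) <= tol * max(1.0, k):
            k = k_new
            break
        k = k_new
    scale = float(np.exp(k * logx).mean() ** (1.0 / k))
    n = x.size
    ll = (
        n * (math.log(k) - k * math.log(scale))
        + (k - 1.0) * logx.sum()
        - float(np.power(x / scale, k).sum())
    )
    return WeibullFit(
        shape=float(k), scale=scale, log_likelihood=float(ll),
        n_used=n, zero_handling=zero_policy, n_iterations=it)


# ---------------------------------------------------------------------------
# model / results facade

class WeibullOnsetModel:
    """Time-to-onset model for a set of per-case onset days.

    Accepts either a samples frame from :func:`collect_onsets` or a plain
    sequence of day counts. ``fit()`` runs the Weibull MLE under the chosen
    zero policy and returns a results object carrying the parameter
    estimates with large-sample standard errors, the descriptive bins and
    the empirical cumulative incidence.
    """

    def __init__(self, samples, zero_policy: str = "shift_half_day") -> None:
        if isinstance(samples, pd.DataFrame):
            self.days = samples["onset_days"].to_numpy(dtype=float)
        else:
            self.days = np.asarray(list(samples), dtype=float)
        if self.days.size == 0:
            raise ValueError("no onset samples")
        self.zero_policy = zero_policy

    @classmethod
    def from_corpus(cls, corpus: CaseCorpus, zero_policy: str = "shift_half_day"):
        samples, report = collect_onsets(corpus)
        model = cls(samples, zero_policy=zero_policy)
        model.exclusion_report = report
        return model

    def fit(self) -> "WeibullOnsetResults":
        fit = weibull_fit(self.days, zero_policy=self.zero_policy)
        return WeibullOnsetResults(self, fit)


class WeibullOnsetResults:
    """Fitted onset model: parameters, uncertainty and descriptives."""

    def __init__(self, model: WeibullOnsetModel, fit: WeibullFit) -> None:
        self.model = model
        self.fit_ = fit
        self.shape = fit.shape
        self.scale = fit.scale
        self.log_likelihood = fit.log_likelihood
        self.n_used = fit.n_used
        self.shape_se, self.scale_se = self._wald_se()

    def _wald_se(self) -> tuple[float, float]:
        # observed information of the log-likelihood in (shape, scale),
        # central finite differences on the profile-free log-likelihood
        x = _apply_zero_policy(self.model.days, self.model.zero_policy)

        def ll(k: float, lam: float) -> float:
            n = x.size
            return (
                n * (math.log(k) - k * math.log(lam))
                + (k - 1.0) * float(np.log(x).sum())
                - float(np.power(x / lam, k).sum()))

        k, lam = self.shape, self.scale
        hk, hl = 1e-5 * max(k, 1e-3), 1e-5 * max(lam, 1e-3)
        h = np.zeros((2, 2))
        h[0, 0] = (ll(k + hk, lam) - 2 * ll(k, lam) + ll(k - hk, lam)) / hk**2
        h[1, 1] = (ll(k, lam + hl) - 2 * ll(k, lam) + ll(k, lam - hl)) / hl**2
        h[0, 1] = h[1, 0] = (
            ll(k + hk, lam + hl) - ll(k + hk, lam - hl)
            - ll(k - hk, lam + hl) + ll(k - hk, lam - hl)) / (4 * hk * hl)
        try:
            cov = np.linalg.inv(-h)
            if cov[0, 0] > 0 and cov[1, 1] > 0:
                return float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass
        return float("nan"), float("nan")

    def bins(self) -> pd.DataFrame:
        return bin_onsets(self.model.days)

    def median_iqr(self) -> tuple[float, float, float]:
        return median_iqr(self.model.days)

    def cumulative_incidence(self) -> pd.DataFrame:
        return cumulative_incidence(self.model.days)

    def summary(self) -> str:
        med, q1, q3 = self.median_iqr()
        lines = [
            "Weibull time-to-onset model",
            f"  n used          : {self.n_used} "
            f"(zero policy: {self.fit_.zero_handling})",
            f"  shape (k)       : {self.shape:.4f} (SE {self.shape_se:.4f})",
            f"  scale (days)    : {self.scale:.4f} (SE {self.scale_se:.4f})",
            f"  log-likelihood  : {self.log_likelihood:.3f}",
            f"  median [IQR]    : {med:.2f} [{q1:.2f}-{q3:.2f}] days",
            "",
            self.bins().to_string(index=False),
        ]
        return "\n".join(lines)
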