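"""Enrichment and survival association of genomic features.

Feature-vs-group enrichment uses the two-sided Fisher exact test with a
conditional maximum-likelihood odds ratio. Time-to-event association uses
the Kaplan–Meier product-limit estimator with Greenwood variance, the
log-rank test (with an "extreme pair" mode for more than two groups that
compares the best and worst median-survival groups), and univariate Cox
proportional-hazards models with Efron tie handling and Wald inference.
BH-FDR is applied per analysis table by the caller-facing helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .drivers import bh_fdr


@dataclass(frozen=True)
class SurvivalRecord:
    patient: str
    time: float  # months
    event: int   # 1 observed, 0 censored
    endpoint: str = "PFS"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient": [r.patient for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        }
    )


@dataclass
class EnrichmentResult:
    feature: str
    group_def: str
    odds_ratio: float
    p: float
    fdr: float = math.nan
    reason: Optional[str] = None


def fisher_enrichment(
    feature: Sequence[int], group: Sequence[int],
    feature_name: str = "", group_name: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of a binary feature against a binary
    group label, with the conditional-MLE odds ratio. Constant vectors give
    an NA result with a reason."""
    f = np.asarray(feature, dtype=int)
    g = np.asarray(group, dtype=int)
    if f.shape != g.shape:
        raise ValueError("feature and group vectors differ in length")
    if f.min() == f.max() or g.min() == g.max():
        return EnrichmentResult(feature_name, group_name, math.nan, math.nan,
                                reason="constant vector")
    table = [
        [int(np.sum((f == 1) & (g == 1))), int(np.sum((f == 1) & (g == 0)))],
        [int(np.sum((f == 0) & (g == 1))), int(np.sum((f == 0) & (g == 0)))],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    or_mle = _odds_ratio(table, kind="conditional").statistic
    return EnrichmentResult(feature_name, group_name, float(or_mle), float(p))


def enrichment_table(
    matrix: pd.DataFrame, group: Sequence[int], group_name: str = ""
) -> pd.DataFrame:
    """Fisher enrichment for every feature column, BH-FDR across the table."""
    results = [
        fisher_enrichment(matrix[c], group, feature_name=str(c), group_name=group_name)
        for c in matrix.columns
    ]
    testable = [r for r in results if not math.isnan(r.p)]
    if testable:
        q = bh_fdr([r.p for r in testable])
        for r, qq in zip(testable, q):
            r.fdr = float(qq)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "reason": [r.reason for r in results],
        }
    )


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood
    median: float         # NaN when S never reaches 0.5


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Product-limit survival estimate with Greenwood variance and median
    survival (first time S(t) <= 0.5; NaN if never reached)."""
    if not records:
        raise ValueError("no survival records")
    df = _to_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    surv = kmf.survival_function_["KM_estimate"]
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d))) over event times
    et = kmf.event_table
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = et["observed"] / (et["at_risk"] * (et["at_risk"] - et["observed"]))
    incr = incr.replace([np.inf, -np.inf], 0.0).fillna(0.0)
    var = incr.cumsum().reindex(surv.index).fillna(0.0) * surv**2
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = math.nan
    return KMEstimate(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        variance=np.asarray(var, dtype=float),
        median=median,
    )


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float
    mode: str = "all_groups"
    extreme_pair: Optional[tuple[str, str]] = None


def logrank_test(
    groups: dict[str, Sequence[SurvivalRecord]], extreme_pair: bool = False
) -> LogrankResult:
    """Log-rank test over labelled groups.

    With more than two groups and ``extreme_pair=True``, the groups with the
    best and worst median survival are compared pairwise (the convention
    used for multi-curve Kaplan–Meier figures); otherwise the joint
    (k-1 df) statistic is returned.
    """
    groups = {k: list(v) for k, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    if extreme_pair and len(groups) > 2:
        med = {}
        for name, recs in groups.items():
            kmf = KaplanMeierFitter().fit(
                [r.time for r in recs], [r.event for r in recs]
            )
            m = float(kmf.median_survival_time_)
            med[name] = math.inf if math.isinf(m) else m
        lo = min(med, key=lambda n: (med[n], n))
        hi = max(med, key=lambda n: (med[n], n))
        sub = {lo: groups[lo], hi: groups[hi]}
        res = logrank_test(sub)
        return LogrankResult(res.chi2, 1, res.p, mode="extreme_pair",
                             extreme_pair=(lo, hi))
    if len(groups) == 2:
        (na, ra), (nb, rb) = groups.items()
        r = _ll_logrank(
            [x.time for x in ra], [x.time for x in rb],
            event_observed_A=[x.event for x in ra],
            event_observed_B=[x.event for x in rb],
        )
        return LogrankResult(float(r.test_statistic), 1, float(r.p_value))
    times, events, labels = [], [], []
    for name, recs in groups.items():
        for x in recs:
            times.append(x.time)
            events.append(x.event)
            labels.append(name)
    r = multivariate_logrank_test(times, labels, events)
    return LogrankResult(float(r.test_statistic), len(groups) - 1, float(r.p_value))


@dataclass
class CoxResult:
    feature: str
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float
    fdr: float = math.nan
    reason: Optional[str] = None


def cox_univariate(
    feature: Sequence[int | float],
    records: Sequence[SurvivalRecord],
    feature_name: str = "",
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling, Wald p).

    Monotone-likelihood / non-convergent fits (e.g. zero events in one arm)
    are returned as NA with a reason rather than raised.
    """
    x = np.asarray(feature, dtype=float)
    if len(x) != len(records):
        raise ValueError("feature vector and records differ in length")
    df = _to_frame(records)
    df["x"] = x
    events_present = df.loc[df["event"] == 1, "x"]
    if x.min() == x.max():
        return CoxResult(feature_name, math.nan, (math.nan, math.nan), math.nan,
                         reason="constant feature")
    if df["event"].sum() == 0:
        return CoxResult(feature_name, math.nan, (math.nan, math.nan), math.nan,
                         reason="no events")
    if events_present.nunique() < 2 and set(np.unique(x)) == {0.0, 1.0}:
        return CoxResult(feature_name, math.nan, (math.nan, math.nan), math.nan,
                         reason="monotone likelihood (events in one arm only)")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["time", "event", "x"]], duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxResult(feature_name, math.nan, (math.nan, math.nan), math.nan,
                         reason="non-convergence")
    s = cph.summary.loc["x"]
    return CoxResult(
        feature_name,
        float(s["exp(coef)"]),
        (float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
        float(s["p"]),
    )


def cox_table(matrix: pd.DataFrame, records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Univariate Cox per feature column with BH-FDR across the table
    (one FDR family per endpoint table)."""
    results = [cox_univariate(matrix[c], records, feature_name=str(c)) for c in matrix.columns]
    testable = [r for r in results if not math.isnan(r.p)]
    if testable:
        q = bh_fdr([r.p for r in testable])
        for r, qq in zip(testable, q):
            r.fdr = float(qq)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "hazard_ratio": [r.hazard_ratio for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "reason": [r.reason for r in results],
        }
    )
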