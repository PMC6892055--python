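"""Cohort statistics and search-strategy classification.

Per-individual Δ metrics (experiment minus acclimation) are tested against
zero with paired t-tests; treatment-vs-control comparisons (discovery time,
activity) use two-sample Welch tests.  Raw p-values within the six-metric
family are adjusted by Holm step-down, and the resulting significance
pattern is matched against the four canonical search-strategy models:

====================  ==  ===  ===  ==  ====  ====
strategy              ΔP  ΔDP  ΔDS  ΔCS ΔDTI  ΔCTI
====================  ==  ===  ===  ==  ====  ====
anosmic               .   .    .    .   .     .
chemotaxis            *   *    .    .   *     .
klinokinesis          *   .    .    .   .     *
chemokinesis          *   .    .    *   .     .
====================  ==  ===  ===  ==  ====  ====

A pattern that matches no strategy exactly is assigned to the nearest one
by Hamming distance, with ties broken in fewest-assumptions-first order
(anosmic < chemokinesis < klinokinesis < chemotaxis).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ClassificationError, InsufficientDataError, ValidationError
from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTestResult", "StrategyCall", "STRATEGY_PATTERNS", "STRATEGY_ORDER",
    "welch_paired", "welch_two_sample", "adjust_p", "cohort_tests",
    "classify_strategy", "results_table", "write_results",
]

#: expected significance patterns in METRIC_NAMES order (P, DP, DS, CS, DTI, CTI)
STRATEGY_PATTERNS = {
    "anosmic":      (0, 0, 0, 0, 0, 0),
    "chemotaxis":   (1, 1, 0, 0, 1, 0),
    "klinokinesis": (1, 0, 0, 0, 0, 1),
    "chemokinesis": (1, 0, 0, 1, 0, 0),
}

#: deterministic tie-break preference: fewest behavioural assumptions first
STRATEGY_ORDER = ("anosmic", "chemokinesis", "klinokinesis", "chemotaxis")


@dataclass
class CohortTestResult:
    metric: str
    n: int
    t: float
    df: float
    p_raw: float
    p_adj: float = np.nan
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self):
        p = self.p_adj if np.isfinite(self.p_adj) else self.p_raw
        return bool(p < self.alpha)


def _drop_nan_pairs(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def welch_paired(values_a, values_b, alpha=0.05, metric="") -> CohortTestResult:
    """Paired t-test of per-individual differences (b - a) against zero.

    Pairs with a missing value on either side are dropped.  With a single
    difference sample the Welch-Satterthwaite correction reduces to the
    ordinary paired test, df = n - 1.  Zero-variance differences are flagged
    as degenerate: p = 1 when the mean difference is also zero, else p = 0.
    """
    a, b = _drop_nan_pairs(values_a, values_b)
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"paired test needs n >= 2, got {n}")
    d = b - a
    if np.var(d, ddof=1) == 0.0:
        equal = d.mean() == 0.0
        logger.warning("welch_paired(%s): zero-variance differences (degenerate), p=%s",
                       metric or "?", 1.0 if equal else 0.0)
        return CohortTestResult(metric=metric, n=n, t=0.0 if equal else np.inf,
                                df=n - 1, p_raw=1.0 if equal else 0.0,
                                alpha=alpha, degenerate=True)
    res = sps.ttest_1samp(d, 0.0)
    return CohortTestResult(metric=metric, n=n, t=float(res.statistic),
                            df=float(n - 1), p_raw=float(res.pvalue), alpha=alpha)


def welch_two_sample(group_a, group_b, alpha=0.05, metric="") -> CohortTestResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Welch test needs n >= 2 in each group")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        equal = a.mean() == b.mean()
        logger.warning("welch_two_sample(%s): zero variance in both samples", metric or "?")
        return CohortTestResult(metric=metric, n=a.size + b.size,
                                t=0.0 if equal else np.inf, df=a.size + b.size - 2,
                                p_raw=1.0 if equal else 0.0, alpha=alpha,
                                degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return CohortTestResult(metric=metric, n=a.size + b.size, t=float(res.statistic),
                            df=float(res.df), p_raw=float(res.pvalue), alpha=alpha)


def adjust_p(p_values, method="holm"):
    """Multiplicity adjustment; Holm step-down by default, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in ("holm", "bonferroni"):
        raise ValidationError(f"unknown adjustment method '{method}'")
    return multipletests(p, method=method)[1]


def cohort_tests(metric_frame: pd.DataFrame, alpha=0.05, method="holm",
                 control_frame: pd.DataFrame | None = None):
    """Paired tests of all six Δ metrics for one stimulus cohort.

    Parameters
    ----------
    metric_frame : output of :func:`larvanav.metrics.metrics_frame`
    alpha : significance level after adjustment
    method : multiplicity adjustment within the six-metric family
    control_frame : optional control cohort; if given, experiment-phase
        discovery times (censored values entered at the censoring bound) are
        compared treatment vs control with a two-sample Welch test, reported
        under "D".  Discovery time has no within-individual pairing and never
        enters the six-flag strategy pattern.

    Returns an ordered dict ``{metric: CohortTestResult}``; metrics with
    fewer than 2 complete pairs are flagged as undefined (NaN p) and
    excluded from the adjustment family and the pattern.
    """
    results: dict[str, CohortTestResult] = {}
    for name in METRIC_NAMES:
        a = metric_frame[f"{name}_acc"].to_numpy(float)
        b = metric_frame[f"{name}_exp"].to_numpy(float)
        try:
            results[name] = welch_paired(a, b, alpha=alpha, metric=name)
        except InsufficientDataError:
            logger.warning("cohort_tests: metric %s undefined (insufficient data)", name)
            results[name] = CohortTestResult(metric=name, n=0, t=np.nan, df=np.nan,
                                             p_raw=np.nan, alpha=alpha)
    testable = [m for m in METRIC_NAMES if np.isfinite(results[m].p_raw)]
    if testable:
        adj = adjust_p([results[m].p_raw for m in testable], method=method)
        for m, p in zip(testable, adj):
            results[m].p_adj = float(p)

    if control_frame is not None:
        d_treat = metric_frame["D_exp"].to_numpy(float)
        d_ctrl = control_frame["D_exp"].to_numpy(float)
        n_cens = int(metric_frame["D_censored_exp"].sum() + control_frame["D_censored_exp"].sum())
        if n_cens:
            logger.info("cohort_tests: %d censored discovery times entered at the bound", n_cens)
        res = welch_two_sample(d_treat, d_ctrl, alpha=alpha, metric="D")
        res.p_adj = res.p_raw
        results["D"] = res
    return results


@dataclass
class StrategyCall:
    observed: tuple
    call: str
    match: str            # "exact" or "nearest"
    distance: int
    alpha: float = 0.05
    per_metric: dict = dc_field(default_factory=dict)

    def summary(self):
        pat = "".join(str(int(f)) for f in self.observed)
        return (f"pattern {pat} ({'/'.join(METRIC_NAMES)}) -> {self.call} "
                f"[{self.match}, Hamming distance {self.distance}]")

    def to_dict(self):
        return {
            "observed": [int(f) for f in self.observed],
            "metrics": list(METRIC_NAMES),
            "call": self.call, "match": self.match,
            "distance": int(self.distance), "alpha": self.alpha,
            "per_metric": self.per_metric,
        }


def classify_strategy(results) -> StrategyCall:
    """Map a six-metric significance pattern to the nearest canonical strategy.

    ``results`` is either the dict returned by :func:`cohort_tests` or a
    sequence of six significance flags in METRIC_NAMES order.
    """
    per_metric = {}
    if isinstance(results, dict):
        missing = [m for m in METRIC_NAMES
                   if m not in results or not np.isfinite(results[m].p_raw)]
        if missing:
            raise ClassificationError(f"cannot classify: undefined metrics {missing}")
        flags = tuple(int(results[m].significant) for m in METRIC_NAMES)
        per_metric = {m: {"p_raw": results[m].p_raw, "p_adj": results[m].p_adj,
                          "significant": results[m].significant} for m in METRIC_NAMES}
        alpha = results[METRIC_NAMES[0]].alpha
    else:
        flags = tuple(int(bool(f)) for f in results)
        if len(flags) != len(METRIC_NAMES):
            raise ClassificationError(f"expected {len(METRIC_NAMES)} flags, got {len(flags)}")
        alpha = np.nan

    distances = {s: sum(f != e for f, e in zip(flags, STRATEGY_PATTERNS[s]))
                 for s in STRATEGY_ORDER}
    best = min(STRATEGY_ORDER, key=lambda s: (distances[s], STRATEGY_ORDER.index(s)))
    dist = distances[best]
    return StrategyCall(observed=flags, call=best,
                        match="exact" if dist == 0 else "nearest",
                        distance=dist, alpha=alpha, per_metric=per_metric)


def results_table(results) -> pd.DataFrame:
    """One row per metric: t, df, p_raw, p_adj, n, significance flag."""
    rows = []
    for name, r in results.items():
        rows.append({"metric": name, "n": r.n, "t": r.t, "df": r.df,
                     "p_raw": r.p_raw, "p_adj": r.p_adj,
                     "significant": r.significant if np.isfinite(r.p_raw) else None,
                     "degenerate": r.degenerate})
    return pd.DataFrame(rows)


def write_results(results, call: StrategyCall | None, csv_path, json_path=None):
    """Write the per-metric table (CSV) and the classifier verdict (JSON)."""
    results_table(results).to_csv(csv_path, index=False)
    if call is not None and json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(call.to_dict(), fh, indent=2)
    return csv_path
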