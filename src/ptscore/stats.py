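"""Univariate association battery: Fisher, Mann-Whitney, KM, log-rank.

All tests are two-sided and uncorrected for multiplicity (the selection
procedure screens features at raw p < 0.05 on both a group-difference
test and a survival test; see :func:`select_candidates`).  Fisher's
exact test uses the minimum-likelihood two-sided convention (sum of
hypergeometric point probabilities no larger than the observed table's),
which is what mainstream statistical software prints.

The survival-curve hazard ratio defaults to the observed/expected ratio
(O1/E1)/(O2/E2) from the log-rank risk-set table, with a standard
log-scale CI (var log HR ~= 1/E1 + 1/E2).  A single-covariate
proportional-hazards fit is available behind ``hr_method="cox"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_exact_two_sided",
    "mann_whitney_two_sided",
    "km_estimate",
    "logrank_test",
    "dichotomize_by_median",
    "select_candidates",
]


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    test: str
    statistic: float
    p_value: float
    effect: float | None = None  # odds ratio or hazard ratio
    ci_low: float | None = None
    ci_high: float | None = None


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    ``table`` is ((a, b), (c, d)) with rows = feature present/absent and
    columns = sensitive/resistant (any orientation; the p-value is
    invariant to transposition).  The reported effect is the sample odds
    ratio ad/bc (inf/nan for zero cells).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    res = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        test="fisher_exact", statistic=float(res.statistic), p_value=float(res.pvalue),
        effect=float(res.statistic),
    )


def mann_whitney_two_sided(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Exact enumeration of the permutation null when n + m <= ``exact_max_n``
    and the pooled data are tie-free; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        test="mann_whitney", statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step-function table with columns ``time`` and ``survival``
    (starting at S(0) = 1, non-increasing, right-censoring handled).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def _oe_table(time, event, group_mask):
    """Observed and expected event counts per group over shared risk sets."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(group_mask, dtype=bool)
    O = np.zeros(2)
    E = np.zeros(2)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        O[0] += d1
        O[1] += d - d1
        E[0] += d * n1 / n
        E[1] += d * (n - n1) / n
    return O, E


def logrank_test(time, event, group, hr_method: str = "oe") -> TestResult:
    """Two-group log-rank test with a hazard-ratio estimate.

    ``group`` is a binary/boolean vector; the hazard ratio is reported
    for group==1 relative to group==0.  ``hr_method`` selects the O/E
    ratio ("oe", default) or a single-covariate Cox fit ("cox").
    Requires two non-empty groups and at least one event.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g = np.asarray(group).astype(bool)
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    if event.sum() == 0:
        raise ValueError("no events observed")
    res = _ll_logrank(time[g], time[~g], event_observed_A=event[g], event_observed_B=event[~g])
    if hr_method == "cox":
        df = pd.DataFrame({"time": time, "event": event, "group": g.astype(int)})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["group"]))
        lo, hi = np.exp(cph.confidence_intervals_.loc["group"]).to_numpy()
    else:
        O, E = _oe_table(time, event, g)
        if E[0] > 0 and E[1] > 0 and O[0] > 0 and O[1] > 0:
            hr = (O[0] / E[0]) / (O[1] / E[1])
            se = np.sqrt(1.0 / E[0] + 1.0 / E[1])
            lo, hi = hr * np.exp(-1.96 * se), hr * np.exp(1.96 * se)
        else:
            hr = lo = hi = float("nan")
    return TestResult(
        test="logrank", statistic=float(res.test_statistic),
        p_value=float(res.p_value), effect=hr, ci_low=float(lo), ci_high=float(hi),
    )


def dichotomize_by_median(values) -> np.ndarray:
    """Label values "high" when strictly above the cohort median, else "low"."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty input")
    med = np.median(v)
    return np.where(v > med, "high", "low")


def _is_binary(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def select_candidates(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha_assoc: float = 0.05,
    alpha_survival: float = 0.05,
) -> pd.DataFrame:
    """Screen features for the integration model.

    A feature is a candidate iff (1) it differs between platinum-
    sensitive and resistant patients (Fisher for binary features,
    Mann-Whitney for continuous ones) at ``alpha_assoc``, and (2) its
    groups (the feature itself when binary, median-dichotomised
    otherwise) separate OS or DFS by log-rank at ``alpha_survival``.

    ``clinical`` must carry ``pt_sensitive`` plus ``os_months``,
    ``os_event``, ``dfs_months``, ``dfs_event`` and share its index (or a
    ``sample`` column) with ``features``.
    """
    if "sample" in clinical.columns:
        clinical = clinical.set_index("sample")
    if "sample" in features.columns:
        features = features.set_index("sample")
    common = features.index.intersection(clinical.index)
    features = features.loc[common]
    clinical = clinical.loc[common]
    y = clinical["pt_sensitive"].astype(int).to_numpy()
    rows = []
    for name in features.columns:
        col = features[name]
        if _is_binary(col):
            f = col.astype(int).to_numpy()
            tab = [
                [int(((f == 1) & (y == 1)).sum()), int(((f == 1) & (y == 0)).sum())],
                [int(((f == 0) & (y == 1)).sum()), int(((f == 0) & (y == 0)).sum())],
            ]
            try:
                assoc = fisher_exact_two_sided(tab)
            except ValueError:
                continue
            groups = f.astype(bool)
            kind = "binary"
        else:
            v = col.to_numpy(dtype=float)
            if len(np.unique(v)) < 2 or y.sum() in (0, len(y)):
                continue
            assoc = mann_whitney_two_sided(v[y == 1], v[y == 0])
            groups = dichotomize_by_median(v) == "high"
            kind = "continuous"
        surv_p = {}
        for prefix in ("os", "dfs"):
            try:
                r = logrank_test(
                    clinical[f"{prefix}_months"], clinical[f"{prefix}_event"], groups
                )
                surv_p[prefix] = r.p_value
            except (ValueError, KeyError):
                surv_p[prefix] = np.nan
        best_surv = np.nanmin([surv_p["os"], surv_p["dfs"]]) if surv_p else np.nan
        rows.append(
            {
                "feature": name,
                "kind": kind,
                "assoc_test": assoc.test,
                "assoc_p": assoc.p_value,
                "os_logrank_p": surv_p.get("os", np.nan),
                "dfs_logrank_p": surv_p.get("dfs", np.nan),
                "candidate": bool(
                    assoc.p_value < alpha_assoc
                    and np.isfinite(best_surv)
                    and best_surv < alpha_survival
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature", "kind", "assoc_test", "assoc_p",
            "os_logrank_p", "dfs_logrank_p", "candidate",
        ],
    )
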