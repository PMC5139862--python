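"""Group summaries, Kaplan-Meier curves and the two-sample log-rank test.

The survival machinery is implemented from first principles (product-limit
estimator, hypergeometric expected deaths) so its arithmetic is fully
auditable; established survival packages serve only as cross-check oracles
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

GROUPS = ("low", "high")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching conventional printed percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, denom: int) -> float:
    return round_half_up(100.0 * count / denom, 1)


@dataclass(frozen=True)
class GroupStats:
    n: int
    deaths: int
    death_pct: float
    group_pct: float


@dataclass(frozen=True)
class ContingencySummary:
    """Group-by-outcome 2x2 summary of a dichotomized cohort.

    Percentages are always re-derived from the integer counts with half-up
    rounding to one decimal, so printing and computation cannot diverge.
    """

    n_total: int
    groups: dict[str, GroupStats]
    rejected_ids: tuple[str, ...] = ()


def summarize_groups(cohort: pd.DataFrame) -> ContingencySummary:
    """Count cases and deaths per MVD group.

    Records with a missing ``mvd_group`` are listed in ``rejected_ids`` and
    excluded from every denominator.
    """
    if len(cohort) == 0:
        raise DomainError("cohort is empty")
    grp = cohort["mvd_group"]
    missing = grp.isna() | (grp.astype(object) == "")
    rejected = tuple(str(pid) for pid in cohort.loc[missing, "patient_id"])
    scored = cohort.loc[~missing]
    if len(scored) == 0:
        raise DomainError("no record has an mvd_group label")
    bad = set(scored["mvd_group"]) - set(GROUPS)
    if bad:
        raise DomainError(f"unknown mvd_group labels: {sorted(bad)}")

    n_total = len(scored)
    groups = {}
    for g in GROUPS:
        sub = scored[scored["mvd_group"] == g]
        n = len(sub)
        deaths = int(sub["death_event"].astype(bool).sum())
        groups[g] = GroupStats(
            n=n,
            deaths=deaths,
            death_pct=_pct(deaths, n) if n else 0.0,
            group_pct=_pct(n, n_total),
        )
    return ContingencySummary(n_total=n_total, groups=groups, rejected_ids=rejected)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct death times in increasing order;
    ``survival[i]`` is S(t) just after ``event_times[i]``; ``at_risk`` and
    ``deaths`` are the risk-set size and death count at each event time.
    S(0) = 1 by construction.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t): the step function evaluated at time t (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def greenwood_variance(self) -> np.ndarray:
        """Greenwood's variance estimate of S at each event time."""
        d, n = self.deaths.astype(float), self.at_risk.astype(float)
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
        return self.survival**2 * np.cumsum(terms)


def km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimator with deaths-before-censoring at tied times.

    A subject censored at time t is still in the risk set for deaths at t
    (the standard convention); it leaves the risk set afterwards.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise DomainError("at least one subject is required")
    if (times < 0).any():
        raise DomainError("negative follow-up times")

    death_times = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in death_times], dtype=int)
    deaths = np.array([((times == t) & events).sum() for t in death_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - deaths / at_risk) if len(death_times) else np.array([])
    return KMCurve(
        event_times=death_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=at_risk,
        deaths=deaths,
        n_subjects=int(times.size),
    )


@dataclass(frozen=True)
class LogRankResult:
    """Two-sample log-rank test (chi-square with 1 df)."""

    statistic: float
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    permutation_p: float | None = None


def _logrank_statistic(
    times: np.ndarray, events: np.ndarray, in_a: np.ndarray
) -> tuple[float, float, float]:
    """(sum(O_a - E_a), sum(V), O_a) over the pooled distinct death times."""
    death_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    obs_a = 0.0
    for t in death_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        na = int((at_risk & in_a).sum())
        d = int(((times == t) & events).sum())
        da = int(((times == t) & events & in_a).sum())
        obs_a += da
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (1.0 - na / n) * (n - d) / (n - 1)
    return o_minus_e, var, obs_a


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
    permutations: int | None = None,
    seed: int | None = None,
) -> LogRankResult:
    """Standard two-sample log-rank test.

    At each distinct death time the expected deaths in group A come from
    the hypergeometric mean ``d * n_a / n`` with the matching variance; the
    statistic is ``(sum O-E)^2 / sum V`` referred to chi-square(1).  With
    zero total deaths (or zero variance) the test carries no information
    and returns statistic 0, p = 1.  ``permutations`` adds a permutation
    p-value from seeded group-label reshuffles as a robustness alternative.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if times_a.size == 0 or times_b.size == 0:
        raise DomainError("both groups must be non-empty")
    if (times_a < 0).any() or (times_b < 0).any():
        raise DomainError("negative follow-up times")

    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: times_a.size] = True

    o_minus_e, var, obs_a = _logrank_statistic(times, events, in_a)
    total_deaths = float(events.sum())
    if total_deaths == 0 or var == 0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e**2 / var
        p = float(stats.chi2.sf(stat, df=1))
    exp_a = obs_a - o_minus_e

    perm_p = None
    if permutations:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(in_a)
            ome, v, _ = _logrank_statistic(times, events, perm)
            s = ome**2 / v if v > 0 else 0.0
            if s >= stat - 1e-12:
                hits += 1
        perm_p = (hits + 1) / (permutations + 1)

    return LogRankResult(
        statistic=float(stat),
        p_value=p,
        observed={"a": obs_a, "b": total_deaths - obs_a},
        expected={"a": exp_a, "b": total_deaths - exp_a},
        permutation_p=perm_p,
    )


def cohort_descriptives(cohort: pd.DataFrame) -> dict:
    """Demographic and clinicopathological summary, recomputed from records."""
    if len(cohort) == 0:
        raise DomainError("cohort is empty")
    n = len(cohort)

    def cat_pct(col: str) -> dict[str, float]:
        counts = cohort[col].value_counts()
        return {str(k): _pct(int(v), n) for k, v in counts.items()}

    return {
        "n": n,
        "age_mean": float(cohort["age_years"].mean()),
        "age_sd": float(cohort["age_years"].std(ddof=1)) if n > 1 else 0.0,
        "sex_counts": {
            s: int((cohort["sex"] == s).sum()) for s in ("M", "F")
        },
        "site_pct": cat_pct("site"),
        "histology_pct": cat_pct("histology"),
        "risk_category_pct": cat_pct("risk_category"),
        "metastasis_pct": _pct(int(cohort["metastasis"].astype(bool).sum()), n),
        "followup_mean": float(cohort["followup_years"].mean()),
        "followup_median": float(cohort["followup_years"].median()),
    }
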