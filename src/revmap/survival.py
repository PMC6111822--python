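"""Median-split stratification and Kaplan-Meier survival analysis.

A prognostic gene is screened by dichotomizing patients at its median
expression and comparing the survival of the two groups: the product-limit
(Kaplan-Meier) curve with Greenwood variance, the restricted mean survival
time (RMST — the area under the curve up to a truncation time tau, the
quantity reported as "mean survival time" with a confidence interval), and
the two-group log-rank test.

"Mean survival" is deliberately the KM-based restricted mean to the largest
observed time by default: the unrestricted mean is undefined when the
largest time is censored, and the restricted mean with a normal CI is what
standard clinical-statistics software prints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as sps

from .datatypes import ExpressionCohort
from .errors import EstimationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedCohort",
    "KMEstimate",
    "median_split",
    "km_estimate",
    "mean_survival_ci",
    "logrank_test",
    "survival_report",
]


@dataclass
class StratifiedCohort:
    """Per-sample high/low labels from a median split."""

    labels: pd.Series  # values "high"/"low", index = sample ids
    cut_value: float
    gene: str

    def samples(self, group: str) -> pd.Index:
        return self.labels.index[self.labels == group]


def median_split(cohort: ExpressionCohort, gene: str) -> StratifiedCohort:
    """Dichotomize samples at the median expression of `gene`.

    Samples strictly above the median are labelled "high"; samples at or
    below it "low" (so ties at the median go to the low group).
    """
    expr = cohort.expression(gene)
    cut = float(expr.median())
    labels = pd.Series(
        np.where(expr.to_numpy() > cut, "high", "low"), index=expr.index
    )
    if (labels == "high").sum() == 0:
        logger.warning(
            "gene %s: no sample above the median (constant expression?); "
            "all samples labelled 'low'", gene,
        )
    return StratifiedCohort(labels=labels, cut_value=cut, gene=gene)


@dataclass
class KMEstimate:
    """Product-limit survival estimate with restricted-mean summary.

    ``survival[i]`` is S(t) just after ``event_times[i]``; the curve is 1
    before the first event.  ``greenwood_var[i]`` is the Greenwood variance
    of S at that step.  ``rmst`` is the exact area under the step function
    from 0 to ``tau``.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    rmst: float
    rmst_se: float
    tau: float
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): the estimated probability of surviving beyond t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
            }
        )


def km_estimate(
    times: Sequence[float], events: Sequence[int], tau: float | None = None
) -> KMEstimate:
    """Kaplan-Meier estimate with Greenwood variance and RMST.

    Parameters
    ----------
    times : survival/censoring times in months, all > 0
    events : 1 for an observed death, 0 for right censoring
    tau : RMST truncation time; defaults to the largest observed time
        (event or censored)

    The RMST is the exact rectangle-sum integral of the step function up
    to tau; its standard error uses the standard restricted-mean variance

        var(RMST) = sum_i A_i^2 * d_i / (n_i (n_i - d_i)),

    where A_i is the area under S from event time t_i to tau.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1 or len(t) == 0:
        raise InputError("times and events must be equal-length 1-d sequences")
    if (t <= 0).any():
        raise InputError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise InputError("events must be 0/1")
    if e.sum() == 0:
        raise EstimationError("no events observed; survival curve undefined")

    t_max = float(t.max())
    if tau is None:
        tau = t_max
    if tau <= 0:
        raise InputError("tau must be positive")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n_total = len(t)

    death_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= ti).sum() for ti in death_times], dtype=np.int64)
    deaths = np.array([((t == ti) & (e == 1)).sum() for ti in death_times],
                      dtype=np.int64)

    surv = np.cumprod(1.0 - deaths / at_risk)
    # Greenwood: var S(t) = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i));
    # the final term is infinite when everyone at risk dies — propagate inf.
    with np.errstate(divide="ignore"):
        increments = np.where(
            at_risk > deaths,
            deaths / (at_risk * (at_risk - deaths).astype(float)),
            np.inf,
        )
    with np.errstate(invalid="ignore"):
        gw = surv**2 * np.cumsum(increments)
    gw = np.where(surv == 0.0, 0.0, gw)  # S=0 pins the variance to 0

    # RMST: rectangles between successive event times, clipped at tau
    knots = np.concatenate(([0.0], death_times, [max(tau, death_times[-1])]))
    heights = np.concatenate(([1.0], surv))
    widths = np.clip(np.minimum(knots[1:], tau) - np.minimum(knots[:-1], tau), 0, None)
    rmst = float(np.sum(widths * heights))

    # area under S from each event time to tau
    rev_area = np.concatenate((np.cumsum((widths * heights)[::-1])[::-1], [0.0]))
    A = rev_area[1:len(death_times) + 1]
    in_window = death_times <= tau
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            at_risk > deaths,
            deaths / (at_risk * (at_risk - deaths).astype(float)),
            0.0,
        )
    rmst_var = float(np.sum((A[in_window] ** 2) * terms[in_window]))
    return KMEstimate(
        event_times=death_times,
        at_risk=at_risk,
        deaths=deaths,
        survival=surv,
        greenwood_var=gw,
        rmst=rmst,
        rmst_se=float(np.sqrt(rmst_var)),
        tau=float(tau),
        n=n_total,
    )


def mean_survival_ci(
    est: KMEstimate, level: float = 0.95
) -> Tuple[float, float, float]:
    """Restricted mean survival with a symmetric normal CI, in months."""
    if not 0.0 < level < 1.0:
        raise InputError(f"confidence level must lie in (0, 1), got {level}")
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * est.rmst_se
    return est.rmst, est.rmst - half, est.rmst + half


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[int],
    times_b: Sequence[float], events_b: Sequence[int],
) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise InputError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise InputError("at least one event is required across the groups")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def survival_report(
    cohort: ExpressionCohort,
    gene: str,
    tau: float | None = None,
    level: float = 0.95,
) -> dict:
    """Full median-split survival comparison for one gene.

    Returns a JSON-serializable report: per-group sample size, restricted
    mean survival with CI, and the log-rank p-value.  A shared tau (the
    largest observed time overall, unless given) keeps the two groups'
    restricted means comparable.
    """
    strat = median_split(cohort, gene)
    clin = cohort.clinical
    if tau is None:
        tau = float(clin["time_months"].max())
    report: dict = {"gene": gene, "cut_value": strat.cut_value, "tau": tau}
    groups = {}
    for grp in ("high", "low"):
        ids = strat.samples(grp)
        sub = clin.loc[ids]
        est = km_estimate(sub["time_months"], sub["event"], tau=tau)
        mean, lo, hi = mean_survival_ci(est, level)
        groups[grp] = {
            "n": int(len(ids)),
            "events": int(sub["event"].sum()),
            "mean_months": mean,
            "ci_lo": lo,
            "ci_hi": hi,
        }
    hi_ids, lo_ids = strat.samples("high"), strat.samples("low")
    chi2, p = logrank_test(
        clin.loc[hi_ids, "time_months"], clin.loc[hi_ids, "event"],
        clin.loc[lo_ids, "time_months"], clin.loc[lo_ids, "event"],
    )
    report["groups"] = groups
    report["logrank_chi2"] = chi2
    report["logrank_p"] = p
    return report
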