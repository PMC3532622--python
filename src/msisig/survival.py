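"""Survival and expression analyses of classifier strata.

The prognostic endpoint is distant-metastasis-free survival censored
administratively at a 10-year horizon.  Kaplan-Meier estimation, the
log-rank test and the Cox proportional-hazards model come from lifelines
(Efron tie handling); this module provides the stratum bookkeeping, horizon
censoring, and the thymidylate synthase (TYMS) expression comparison across
signature classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ValidationError
from .io_formats import MSI, MSI_LIKE, MSS, ExpressionMatrix

__all__ = ["apply_horizon", "km_curve", "logrank_test", "cox_hr", "CoxResult", "tyms_comparison"]

DEFAULT_HORIZON_YEARS = 10.0


def apply_horizon(times, events, horizon: float = DEFAULT_HORIZON_YEARS):
    """Administrative censoring: times capped at the horizon, later events censored."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValidationError("survival times must be nonnegative")
    capped = np.minimum(times, horizon)
    ev = np.where(times > horizon, 0, events)
    return capped, ev


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame with one row per distinct event/censoring time: ``time``,
    ``survival`` (non-increasing, starting from 1) and ``at_risk``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("empty stratum")
    if (times < 0).any():
        raise ValidationError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({"time": surv.index.to_numpy(), "survival": surv.to_numpy(), "at_risk": at_risk.to_numpy()})


def logrank_test(times, events, groups):
    """Log-rank test across >= 2 strata; returns (chi2, p, df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValidationError("log-rank test needs >= 2 strata")
    if events.sum() == 0:
        raise ValidationError("log-rank test undefined with no events")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value), int(res.degrees_of_freedom)


@dataclass
class CoxResult:
    """Hazard ratio for signature-positive vs MSS with Wald CI and p."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    warning: str | None = None


def cox_hr(times, events, positive, horizon: float = DEFAULT_HORIZON_YEARS) -> CoxResult:
    """Univariable Cox PH model of a binary signature status.

    ``positive`` is 1 for signature-positive (MSI or MSI-like) samples.
    Times are administratively censored at ``horizon``.  When one group has
    no events the partial likelihood is monotone and the Wald CI unbounded;
    the estimate is still reported, with a warning recorded.
    """
    times, events = apply_horizon(times, events, horizon)
    positive = np.asarray(positive, dtype=int)
    if not ((positive == 1).any() and (positive == 0).any()):
        raise ValidationError("both signature groups must be present")
    df = pd.DataFrame({"time": times, "event": events, "positive": positive})
    warning = None
    ev_pos = int(df.loc[df.positive == 1, "event"].sum())
    ev_neg = int(df.loc[df.positive == 0, "event"].sum())
    if ev_pos == 0 or ev_neg == 0:
        warning = "a group has zero events; HR estimate is degenerate and the CI unbounded"
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["positive"]
    with np.errstate(over="ignore"):  # unbounded CI when a group has no events
        ci_low, ci_high = np.exp(s["coef lower 95%"]), np.exp(s["coef upper 95%"])
    return CoxResult(
        hr=float(np.exp(s["coef"])),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(s["p"]),
        n=len(df),
        n_events=int(events.sum()),
        warning=warning,
    )


def tyms_comparison(matrix: ExpressionMatrix, calls, gene: str = "TYMS") -> dict:
    """TYMS expression by signature class, with t-tests vs the MSS group.

    ``calls`` are three-way signature calls aligned to the matrix samples.
    Returns group means and two-sided Student t p-values for MSI vs MSS and
    MSI-like vs MSS.
    """
    if gene not in matrix.gene_ids:
        raise ValidationError(f"gene {gene!r} absent from matrix")
    calls = np.asarray(calls)
    if calls.shape != (matrix.n_samples,):
        raise ValidationError("calls must align with matrix samples")
    expr = matrix.values[:, matrix.gene_ids.index(gene)]
    out: dict = {"gene": gene, "means": {}}
    for cls in (MSS, MSI_LIKE, MSI):
        vals = expr[calls == cls]
        out["means"][cls] = float(vals.mean()) if len(vals) else float("nan")
    mss_vals = expr[calls == MSS]
    for cls, key in [(MSI, "p_msi_vs_mss"), (MSI_LIKE, "p_msi_like_vs_mss")]:
        vals = expr[calls == cls]
        if len(vals) >= 2 and len(mss_vals) >= 2:
            if np.array_equal(np.sort(vals), np.sort(mss_vals)):
                out[key] = 1.0
            else:
                out[key] = float(stats.ttest_ind(vals, mss_vals, equal_var=True).pvalue)
        else:
            out[key] = float("nan")
    return out
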