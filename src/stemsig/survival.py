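"""Kaplan-Meier / log-rank comparisons and multivariate Cox modeling.

The central use case: a cohort is dichotomized on a signature score for a
Kaplan-Meier comparison, and the stemness and stromal signature levels enter
a two-covariate Cox proportional-hazards model together, so the hazard of
each is adjusted for the other. Covariates are z-scored by default, making
hazard ratios per-SD and the fit invariant to affine rescaling of the scores
(hence to the ssGSEA normalization choice).

Fitting is delegated to lifelines (Efron tie handling, Newton-Raphson
partial-likelihood maximization); this module owns the contracts: input
validation, deterministic dichotomization, per-SD standardization, and
skip-with-reason semantics for multi-cohort tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .io import CohortClinical
from .ssgsea import ScoreMatrix

__all__ = [
    "dichotomize",
    "km_logrank",
    "cox_fit",
    "pan_cohort_cox",
    "CoxFit",
    "KmResult",
    "survival_frame",
]

logger = logging.getLogger(__name__)


def survival_frame(
    clinical: CohortClinical, covariates: Mapping[str, pd.Series] | None = None
) -> pd.DataFrame:
    """Assemble a (time, event, covariate...) frame aligned on sample id."""
    if clinical.time_col is None or clinical.event_col is None:
        raise ValueError("clinical table lacks survival time/event columns")
    df = pd.DataFrame(
        {
            "time": pd.to_numeric(clinical.table[clinical.time_col]),
            "event": clinical.table[clinical.event_col].astype(int),
        }
    )
    for name, series in (covariates or {}).items():
        df[name] = series.reindex(df.index)
    df = df.dropna()
    if not len(df):
        raise ValueError("no samples with complete survival records")
    return df


def dichotomize(scores: pd.Series, rule: str = "median", q: float = 0.5) -> tuple[pd.Series, float]:
    """Split scores into ``high`` (> cutoff) and ``low`` (<= cutoff) groups.

    ``rule='median'`` uses the median; ``rule='quantile'`` uses quantile
    ``q``. Returns (labels, cutoff). All-equal scores cannot be split.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    if rule == "median":
        cutoff = float(scores.median())
    elif rule == "quantile":
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        cutoff = float(scores.quantile(q))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if scores.nunique() == 1:
        raise ValueError("all scores equal; no split possible")
    labels = pd.Series(
        np.where(scores > cutoff, "high", "low"), index=scores.index, name="group"
    )
    if labels.nunique() < 2:
        raise ValueError("cutoff produced a single group; use a different rule")
    return labels, cutoff


@dataclass
class KmResult:
    curves: dict[str, pd.DataFrame]  # per group: timeline, survival, at risk
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    group_events: dict[str, int]


def km_logrank(records: pd.DataFrame, groups: pd.Series) -> KmResult:
    """Product-limit curves per group plus the two-group log-rank test.

    ``records`` needs ``time`` and ``event`` columns indexed by sample;
    ``groups`` is a two-level label series over the same samples. Each group
    must contain at least one event.
    """
    common = records.index.intersection(groups.index)
    rec = records.loc[common]
    grp = groups.loc[common]
    levels = sorted(grp.unique().tolist(), key=str)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(levels)}")
    curves, sizes, events = {}, {}, {}
    for lv in levels:
        sub = rec[grp == lv]
        n_ev = int(sub["event"].sum())
        if n_ev == 0:
            raise ValueError(
                f"group {lv!r} has zero events; log-rank undefined — merge or regroup"
            )
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(lv))
        curves[lv] = pd.DataFrame(
            {
                "survival": kmf.survival_function_[str(lv)],
            }
        )
        sizes[lv], events[lv] = len(sub), n_ev
    a, b = levels
    res = logrank_test(
        rec.loc[grp == a, "time"],
        rec.loc[grp == b, "time"],
        event_observed_A=rec.loc[grp == a, "event"],
        event_observed_B=rec.loc[grp == b, "event"],
    )
    return KmResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=sizes,
        group_events=events,
    )


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: coef, hazard_ratio, se, z, p
    n: int
    n_events: int
    tie_method: str = "efron"
    standardized: bool = True

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hazard_ratio"])

    def z(self, name: str) -> float:
        return float(self.summary.loc[name, "z"])

    def p(self, name: str) -> float:
        return float(self.summary.loc[name, "p"])


def cox_fit(
    records: pd.DataFrame,
    covariate_names: Sequence[str],
    standardize: bool = True,
) -> CoxFit:
    """Multivariate Cox proportional-hazards fit (Efron ties).

    ``records``: time, event and covariate columns. With ``standardize`` the
    covariates are z-scored first, so coefficients are log-hazard per SD and
    the fit is invariant to affine rescaling of the inputs. Non-convergence
    and complete separation surface as errors.
    """
    covariate_names = list(covariate_names)
    missing = [c for c in covariate_names if c not in records.columns]
    if missing:
        raise KeyError(f"missing covariate column(s): {missing}")
    df = records[["time", "event", *covariate_names]].dropna().copy()
    n, n_events = len(df), int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the cohort")
    for c in covariate_names:
        col = df[c].astype(float)
        if col.nunique() == 1:
            raise ValueError(f"constant covariate {c!r}")
        if standardize:
            df[c] = (col - col.mean()) / col.std(ddof=1)
    if n_events < 10 * len(covariate_names):
        warnings.warn(
            f"only {n_events} events for {len(covariate_names)} covariates "
            "(< 10 per covariate); estimates may be unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9, "max_steps": 500},
            )
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": np.exp(s["coef"]),
            "se": s["se(coef)"],
            "z": s["z"],
            "p": s["p"],
            "hr_ci_lower": np.exp(s["coef lower 95%"]),
            "hr_ci_upper": np.exp(s["coef upper 95%"]),
        }
    )
    summary.index.name = "covariate"
    if not np.isfinite(summary[["coef", "se"]].to_numpy()).all():
        raise RuntimeError("Cox fit diverged (monotone likelihood / separation?)")
    return CoxFit(summary=summary, n=n, n_events=n_events, standardized=standardize)


def pan_cohort_cox(
    cohorts: Mapping[str, tuple[ScoreMatrix, pd.DataFrame]],
    covariate_names: Sequence[str],
    significance: float = 0.05,
) -> pd.DataFrame:
    """Fit the same multivariate Cox model independently in every cohort.

    ``cohorts`` maps tumor type to (signature ScoreMatrix, survival records
    frame). The named covariates are taken from the ScoreMatrix rows.
    Cohorts violating the fit preconditions are skipped with a logged
    reason; a table row per surviving cohort reports each covariate's HR,
    CI, p and a significance flag.
    """
    if not cohorts:
        raise ValueError("empty cohort map")
    rows = []
    for cohort_name, (scores, records) in cohorts.items():
        try:
            covs = {c: scores.row(c) for c in covariate_names}
            df = records.copy()
            for c, series in covs.items():
                df[c] = series.reindex(df.index)
            fit = cox_fit(df.dropna(), covariate_names)
        except (ValueError, KeyError, RuntimeError) as exc:
            logger.warning("cohort %s skipped: %s", cohort_name, exc)
            continue
        row: dict[str, object] = {
            "cohort": cohort_name, "n": fit.n, "n_events": fit.n_events,
        }
        for c in covariate_names:
            row[f"{c}_hr"] = fit.hazard_ratio(c)
            row[f"{c}_hr_ci_lower"] = float(fit.summary.loc[c, "hr_ci_lower"])
            row[f"{c}_hr_ci_upper"] = float(fit.summary.loc[c, "hr_ci_upper"])
            row[f"{c}_p"] = fit.p(c)
            row[f"{c}_significant"] = fit.p(c) < significance
        rows.append(row)
    if not rows:
        raise ValueError("every cohort failed Cox preconditions")
    return pd.DataFrame(rows).set_index("cohort")
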