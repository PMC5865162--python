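"""Subtype survival characterization.

Kaplan–Meier curves and medians, Mantel–Cox log-rank tests, Cox
proportional-hazards ratios, Harrell's concordance index (with a normal
approximation p-value against chance), and the six-configuration covariate
comparison: age alone, tumor location alone, imaging subtype alone, subtype
with age, subtype with location, and all three together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm

LOCATION_COLUMNS = [f"LOC_{r.upper()}" for r in (
    "frontal", "temporal", "parietal", "basal_ganglia", "insula",
    "cc_fornix", "occipital", "cerebellum", "brain_stem")]


def _check_records(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        raise ValueError("no records")
    if (df["survival_months"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event flag must be 0 or 1")
    return df


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray      # S(t) after each event time
    at_risk: np.ndarray
    median: float             # NaN when S never reaches 0.5

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk})


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimator. The median is the smallest observed time with
    S(t) <= 0.5 (left endpoint when S sits exactly at 0.5), NaN if S never
    reaches 0.5."""
    df = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["survival_months"], event_observed=df["event"])
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    s = surv.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    below = np.nonzero(s <= 0.5 + 1e-12)[0]
    median = float(times[below[0]]) if below.size else float("nan")
    return KMCurve(times=times, survival=s, at_risk=at_risk, median=median)


def logrank_test(groups: Mapping[str, pd.DataFrame] | pd.DataFrame,
                 group_col: str | None = None) -> tuple[float, float]:
    """Mantel–Cox log-rank statistic and p-value (df = n_groups - 1)."""
    if isinstance(groups, pd.DataFrame):
        if group_col is None:
            raise ValueError("group_col required with a single DataFrame")
        df = _check_records(groups)
        labels = df[group_col]
    else:
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        parts = []
        for name, g in groups.items():
            g = _check_records(g).copy()
            g["__group"] = name
            parts.append(g)
        df = pd.concat(parts, ignore_index=True)
        labels = df["__group"]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(df["survival_months"], labels, df["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxReport:
    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    c_index: float
    c_index_p: float

    def to_json_obj(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "hazard_ratios": self.hazard_ratios.to_dict(),
            "ci_lower": self.ci_lower.to_dict(),
            "ci_upper": self.ci_upper.to_dict(),
            "p_values": self.p_values.to_dict(),
            "c_index": self.c_index,
            "c_index_p": self.c_index_p,
        }


def cox_fit(records: pd.DataFrame, covariates: Sequence[str]) -> CoxReport:
    """Cox proportional-hazards fit by partial-likelihood maximization
    (lifelines); HRs with 95% CI from the observed information, plus the
    apparent Harrell c-index of the fitted linear predictor."""
    df = _check_records(records)
    covariates = list(covariates)
    if df["event"].sum() < 2:
        raise ValueError("need at least 2 observed events")
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")
    cph = CoxPHFitter()
    cph.fit(df[["survival_months", "event", *covariates]],
            duration_col="survival_months", event_col="event")
    summary = cph.summary
    risk = cph.predict_partial_hazard(df[covariates]).to_numpy(dtype=float)
    c, p = harrell_c(risk, df)
    return CoxReport(
        coefficients=summary["coef"],
        hazard_ratios=summary["exp(coef)"],
        ci_lower=summary["exp(coef) lower 95%"],
        ci_upper=summary["exp(coef) upper 95%"],
        p_values=summary["p"],
        c_index=c, c_index_p=p,
    )


def harrell_c(risk_scores: Sequence[float], records: pd.DataFrame) -> tuple[float, float]:
    """Harrell's concordance index with a normal-approximation p-value vs 0.5.

    Comparable pairs: the earlier time carries an event. Concordant = the
    shorter survival has the higher risk; score ties count 0.5. The p-value
    uses the Noether-style variance c(1-c)/N over N comparable pairs — an
    approximation that ignores pair correlation.
    """
    risk = np.asarray(risk_scores, dtype=float)
    df = _check_records(records)
    if len(risk) != len(df):
        raise ValueError("risk scores must align with records")
    t = df["survival_months"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=int)
    concordant = 0.0
    n_pairs = 0
    n = len(t)
    for i in range(n):
        if e[i] != 1:
            continue
        # j comparable with i when t[i] < t[j] (i's event happened first)
        later = t > t[i]
        n_later = int(later.sum())
        if n_later == 0:
            continue
        n_pairs += n_later
        ri = risk[i]
        rj = risk[later]
        concordant += float((rj < ri).sum()) + 0.5 * float((rj == ri).sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    c = concordant / n_pairs
    se = math.sqrt(max(c * (1.0 - c), 1e-12) / n_pairs)
    z = (c - 0.5) / se
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return float(c), float(p)


def encode_subtype(records: pd.DataFrame, subtype_col: str = "subtype",
                   reference: str = "rim_enhancing") -> tuple[pd.DataFrame, list[str]]:
    """K-1 indicator columns with the reference subtype as baseline."""
    df = records.copy()
    levels = [s for s in pd.unique(df[subtype_col]) if s != reference]
    levels.sort()
    cols = []
    for level in levels:
        col = f"subtype_{level}"
        df[col] = (df[subtype_col] == level).astype(float)
        cols.append(col)
    return df, cols


def model_comparison(records: pd.DataFrame, subtype_col: str = "subtype",
                     reference: str = "rim_enhancing",
                     location_cols: Sequence[str] | None = None,
                     ) -> pd.DataFrame:
    """Apparent c-index of the six Cox covariate configurations:
    age | location | subtype | subtype+age | subtype+location | all three."""
    if location_cols is None:
        location_cols = [c for c in LOCATION_COLUMNS if c in records.columns]
    df, subtype_dummies = encode_subtype(records, subtype_col, reference)
    # drop constant location columns (degenerate covariates); the proportions
    # are compositional (rows sum to ~100), so one region is dropped as the
    # reference to keep the design non-singular
    loc = [c for c in location_cols if df[c].nunique() > 1]
    if len(loc) > 1:
        loc = loc[:-1]
    configs = {
        "age": ["age"],
        "location": loc,
        "subtype": subtype_dummies,
        "subtype_age": subtype_dummies + ["age"],
        "subtype_location": subtype_dummies + loc,
        "subtype_age_location": subtype_dummies + ["age"] + loc,
    }
    rows = []
    for name, covs in configs.items():
        report = cox_fit(df, covs)
        rows.append({"model": name, "c_index": report.c_index,
                     "c_index_p": report.c_index_p, "n_covariates": len(covs)})
    return pd.DataFrame(rows).set_index("model")


def pairwise_cox_hr(records: pd.DataFrame, subtype_col: str = "subtype",
                    ) -> pd.DataFrame:
    """Pairwise hazard ratios between subtypes (two-group Cox fits)."""
    out = []
    subtypes = sorted(pd.unique(records[subtype_col]))
    for i in range(len(subtypes)):
        for j in range(i + 1, len(subtypes)):
            a, b = subtypes[i], subtypes[j]
            sub = records[records[subtype_col].isin([a, b])].copy()
            sub["__ind"] = (sub[subtype_col] == b).astype(float)
            report = cox_fit(sub, ["__ind"])
            out.append({"reference": a, "comparison": b,
                        "hr": float(report.hazard_ratios.iloc[0]),
                        "ci_lower": float(report.ci_lower.iloc[0]),
                        "ci_upper": float(report.ci_upper.iloc[0]),
                        "p": float(report.p_values.iloc[0])})
    return pd.DataFrame(out)
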