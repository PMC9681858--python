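"""Cluster-feature association, correlation and survival comparison.

Pearson chi-squared tests for subgroup specificity of clinical and
copy-number features, Spearman correlation for methylation-expression
relationships, Kaplan-Meier estimation and the (unweighted) log-rank test
for progression-free survival comparisons between subgroups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "chi_square_test",
    "spearman_correlation",
    "km_estimate",
    "logrank_test",
    "enrichment_report",
]


def chi_square_test(table, continuity: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns (statistic, df, p) with df = (r-1)(c-1). Yates continuity
    correction (2x2 only) is off by default.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or min(T.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (T < 0).any():
        raise ValueError("counts must be nonnegative")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column")
    res = sps.chi2_contingency(T, correction=continuity)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), p via the
    t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("x and y must be equal-length vectors with n >= 4")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def km_estimate(time, event) -> tuple[pd.DataFrame, KaplanMeierFitter]:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a right-continuous step table (time, survival, at_risk) and the
    fitted estimator; use ``survival_at`` for horizon extraction.
    """
    time = np.asarray(time, dtype=float)
    if (time < 0).any() or not np.isfinite(time).all():
        raise ValueError("times must be finite and nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event, dtype=int))
    table = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(
                kmf.survival_function_.index
            ).to_numpy(),
        }
    )
    return table, kmf


def survival_at(kmf: KaplanMeierFitter, horizon: float = 5.0) -> float:
    """Survival probability at ``horizon`` (years), e.g. 5-year PFS."""
    return float(kmf.predict(horizon))


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """Standard (unweighted) log-rank test across K groups; df = K − 1."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(
        np.asarray(time, dtype=float), groups, np.asarray(event, dtype=int)
    )
    return float(res.test_statistic), int(uniq.size - 1), float(res.p_value)


def _feature_table(
    present: pd.Series, labels: pd.Series
) -> tuple[np.ndarray, list]:
    """2 x K table (present/absent x cluster) over samples with known
    status."""
    known = present.notna()
    labs = labels[known]
    pres = present[known].astype(bool)
    clusters = sorted(pd.unique(labels))
    table = np.array(
        [
            [(pres & (labs == c)).sum() for c in clusters],
            [(~pres & (labs == c)).sum() for c in clusters],
        ],
        dtype=int,
    )
    return table, clusters


def enrichment_report(
    assignments: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cna_profiles: dict | None = None,
    infant_age: float = 1.5,
) -> pd.DataFrame:
    """Per-feature cluster enrichment table over classifiable samples.

    Features: infant diagnosis (age < 1.5 years, strict), MYCN amplification,
    each recurrent arm-level event seen in >= 1 sample, and whole-chromosome
    aberration burden ("at least 1" / "2 or more"). Each row carries the
    per-cluster counts, the overall 2 x K chi-squared p-value and per-cluster
    one-vs-rest 2 x 2 p-values. Samples of unknown status are excluded per
    feature; features present in no sample are skipped.
    """
    cls = assignments[assignments["classifiable"]]
    labels = cls["modal_cluster"]
    sheet = sample_sheet.loc[cls.index]

    features: dict[str, pd.Series] = {}
    age = pd.to_numeric(sheet["age_years"], errors="coerce")
    features["infant"] = (age < infant_age).where(age.notna())
    mycn = sheet["mycn"].astype(str)
    features["mycn_amp"] = (mycn == "amp").where(~mycn.isin(["nan", "NA", ""]))

    if cna_profiles:
        arm_events = sorted({e for s in cls.index for e in cna_profiles[s].arm_event_labels()})
        for ev in arm_events:
            features[f"chr{ev}"] = pd.Series(
                [ev in cna_profiles[s].arm_event_labels() for s in cls.index],
                index=cls.index, dtype=object,
            )
        n_wca = pd.Series([cna_profiles[s].n_wca for s in cls.index], index=cls.index)
        features["wca_at_least_1"] = (n_wca >= 1).astype(object)
        features["wca_2_or_more"] = (n_wca >= 2).astype(object)

    rows = []
    for name, present in features.items():
        if present.dropna().astype(bool).sum() == 0:
            continue
        table, clusters = _feature_table(present, labels)
        try:
            _, _, p_overall = chi_square_test(table)
        except ValueError:
            continue
        row = {"feature": name, "p_overall": p_overall, "n_known": int(table.sum())}
        for j, c in enumerate(clusters):
            row[f"n_cluster_{c}"] = int(table[0, j])
            two = np.array(
                [
                    [table[0, j], table[0].sum() - table[0, j]],
                    [table[1, j], table[1].sum() - table[1, j]],
                ]
            )
            try:
                _, _, p_c = chi_square_test(two)
            except ValueError:
                p_c = np.nan
            row[f"p_cluster_{c}"] = p_c
        rows.append(row)
    return pd.DataFrame(rows)
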