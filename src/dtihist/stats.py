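"""Group statistics: rate of change, Mann-Whitney with Holm-Bonferroni
correction, Pearson correlations with clinical variables, and the
standardised response mean (SRM).

Families for the step-down correction are the analysis blocks: the 30
baseline comparisons (2 regions x 5 indices x 3 metrics), the 30
rate-of-change comparisons, and the correlation family (passing metrics x 4
clinical variables).  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "SrmResult",
    "GroupAnalysisResult",
    "rate_of_change",
    "mann_whitney",
    "holm_bonferroni",
    "pearson_correlation",
    "srm",
    "build_study_table",
    "rates_table",
    "run_group_analysis",
    "CLINICAL_VARIABLES",
]

CLINICAL_VARIABLES = ("cag_repeats", "disease_duration_years", "iacrs_rate", "icars_rate")

_EXACT_MAX_N = 25  # exact Mann-Whitney up to the study's combined sample size


@dataclass(frozen=True)
class ComparisonResult:
    metric_id: tuple  # (region, index, metric)
    median_x: float
    iqr_x: float
    median_y: float
    iqr_y: float
    u_statistic: float
    p_value: float
    rejected: bool = False
    family_size: int = 1


@dataclass(frozen=True)
class SrmResult:
    metric_id: str
    srm: float
    n: int


@dataclass
class GroupAnalysisResult:
    baseline: pd.DataFrame
    rate: pd.DataFrame
    srm: pd.DataFrame
    correlations: pd.DataFrame


def rate_of_change(baseline_value: float, followup_value: float,
                   interval_years: float) -> float:
    """(follow-up - baseline) / interval, in metric units per year."""
    if not interval_years > 0:
        raise ValueError("interval_years must be > 0")
    return (followup_value - baseline_value) / interval_years


def mann_whitney(x_values: Sequence[float], y_values: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U = min(U1, U2), p).

    The p-value is exact (full enumeration of group assignments) for
    tie-free samples with combined n <= 25, otherwise a normal approximation
    with midranks, tie correction and continuity correction.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # degenerate all-tied sample: no evidence either way
        return x.size * y.size / 2.0, 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (not has_ties and x.size + y.size <= _EXACT_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return u, float(res.pvalue)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm rejection flags, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break  # step-down: first failure stops all further rejections
    return flags


def pearson_correlation(x_values: Sequence[float], y_values: Sequence[float]) -> tuple[float, float]:
    """Product-moment r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def srm(change_scores: Sequence[float], metric_id: str = "") -> SrmResult:
    """Standardised response mean: mean(change) / sample SD(change)."""
    c = np.asarray(change_scores, dtype=float)
    if c.size < 2:
        raise ValueError("SRM needs at least 2 change scores")
    sd = float(np.std(c, ddof=1))
    if sd == 0:
        raise ValueError("SRM undefined: change scores have zero SD")
    return SrmResult(metric_id=metric_id, srm=float(np.mean(c)) / sd, n=int(c.size))


# ---------------------------------------------------------------------------
# study-level analysis


def build_study_table(metric_rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate the tidy per-subject metric table.

    Expected columns: subject_id, group, timepoint, region, index, metric,
    value, interval_years.  Every subject must have both timepoints for
    every (region, index, metric) cell.
    """
    df = pd.DataFrame(metric_rows)
    required = {"subject_id", "group", "timepoint", "region", "index",
                "metric", "value", "interval_years"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    counts = df.groupby(["subject_id", "region", "index", "metric"])["timepoint"].nunique()
    if (counts != 2).any():
        bad = counts[counts != 2].index.tolist()[:5]
        raise ValueError(f"incomplete timepoints for cells: {bad}")
    iv = df.groupby("subject_id")["interval_years"].nunique()
    if (iv != 1).any():
        raise ValueError("interval_years must be constant within subject")
    return df


def rates_table(study_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject rate of change for every (region, index, metric)."""
    wide = study_table.pivot_table(
        index=["subject_id", "group", "region", "index", "metric", "interval_years"],
        columns="timepoint", values="value", aggfunc="first").reset_index()
    wide["rate"] = [
        rate_of_change(b, f, iv)
        for b, f, iv in zip(wide["baseline"], wide["followup"], wide["interval_years"])
    ]
    wide["change"] = wide["followup"] - wide["baseline"]
    return wide


def _iqr(values: np.ndarray, method: str) -> float:
    q1, q3 = np.percentile(values, [25, 75], method=method)
    return float(q3 - q1)


def _compare_family(df: pd.DataFrame, value_col: str, alpha: float,
                    quartile_method: str) -> pd.DataFrame:
    rows = []
    p_values = []
    cells = df.groupby(["region", "index", "metric"], sort=True)
    for (region, index, metric), cell in cells:
        x = cell.loc[cell["group"] == "patient", value_col].to_numpy()
        y = cell.loc[cell["group"] == "control", value_col].to_numpy()
        u, p = mann_whitney(x, y)
        rows.append({
            "region": region, "index": index, "metric": metric,
            "patient_median": float(np.median(x)),
            "patient_iqr": _iqr(x, quartile_method),
            "control_median": float(np.median(y)),
            "control_iqr": _iqr(y, quartile_method),
            "u_statistic": u, "p_value": p,
        })
        p_values.append(p)
    out = pd.DataFrame(rows)
    out["rejected"] = holm_bonferroni(p_values, alpha)
    out["family_size"] = len(p_values)
    return out


def run_group_analysis(study_table: pd.DataFrame, records: pd.DataFrame,
                       alpha: float = 0.05,
                       quartile_method: str = "linear") -> GroupAnalysisResult:
    """Baseline and rate-of-change group comparisons, correlations and SRM.

    ``records`` needs columns subject_id, group, interval_years, the
    baseline/follow-up clinical scores and (patients) cag_repeats and
    disease_duration_years.  Correlations are computed in patients only, for
    metrics whose rate of change differs between groups after correction.
    ``quartile_method`` selects the numpy percentile interpolation rule used
    for the reported IQRs.
    """
    baseline_df = study_table[study_table["timepoint"] == "baseline"]
    baseline = _compare_family(baseline_df, "value", alpha, quartile_method)

    rates = rates_table(study_table)
    rate_cmp = _compare_family(rates, "rate", alpha, quartile_method)

    rec = records.set_index("subject_id")
    rec = rec.assign(
        iacrs_rate=(rec["iacrs_followup"] - rec["iacrs_baseline"]) / rec["interval_years"],
        icars_rate=(rec["icars_followup"] - rec["icars_baseline"]) / rec["interval_years"],
        iacrs_change=rec["iacrs_followup"] - rec["iacrs_baseline"],
        icars_change=rec["icars_followup"] - rec["icars_baseline"],
    )
    patients = rec[rec["group"] == "patient"]

    passing = rate_cmp[rate_cmp["rejected"]][["region", "index", "metric"]]

    # correlations: passing metrics' rates vs clinical variables, patients only
    corr_rows = []
    for _, row in passing.iterrows():
        sel = rates[(rates["group"] == "patient")
                    & (rates["region"] == row["region"])
                    & (rates["index"] == row["index"])
                    & (rates["metric"] == row["metric"])].set_index("subject_id")
        metric_rates = sel["rate"].reindex(patients.index)
        for var in CLINICAL_VARIABLES:
            clinical = pd.to_numeric(patients[var], errors="coerce")
            ok = metric_rates.notna() & clinical.notna()
            entry = {"region": row["region"], "index": row["index"],
                     "metric": row["metric"], "clinical_variable": var,
                     "n": int(ok.sum())}
            try:
                r, p = pearson_correlation(metric_rates[ok], clinical[ok])
                entry.update({"r": r, "p_value": p})
            except ValueError:
                entry.update({"r": np.nan, "p_value": np.nan})
            corr_rows.append(entry)
    correlations = pd.DataFrame(
        corr_rows, columns=["region", "index", "metric", "clinical_variable",
                            "n", "r", "p_value"])
    if len(correlations) and correlations["p_value"].notna().all():
        correlations["rejected"] = holm_bonferroni(correlations["p_value"], alpha)
    else:
        correlations["rejected"] = False

    # SRM: clinical scales + passing metrics, change scores in patients
    srm_rows = []
    for scale in ("iacrs", "icars"):
        try:
            res = srm(patients[f"{scale}_change"], metric_id=scale)
            srm_rows.append({"metric_id": scale, "srm": res.srm, "n": res.n})
        except ValueError:
            srm_rows.append({"metric_id": scale, "srm": np.nan,
                             "n": int(len(patients))})
    for _, row in passing.iterrows():
        sel = rates[(rates["group"] == "patient")
                    & (rates["region"] == row["region"])
                    & (rates["index"] == row["index"])
                    & (rates["metric"] == row["metric"])]
        mid = f"{row['region']}/{row['index']}/{row['metric']}"
        try:
            res = srm(sel["change"], metric_id=mid)
            srm_rows.append({"metric_id": mid, "srm": res.srm, "n": res.n})
        except ValueError:
            srm_rows.append({"metric_id": mid, "srm": np.nan, "n": int(len(sel))})
    srm_df = pd.DataFrame(srm_rows, columns=["metric_id", "srm", "n"])

    return GroupAnalysisResult(baseline=baseline, rate=rate_cmp,
                               srm=srm_df, correlations=correlations)
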