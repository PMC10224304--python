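"""Clinical characterization of biomarker clusters.

Continuous characteristics are compared across clusters by classic one-way
ANOVA, categorical ones by Pearson chi-square (no continuity correction);
significant ANOVAs are followed by Tukey HSD all-pairs comparisons. The
summary mirrors a mean(SD) / n(%) characteristics table with one omnibus
p-value per variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Variables summarized per cluster, with their display type.
PROFILE_VARIABLES = (
    ("age", "continuous"),
    ("sex", "categorical"),
    ("bmi", "continuous"),
    ("hba1c", "continuous"),
    ("glucose", "continuous"),
    ("cholesterol", "continuous"),
    ("egfr", "continuous"),
    ("sodium", "continuous"),
    ("potassium", "continuous"),
    ("cortisol", "continuous"),
    ("sbp", "continuous"),
    ("dbp", "continuous"),
    ("dm", "categorical"),
)

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Omnibus cluster comparison for one clinical variable."""

    variable: str
    test: str  # "anova" | "chi_square"
    statistic: float
    df: tuple
    p_value: float
    summaries: dict  # per-cluster mean/sd or count/percent
    pairwise: pd.DataFrame | None = None


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    groups = [values[labels == u] for u in uniq]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    for u, g in zip(uniq, groups):
        if g.size < 2:
            raise ValueError(f"cluster {u!r} has fewer than 2 observations")
    return uniq, groups


def oneway_anova(values, labels, variable: str = "") -> GroupComparison:
    """Classic equal-variance one-way ANOVA across clusters."""
    uniq, groups = _split_groups(values, labels)
    k = len(groups)
    n = sum(g.size for g in groups)
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
        # all observations identical: F is 0/0; report no evidence
        return GroupComparison(
            variable=variable, test="anova", statistic=0.0,
            df=(k - 1, n - k), p_value=1.0,
            summaries={
                str(u): {"mean": float(g.mean()), "sd": float(g.std(ddof=1))}
                for u, g in zip(uniq, groups)
            },
        )
    stat, p = stats.f_oneway(*groups)
    return GroupComparison(
        variable=variable,
        test="anova",
        statistic=float(stat),
        df=(k - 1, n - k),
        p_value=float(p),
        summaries={
            str(u): {"mean": float(g.mean()), "sd": float(g.std(ddof=1))}
            for u, g in zip(uniq, groups)
        },
    )


def chi_square_test(counts, variable: str = "") -> GroupComparison:
    """Pearson chi-square on a category x cluster count table."""
    arr = np.asarray(
        counts.to_numpy() if isinstance(counts, pd.DataFrame) else counts,
        dtype=float,
    )
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    col_tot = arr.sum(axis=0)
    summaries = {
        str(j): {
            "counts": arr[:, j].astype(int).tolist(),
            "percents": (100 * arr[:, j] / col_tot[j]).tolist(),
        }
        for j in range(arr.shape[1])
    }
    return GroupComparison(
        variable=variable, test="chi_square", statistic=float(stat),
        df=(int(df),), p_value=float(p), summaries=summaries,
    )


def tukey_hsd(values, labels, variable: str = "") -> pd.DataFrame:
    """All-pairs Tukey HSD with studentized-range adjusted p-values."""
    uniq, groups = _split_groups(values, labels)
    res = stats.tukey_hsd(*groups)
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            rows.append(
                {
                    "variable": variable,
                    "pair": f"{uniq[a]} vs {uniq[b]}",
                    "mean_difference": float(groups[a].mean() - groups[b].mean()),
                    "p_adjusted": float(res.pvalue[a, b]),
                }
            )
    return pd.DataFrame(rows)


def profile_report(cohort: pd.DataFrame, labels) -> dict:
    """Characteristics-by-cluster summary with omnibus tests and Tukey tables.

    Returns ``{"table": DataFrame, "pairwise": DataFrame}``; the table has
    one row per clinical variable with per-cluster mean(SD) or n(%) cells and
    the ANOVA / chi-square p-value. Tukey follow-up runs only for continuous
    variables whose omnibus p < 0.05. Constant continuous variables are
    reported as NA with the reason.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    missing = [v for v, _ in PROFILE_VARIABLES if v not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing column(s) {missing!r}")
    rows = []
    pairwise_frames = []
    for var, kind in PROFILE_VARIABLES:
        row: dict = {"variable": var, "type": kind}
        if kind == "continuous":
            values = cohort[var].to_numpy(dtype=float)
            if np.ptp(values) == 0:
                for c in clusters:
                    row[f"cluster_{c}"] = "NA"
                row["p_value"] = np.nan
                row["note"] = "constant variable; ANOVA not applicable"
                rows.append(row)
                continue
            comp = oneway_anova(values, labels, variable=var)
            for c in clusters:
                s = comp.summaries[str(c)]
                row[f"cluster_{c}"] = f"{s['mean']:.2f}({s['sd']:.2f})"
            row["p_value"] = comp.p_value
            row["note"] = ""
            if comp.p_value < ALPHA:
                pairwise_frames.append(tukey_hsd(values, labels, variable=var))
        else:
            # binary indicator: count the level of interest per cluster
            if var == "sex":
                indicator = (cohort[var].to_numpy() == "F").astype(int)
                level = "F"
            else:
                indicator = cohort[var].to_numpy(dtype=int)
                level = "yes"
            table = pd.crosstab(indicator, labels).reindex(
                index=[0, 1], fill_value=0
            )
            comp = chi_square_test(table, variable=var)
            for j, c in enumerate(clusters):
                count = int(table.loc[1, c]) if 1 in table.index else 0
                total = int(table[c].sum())
                pct = 100.0 * count / total if total else float("nan")
                row[f"cluster_{c}"] = f"{count}({pct:.0f}%)"
            row["p_value"] = comp.p_value
            row["note"] = f"level counted: {level}"
        rows.append(row)
    pairwise = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame(columns=["variable", "pair", "mean_difference", "p_adjusted"])
    )
    return {"table": pd.DataFrame(rows), "pairwise": pairwise}
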