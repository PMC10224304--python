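"""Agreement between biomarker clusters and the barcode-verified treatment.

The gold standard is the 8-level treatment classification from drug-box
barcode scanning. Each cluster is evaluated against each treatment group
(and against merged group sets such as combined ACEi regimens) on the 2x2
collapse: sensitivity P(cluster | group), specificity P(not cluster | not
group), exact Clopper-Pearson 95% intervals, and Cohen's kappa; a weighted
kappa on full square tables is available for ordered multi-class use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default merged gold-standard group sets mirroring the combined report rows.
DEFAULT_MERGES = {
    "Non-RAAS": ["Normotensive", "Hypertensive", "Non-AHD", "Beta blockers"],
    "ACEi or ACEi+diur": ["ACEi", "ACEi+diuretics"],
    "ARB or ARB+diur": ["ARB", "ARB+diuretics"],
}


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (report parity)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ContingencyTable:
    """Cluster x treatment-group counts."""

    counts: pd.DataFrame  # rows = clusters, columns = groups

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class BinaryAgreement:
    """2x2 collapse of clusters-vs-groups with exact binomial intervals."""

    cluster_set: tuple
    group_set: tuple
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ci_sensitivity: tuple[float, float] | None
    ci_specificity: tuple[float, float] | None
    kappa: float


@dataclass
class KappaResult:
    """Chance-corrected agreement with large-sample Wald interval."""

    kappa: float
    weighting: str
    se: float
    ci: tuple[float, float]


def crosstab(labels, groups) -> ContingencyTable:
    """Exact cluster x group counts from per-subject assignments."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape[0] != groups.shape[0]:
        raise ValueError(
            f"length mismatch: {labels.shape[0]} cluster labels vs "
            f"{groups.shape[0]} group labels"
        )
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(groups, name="group"))
    return ContingencyTable(table)


def merge_groups(table: ContingencyTable, mapping: dict[str, list]) -> ContingencyTable:
    """Sum gold-standard columns into merged sets; untouched columns persist."""
    counts = table.counts
    merged_away: set = set()
    new_cols = {}
    for new_label, old_labels in mapping.items():
        missing = [g for g in old_labels if g not in counts.columns]
        if missing:
            raise ValueError(f"unknown group label(s) {missing!r}")
        new_cols[new_label] = counts[old_labels].sum(axis=1)
        merged_away.update(old_labels)
    kept = counts[[c for c in counts.columns if c not in merged_away]]
    out = pd.concat([kept, pd.DataFrame(new_cols, index=counts.index)], axis=1)
    return ContingencyTable(out)


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval from beta-distribution quantiles.

    Lower bound is 0 when x=0 and upper bound is 1 when x=n.
    """
    if n <= 0 or not 0 <= x <= n:
        raise ValueError(f"invalid successes/trials: x={x}, n={n}")
    alpha = 1.0 - conf
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def _kappa_2x2(tp: int, fp: int, fn: int, tn: int) -> float:
    n = tp + fp + fn + tn
    if n == 0:
        return float("nan")
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def binary_agreement(
    table: ContingencyTable, cluster_set, group_set
) -> BinaryAgreement:
    """Collapse to (in cluster set) vs (in gold-standard group set).

    Sensitivity is the fraction of gold-standard subjects captured by the
    cluster set; specificity the fraction of other subjects excluded from it.
    An empty gold-standard margin leaves sensitivity undefined (None).
    """
    cluster_set = tuple(np.atleast_1d(cluster_set))
    group_set = tuple(np.atleast_1d(group_set))
    if not cluster_set or not group_set:
        raise ValueError("cluster_set and group_set must be non-empty")
    counts = table.counts
    for g in group_set:
        if g not in counts.columns:
            raise ValueError(f"unknown group label {g!r}")
    for c in cluster_set:
        if c not in counts.index:
            raise ValueError(f"unknown cluster label {c!r}")
    in_c = counts.index.isin(cluster_set)
    in_g = counts.columns.isin(group_set)
    arr = counts.to_numpy()
    tp = int(arr[np.ix_(in_c, in_g)].sum())
    fp = int(arr[np.ix_(in_c, ~in_g)].sum())
    fn = int(arr[np.ix_(~in_c, in_g)].sum())
    tn = int(arr[np.ix_(~in_c, ~in_g)].sum())
    if tp + fn > 0:
        sens = tp / (tp + fn)
        ci_sens = clopper_pearson(tp, tp + fn)
    else:
        sens, ci_sens = None, None
    if tn + fp > 0:
        spec = tn / (tn + fp)
        ci_spec = clopper_pearson(tn, tn + fp)
    else:
        spec, ci_spec = None, None
    return BinaryAgreement(
        cluster_set=cluster_set,
        group_set=group_set,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        ci_sensitivity=ci_sens,
        ci_specificity=ci_spec,
        kappa=_kappa_2x2(tp, fp, fn, tn),
    )


def weighted_kappa(
    table: np.ndarray | pd.DataFrame, weighting: str = "unweighted"
) -> KappaResult:
    """Cohen's kappa with optional linear/quadratic disagreement weights.

    kappa_w = 1 - sum(w_ij p_ij) / sum(w_ij e_ij) with w the disagreement
    weights (|i-j|/(c-1), or its square) and e the chance-expected cell
    probabilities from the marginals. The binary collapse makes all
    weightings coincide with ordinary Cohen's kappa. SE is the Fleiss-Cohen-
    Everitt large-sample formula; the CI is Wald.
    """
    arr = np.asarray(
        table.to_numpy() if isinstance(table, pd.DataFrame) else table,
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("weighted kappa needs a square agreement table")
    if weighting not in ("unweighted", "linear", "quadratic"):
        raise ValueError(f"unknown weighting {weighting!r}")
    c = arr.shape[0]
    n = arr.sum()
    if n <= 0:
        raise ValueError("empty table")
    p = arr / n
    pr = p.sum(axis=1)  # row marginals
    pc = p.sum(axis=0)  # column marginals
    i, j = np.meshgrid(np.arange(c), np.arange(c), indexing="ij")
    if weighting == "unweighted":
        w = (i != j).astype(float)
    else:
        w = np.abs(i - j) / (c - 1) if c > 1 else np.zeros((1, 1))
        if weighting == "quadratic":
            w = w**2
    e = np.outer(pr, pc)
    expected_disagree = (w * e).sum()
    if expected_disagree == 0:
        kappa = 1.0 if (w * p).sum() == 0 else 0.0
        return KappaResult(kappa=kappa, weighting=weighting, se=0.0,
                           ci=(kappa, kappa))
    kappa = 1.0 - (w * p).sum() / expected_disagree
    # large-sample variance (Fleiss, Cohen & Everitt) on agreement weights
    v = 1.0 - w  # agreement weights in [0, 1]
    po_w = (v * p).sum()
    pe_w = (v * e).sum()
    vbar_row = (v * pc[None, :]).sum(axis=1)  # row-wise expected agreement
    vbar_col = (v * pr[:, None]).sum(axis=0)
    term = (
        p * (v - (vbar_row[:, None] + vbar_col[None, :]) * (1 - kappa)) ** 2
    ).sum()
    var = (term - (kappa - pe_w * (1 - kappa)) ** 2) / (n * (1 - pe_w) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    return KappaResult(
        kappa=float(kappa),
        weighting=weighting,
        se=se,
        ci=(float(kappa - z * se), float(kappa + z * se)),
    )


def _percent_cell(p: float | None, ci: tuple[float, float] | None) -> str:
    if p is None:
        return "NA"
    lo, hi = ci
    return (
        f"{round_half_up(100 * p)}"
        f"({round_half_up(100 * lo)}–{round_half_up(100 * hi)})"
    )


def agreement_report(
    table: ContingencyTable, merges: dict[str, list] | None = None
) -> pd.DataFrame:
    """Per-(cluster, group) agreement grid including merged group rows.

    One row per cluster x (each gold-standard group + each merged set):
    kappa of the binary collapse, sensitivity and specificity with exact 95%
    intervals, raw proportions, and integer-percent formatted cells.
    """
    merges = DEFAULT_MERGES if merges is None else merges
    group_sets = [(g, [g]) for g in table.counts.columns]
    for name, members in merges.items():
        missing = [g for g in members if g not in table.counts.columns]
        if missing:
            raise ValueError(f"unknown group label(s) {missing!r}")
        group_sets.append((name, list(members)))
    rows = []
    for cluster in table.counts.index:
        for name, members in group_sets:
            ba = binary_agreement(table, [cluster], members)
            rows.append(
                {
                    "cluster": cluster,
                    "group": name,
                    "tp": ba.tp,
                    "fp": ba.fp,
                    "fn": ba.fn,
                    "tn": ba.tn,
                    "kappa": ba.kappa,
                    "sensitivity": ba.sensitivity,
                    "specificity": ba.specificity,
                    "sens_ci_low": None if ba.ci_sensitivity is None else ba.ci_sensitivity[0],
                    "sens_ci_high": None if ba.ci_sensitivity is None else ba.ci_sensitivity[1],
                    "spec_ci_low": None if ba.ci_specificity is None else ba.ci_specificity[0],
                    "spec_ci_high": None if ba.ci_specificity is None else ba.ci_specificity[1],
                    "kappa_pct": round_half_up(100 * ba.kappa),
                    "sensitivity_fmt": _percent_cell(ba.sensitivity, ba.ci_sensitivity),
                    "specificity_fmt": _percent_cell(ba.specificity, ba.ci_specificity),
                }
            )
    return pd.DataFrame(rows)
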