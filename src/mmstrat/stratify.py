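"""The 1q&13 patient classification and group-level tests.

Patients are partitioned three ways by the joint presence (at CCF >= 50) of
a 1q gain and a 13q loss: both present -> "1q&13+", both absent -> "1q&13-",
exactly one -> "1q/13". 1q&13+ patients who additionally carry a CCND2- or
MAF-deregulating IgH translocation (t(4;14), t(14;16), t(14;20)) form the
rarer high-risk "t&1q&13+" category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import T1Q13_TRANSLOCATIONS

LABELS = ("1q&13+", "1q/13", "1q&13-")


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Share of a count as a percentage, rounded as reported in tables."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round(100.0 * numerator / denominator, digits)


def classify_1q13(matrix) -> pd.Series:
    """Three-way 1q&13 label per patient from the alteration matrix.

    Patients with a missing value in either index column get a missing
    label and are excluded from group tests (the count is reported by
    :func:`label_counts`).
    """
    clon = matrix.clonality if hasattr(matrix, "clonality") else matrix
    for col in ("Amp 1q", "Del 13q"):
        if col not in clon.columns:
            raise ValueError(f"matrix lacks the {col!r} column")
    a1q = clon["Amp 1q"]
    d13 = clon["Del 13q"]
    labels = np.select(
        [a1q.isna() | d13.isna(), (a1q > 0) & (d13 > 0), (a1q == 0) & (d13 == 0)],
        [None, "1q&13+", "1q&13-"], default="1q/13")
    return pd.Series(labels, index=clon.index, name="label", dtype=object)


def label_counts(labels: pd.Series) -> dict[str, int]:
    counts = {lab: int((labels == lab).sum()) for lab in LABELS}
    counts["missing"] = int(labels.isna().sum())
    return counts


def flag_t1q13(labels: pd.Series, tihg_type: pd.Series) -> pd.Series:
    """t&1q&13+ flag: 1q&13+ AND a t(4;14)/t(14;16)/t(14;20) translocation."""
    tihg_type = tihg_type.reindex(labels.index)
    flag = (labels == "1q&13+") & tihg_type.isin(T1Q13_TRANSLOCATIONS)
    return flag.rename("t1q13")


@dataclass
class GroupComplexityReport:
    kruskal_h: float
    kruskal_p: float
    medians: dict[str, float]
    median_ci: dict[str, tuple[float, float]]
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


def _bootstrap_median_ci(values: np.ndarray, rng: np.random.Generator,
                         n_boot: int = 2000) -> tuple[float, float]:
    medians = np.median(
        rng.choice(values, size=(n_boot, len(values)), replace=True), axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return float(lo), float(hi)


def group_complexity_test(complexity: pd.Series, labels: pd.Series,
                          seed: int = 0, n_boot: int = 2000) -> GroupComplexityReport:
    """Kruskal-Wallis across the 1q&13 classes plus all pairwise two-sided
    Mann-Whitney tests on genomic complexity, with bootstrap 95% CIs of the
    per-group median."""
    labels = labels.reindex(complexity.index)
    groups = {lab: complexity[labels == lab].to_numpy(dtype=float)
              for lab in LABELS if (labels == lab).sum() > 0}
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups for the complexity test")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):  # scipy rejects all-identical data
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups.values())
    rng = np.random.default_rng(seed)
    medians = {lab: float(np.median(v)) for lab, v in groups.items()}
    cis = {lab: _bootstrap_median_ci(v, rng, n_boot) for lab, v in groups.items()}
    pairwise: dict[tuple[str, str], float] = {}
    skipped: list[tuple[str, str]] = []
    for a, b in combinations(groups, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            skipped.append((a, b))
            continue
        pairwise[(a, b)] = float(
            stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue)
    return GroupComplexityReport(float(h), float(p), medians, cis, pairwise, skipped)


def contingency_report(labels: pd.Series, covariates: pd.DataFrame,
                       kinds: dict[str, str]) -> pd.DataFrame:
    """Baseline-characteristics tests per covariate across the 1q&13 classes.

    ``kinds`` maps covariate name -> "categorical" or "continuous".
    Categorical covariates: for each group and each level, a two-sided
    Fisher exact test of (level vs rest) x (group vs rest). Continuous
    covariates: two-sided Mann-Whitney per group vs rest, with the group
    median and IQR echoed. All-missing covariates are skipped with a
    warning row.
    """
    rows = []
    labels = labels.reindex(covariates.index)
    classified = labels.notna()
    for cov, kind in kinds.items():
        if cov not in covariates.columns:
            raise ValueError(f"covariate {cov!r} not in the table")
        values = covariates.loc[classified, cov]
        labs = labels[classified]
        ok = values.notna()
        if not ok.any():
            rows.append({"covariate": cov, "kind": kind, "group": None,
                         "level": None, "p": np.nan, "note": "all missing; skipped"})
            continue
        values, labs = values[ok], labs[ok]
        if kind == "categorical":
            for group in LABELS:
                in_group = labs == group
                if in_group.sum() == 0:
                    continue
                for level in sorted(values.unique(), key=str):
                    is_level = values == level
                    table = [[int((in_group & is_level).sum()),
                              int((in_group & ~is_level).sum())],
                             [int((~in_group & is_level).sum()),
                              int((~in_group & ~is_level).sum())]]
                    _, p = stats.fisher_exact(table, alternative="two-sided")
                    rows.append({"covariate": cov, "kind": kind, "group": group,
                                 "level": level, "p": float(p), "note": ""})
        elif kind == "continuous":
            vals = pd.to_numeric(values)
            for group in LABELS:
                in_group = labs == group
                if in_group.sum() == 0 or (~in_group).sum() == 0:
                    continue
                p = float(stats.mannwhitneyu(vals[in_group], vals[~in_group],
                                             alternative="two-sided").pvalue)
                q1, med, q3 = np.percentile(vals[in_group], [25, 50, 75])
                rows.append({"covariate": cov, "kind": kind, "group": group,
                             "level": None, "p": p,
                             "median": float(med), "iqr_low": float(q1),
                             "iqr_high": float(q3), "note": ""})
        else:
            raise ValueError(f"covariate kind must be categorical or continuous, "
                             f"got {kind!r}")
    return pd.DataFrame(rows)


def stratified_frame(matrix, tihg_type: pd.Series,
                     complexity_merged: pd.Series | None = None,
                     complexity_per_arm: pd.Series | None = None) -> pd.DataFrame:
    """One row per patient: label, t&1q&13 flag, complexity counts."""
    labels = classify_1q13(matrix)
    out = pd.DataFrame({"label": labels,
                        "t1q13": flag_t1q13(labels, tihg_type)})
    if complexity_merged is not None:
        out["complexity_merged"] = complexity_merged.reindex(out.index)
    if complexity_per_arm is not None:
        out["complexity_per_arm"] = complexity_per_arm.reindex(out.index)
    out["tihg_type"] = tihg_type.reindex(out.index)
    return out
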