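"""Driverness Index: penetrance over carrier genomic complexity.

For an alteration A, DI(A) = rho / MTGC where rho is the fraction of the
cohort carrying A at CCF >= 50 and MTGC is the median total genomic
complexity of the carriers. Complexity has two conventions:

* merged - number of catalogue variables present per patient (HD and t-IgH
  each count once); this is the convention bound to the DI, so that a
  hyperdiploid genome counts as one founding event rather than many arms;
* per_arm - number of distinct (arm, direction) calls at CCF >= 50 plus one
  per translocation; this is the convention used for the per-class
  complexity comparisons.

A frequent alteration arising on simple genomic backgrounds (high rho, low
MTGC) scores high and is read as a driver / primary event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import TIHG_TYPES


@dataclass(frozen=True)
class DriverScore:
    variable: str
    rho: float    # penetrance: carriers / cohort size
    mtgc: float   # median merged-mode complexity of carriers (>= 1)
    di: float     # rho / mtgc


def complexity_merged(matrix) -> pd.Series:
    """Merged-mode complexity: catalogue variables present per patient."""
    binary = matrix.binary if hasattr(matrix, "binary") else (matrix > 0).astype(int)
    return binary.sum(axis=1).rename("complexity_merged")


def complexity_per_arm(calls: pd.DataFrame, tihg_table: pd.DataFrame,
                       patients: list[str] | None = None,
                       min_ccf: float = 50.0) -> pd.Series:
    """Per-arm complexity: distinct (arm, direction) calls at CCF >= min_ccf
    plus one per translocation carried."""
    major = calls[calls["ccf"] >= min_ccf]
    arm_counts = (major.drop_duplicates(["sample_id", "chromosome", "arm", "direction"])
                  .groupby("sample_id").size())
    tihg = tihg_table.set_index("patient_id") if "patient_id" in tihg_table.columns \
        else tihg_table
    t_counts = tihg[list(TIHG_TYPES)].sum(axis=1)
    if patients is None:
        patients = sorted(set(arm_counts.index.astype(str)) | set(t_counts.index.astype(str)))
    idx = pd.Index([str(p) for p in patients], name="patient_id")
    total = (arm_counts.reindex(idx).fillna(0) + t_counts.reindex(idx).fillna(0))
    return total.astype(int).rename("complexity_per_arm")


def complexity(mode: str, matrix=None, calls: pd.DataFrame | None = None,
               tihg_table: pd.DataFrame | None = None, **kw) -> pd.Series:
    if mode == "merged":
        if matrix is None:
            raise ValueError("merged mode needs the alteration matrix")
        return complexity_merged(matrix)
    if mode == "per_arm":
        if calls is None or tihg_table is None:
            raise ValueError("per_arm mode needs arm calls and the translocation table")
        return complexity_per_arm(calls, tihg_table, **kw)
    raise ValueError(f"unknown complexity mode {mode!r}")


def driverness_index(matrix, variable: str) -> DriverScore | None:
    """DI for one variable; None (missing) when it has no carriers."""
    binary = matrix.binary if hasattr(matrix, "binary") else (matrix > 0).astype(int)
    if variable not in binary.columns:
        raise ValueError(f"variable {variable!r} not in the matrix")
    carriers = binary[variable] > 0
    n_carriers = int(carriers.sum())
    if n_carriers == 0:
        return None
    rho = n_carriers / len(binary)
    mtgc = float(complexity_merged(binary)[carriers].median())
    return DriverScore(variable, rho, mtgc, rho / mtgc)


def rank_drivers(matrix) -> pd.DataFrame:
    """All variables scored and sorted by descending DI (ties: higher rho,
    then name). Variables without carriers are listed last with missing DI."""
    binary = matrix.binary if hasattr(matrix, "binary") else (matrix > 0).astype(int)
    rows = []
    for var in binary.columns:
        score = driverness_index(binary, var)
        if score is None:
            rows.append({"variable": var, "rho": 0.0, "mtgc": np.nan, "di": np.nan})
        else:
            rows.append({"variable": score.variable, "rho": score.rho,
                         "mtgc": score.mtgc, "di": score.di})
    df = pd.DataFrame(rows)
    df["_name"] = df["variable"]
    df = (df.sort_values(["di", "rho", "_name"],
                         ascending=[False, False, True], na_position="last")
          .drop(columns="_name").reset_index(drop=True))
    df.index = pd.RangeIndex(1, len(df) + 1, name="rank")
    return df


def cross_cohort_spearman(scores_a: pd.DataFrame, scores_b: pd.DataFrame):
    """Spearman rank correlation of DI over the shared variables of two
    cohorts' driver tables (as produced by :func:`rank_drivers`)."""
    a = scores_a.set_index("variable")["di"].dropna()
    b = scores_b.set_index("variable")["di"].dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared variables; need >= 5")
    rho, p = stats.spearmanr(a[shared], b[shared])
    return float(rho), float(p)
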