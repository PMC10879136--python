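"""Pairwise co-occurrence of alterations.

Pearson correlation is computed on the clonality-valued matrix (absence
coded 0, presence the CCF in [50, 100]) with a two-sided p-value from the
t reference distribution on n-2 degrees of freedom. Jaccard similarity is
computed on the binary matrix. Mirroring the source analysis convention, no
multiple-testing correction is applied to the canonical output; a
Benjamini-Hochberg column is emitted as clearly-labelled supplementary
output only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairwiseMatrix:
    statistic: pd.DataFrame          # variables x variables
    kind: str                        # "pearson" or "jaccard"
    p_value: pd.DataFrame | None = None
    alpha: float = 0.05
    low_freq_vars: tuple[str, ...] = ()  # excluded from the plotted matrix

    @property
    def significant(self) -> pd.DataFrame | None:
        if self.p_value is None:
            return None
        return self.p_value < self.alpha

    def long_format(self, include_bh: bool = True) -> pd.DataFrame:
        """One row per unordered variable pair (upper triangle)."""
        cols = self.statistic.columns
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rec = {"var_a": a, "var_b": b,
                       "statistic": self.statistic.at[a, b]}
                if self.p_value is not None:
                    rec["p"] = self.p_value.at[a, b]
                    rec["significant"] = bool(rec["p"] < self.alpha) \
                        if np.isfinite(rec["p"]) else False
                rows.append(rec)
        out = pd.DataFrame(rows)
        if include_bh and self.p_value is not None and len(out):
            # supplementary, non-canonical: BH-adjusted q-values
            out["q_bh_supplementary"] = _benjamini_hochberg(out["p"].to_numpy())
        return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def pearson_cooccurrence(matrix, min_freq: float = 0.05,
                         alpha: float = 0.05) -> PairwiseMatrix:
    """Pearson R and two-sided p for every pair of clonality-valued columns.

    ``matrix`` is an AlterationMatrix or a plain clonality DataFrame.
    Zero-variance columns yield missing (NaN) statistics, not 0. Pairs whose
    variables fall below ``min_freq`` cohort frequency are retained in the
    output but listed in ``low_freq_vars`` for exclusion from plots.
    """
    clon = matrix.clonality if hasattr(matrix, "clonality") else matrix
    n = len(clon)
    if n < 3:
        raise ValueError(f"need >= 3 patients for Pearson co-occurrence (got {n})")
    X = clon.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[np.abs(R) > 1] = np.sign(R[np.abs(R) > 1])  # numerical guard
    zero_var = sd == 0
    R[zero_var, :] = np.nan
    R[:, zero_var] = np.nan
    np.fill_diagonal(R, np.where(zero_var, np.nan, 1.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(R), 1.0)] = 0.0
    p[np.isnan(R)] = np.nan
    np.fill_diagonal(p, np.nan)

    cols = clon.columns
    freqs = (clon > 0).mean(axis=0)
    return PairwiseMatrix(
        statistic=pd.DataFrame(R, index=cols, columns=cols),
        p_value=pd.DataFrame(p, index=cols, columns=cols),
        kind="pearson", alpha=alpha,
        low_freq_vars=tuple(freqs.index[freqs < min_freq]))


def jaccard_cooccurrence(matrix) -> PairwiseMatrix:
    """Jaccard similarity |A n B| / |A u B| for every pair of binary columns;
    missing (NaN) when both columns are all-zero."""
    binary = matrix.binary if hasattr(matrix, "binary") else matrix
    B = (binary.to_numpy(dtype=float) > 0).astype(float)
    inter = B.T @ B
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / union, np.nan)
    cols = binary.columns
    return PairwiseMatrix(statistic=pd.DataFrame(J, index=cols, columns=cols),
                          kind="jaccard")
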