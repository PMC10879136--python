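"""The merged alteration matrix (patients x catalogue variables).

Gains on the odd hyperdiploidy chromosomes are merged into a single "HD"
label (called when gains cover >= 2 arms of >= 2 distinct odd chromosomes);
the five mutually exclusive IgH translocations are merged into "t-IgH".
The matrix exists in a binary view (presence at CCF >= 50) and a clonality
view (0 when absent, the CCF in [50, 100] when present; translocations are
FISH-binary and coded 100). In "recompute" mode CNA variables observed in
fewer than 5% of the cohort are dropped; the default "fixed" mode keeps the
printed catalogue layout for cross-cohort comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import CATALOGUE, HD_CHROMOSOMES, TIHG_TYPES, variable_kind

FREQ_FILTER = 0.05


@dataclass
class AlterationMatrix:
    """Clonality-valued and binary views of the cohort alteration matrix."""
    clonality: pd.DataFrame  # patients x variables; 0 = absent, else CCF
    frequencies: pd.Series   # per-variable cohort frequency in [0, 1]
    mode: str                # "fixed" or "recompute"

    @property
    def binary(self) -> pd.DataFrame:
        return (self.clonality > 0).astype(int)

    @property
    def patients(self) -> pd.Index:
        return self.clonality.index

    @property
    def variables(self) -> pd.Index:
        return self.clonality.columns

    def to_tsv(self, path, view: str = "clonality") -> None:
        frame = self.clonality if view == "clonality" else self.binary
        frame.rename_axis("patient_id").to_csv(path, sep="\t")


def hd_flag(patient_calls: pd.DataFrame) -> bool:
    """Hyperdiploidy: gain-direction calls covering >= 2 arms that belong to
    >= 2 distinct odd chromosomes (3, 5, 7, 9, 11, 15, 19, 21)."""
    gains = patient_calls[(patient_calls["direction"] == "gain")
                          & patient_calls["chromosome"].isin(HD_CHROMOSOMES)]
    arms = set(zip(gains["chromosome"], gains["arm"]))
    chroms = {c for c, _ in arms}
    return len(arms) >= 2 and len(chroms) >= 2


def build_matrix(arm_calls: pd.DataFrame,
                 tihg_table: pd.DataFrame,
                 patients: list[str] | None = None,
                 mode: str = "fixed",
                 min_ccf: float = 50.0,
                 freq_filter: float = FREQ_FILTER) -> AlterationMatrix:
    """Assemble the merged alteration matrix from arm calls + FISH table.

    ``tihg_table`` has one row per patient with 0/1 columns per translocation
    partner. ``patients`` fixes the row universe (default: union of the two
    inputs). Odd-chromosome gain calls are consumed by the HD merge and never
    emit standalone columns; merged-variable clonality is the maximum CCF of
    the contributing events (100 for translocations).
    """
    if mode not in ("fixed", "recompute"):
        raise ValueError(f"unknown mode {mode!r}: expected 'fixed' or 'recompute'")
    calls = arm_calls[arm_calls["ccf"] >= min_ccf]
    unknown = set(calls["variable"]) - set(CATALOGUE)
    odd_gain = calls["chromosome"].isin(HD_CHROMOSOMES) & (calls["direction"] == "gain")
    unknown -= set(calls.loc[odd_gain, "variable"])  # consumed by HD
    if unknown:
        raise ValueError(f"calls carry variables outside the catalogue: "
                         f"{sorted(unknown)}")

    tihg = tihg_table.set_index("patient_id") if "patient_id" in tihg_table.columns \
        else tihg_table
    missing_t = [t for t in TIHG_TYPES if t not in tihg.columns]
    if missing_t:
        raise ValueError(f"translocation table is missing columns {missing_t}")

    if patients is None:
        patients = sorted(set(calls["sample_id"]) | set(tihg.index.astype(str)))
    mat = pd.DataFrame(0.0, index=pd.Index(patients, name="patient_id"),
                       columns=list(CATALOGUE))

    by_patient = dict(tuple(calls.groupby("sample_id", sort=False)))
    for pid in patients:
        grp = by_patient.get(pid)
        if grp is None:
            continue
        odd = grp["chromosome"].isin(HD_CHROMOSOMES) & (grp["direction"] == "gain")
        if hd_flag(grp):
            mat.at[pid, "HD"] = grp.loc[odd, "ccf"].max()
        for row in grp[~odd].itertuples(index=False):
            mat.at[pid, row.variable] = max(mat.at[pid, row.variable], row.ccf)

    t_flags = tihg.reindex([str(p) for p in patients])[list(TIHG_TYPES)].fillna(0)
    mat["t-IgH"] = np.where(t_flags.sum(axis=1).to_numpy() > 0, 100.0, 0.0)

    freqs = (mat > 0).mean(axis=0)
    if mode == "recompute":
        keep = [v for v in mat.columns
                if variable_kind(v) == "merged" or freqs[v] >= freq_filter]
        mat = mat[keep]
        freqs = freqs[keep]
    return AlterationMatrix(clonality=mat, frequencies=freqs, mode=mode)


def load_tihg(path) -> pd.DataFrame:
    """Read the translocation TSV (patient_id plus one 0/1 column per partner)."""
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns:
        raise ValueError(f"translocation table {path} lacks a patient_id column")
    missing = [t for t in TIHG_TYPES if t not in df.columns]
    if missing:
        raise ValueError(f"translocation table {path} is missing columns {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df
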