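"""Arm-level CNA calling from purity-corrected copy-number segments.

Thresholds follow the array pipeline conventions this package targets:
single-copy gain at CN >= 2.1, single-copy loss at CN <= 1.9, two-or-more
copy gain at CN >= 3.4, homozygous loss at CN <= 0.6, LOH at BAF >= 0.8.
A broad call requires qualifying segments to span more than 25% of the
chromosome arm; any qualifying segment overlapping one of the eight
recurrent focal regions yields a focal call regardless of arm fraction.
Calls are annotated with a clonality class from their cancer cell fraction
(clonal > 90%, sub-clonal major 50-90%, sub-clonal minor 10-50%); events
below 10% CCF are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import ACROCENTRIC, arm_table, focal_regions, variable_name

GAIN_CN = 2.1
LOSS_CN = 1.9
HIGH_GAIN_CN = 3.4
HOMO_LOSS_CN = 0.6
BAF_LOH = 0.8
BROAD_FRACTION = 0.25
MIN_CCF = 10.0

REQUIRED_SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "CN", "BAF", "CCF")


@dataclass(frozen=True)
class ArmCall:
    sample_id: str
    variable: str            # e.g. "Del 13q"
    chromosome: int
    arm: str
    direction: str           # gain | loss
    level: str               # gain | high_gain | loss | homo_loss
    basis: str               # "broad" or "focal:<region>"
    ccf: float               # length-weighted median CCF of qualifying span
    clonality_class: str     # clonal | subclonal_major | subclonal_minor
    loh: bool


def clonality_class(ccf: float) -> str | None:
    """Clonality band of a CCF percentage; None below the minor band."""
    if ccf > 90.0:
        return "clonal"
    if ccf >= 50.0:
        return "subclonal_major"
    if ccf >= MIN_CCF:
        return "subclonal_minor"
    return None


def load_seg(path) -> pd.DataFrame:
    """Read a SEG-like TSV into the internal segment frame.

    On-disk coordinates are 1-based inclusive; internally segments are
    0-based half-open. Rows with non-numeric CN (or coordinates) are rejected
    with their line numbers; overlapping segments of one sample on one
    chromosome are a parse error.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_SEG_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"SEG file {path} is missing columns {missing}")
    df = pd.DataFrame({
        "sample_id": raw["Sample"].astype(str),
        "chromosome": pd.to_numeric(raw["Chromosome"], errors="coerce"),
        "start": pd.to_numeric(raw["Start"], errors="coerce"),
        "end": pd.to_numeric(raw["End"], errors="coerce"),
        "cn": pd.to_numeric(raw["CN"], errors="coerce"),
        "baf": pd.to_numeric(raw["BAF"], errors="coerce"),
        "ccf": pd.to_numeric(raw["CCF"], errors="coerce"),
    })
    bad = df[["chromosome", "start", "end", "cn"]].isna().any(axis=1)
    if bad.any():
        lines = [i + 2 for i in df.index[bad]]  # +1 header, +1 one-based
        raise ValueError(f"non-numeric CN/coordinates on line(s) {lines} of {path}")
    df["chromosome"] = df["chromosome"].astype(int)
    df["start"] = df["start"].astype(int) - 1  # -> 0-based half-open
    df["end"] = df["end"].astype(int)
    malformed = df["start"] >= df["end"]
    if malformed.any():
        lines = [i + 2 for i in df.index[malformed]]
        raise ValueError(f"start >= end on line(s) {lines} of {path}")
    validate_segments(df)
    return df


def validate_segments(segments: pd.DataFrame) -> None:
    """Reject overlapping segments of one sample on one chromosome."""
    for (sample, chrom), grp in segments.groupby(["sample_id", "chromosome"],
                                                 sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].values[1:] < g["end"].values[:-1]
        if overlap.any():
            raise ValueError(f"overlapping segments for sample {sample!r} "
                             f"chromosome {chrom}")


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cutoff = 0.5 * w.sum()
    return float(v[np.searchsorted(cum, cutoff)])


def call_arm_events(segments: pd.DataFrame,
                    arms: pd.DataFrame | None = None,
                    focal: pd.DataFrame | None = None,
                    broad_fraction: float = BROAD_FRACTION) -> pd.DataFrame:
    """Call arm-level CNAs for every sample.

    For each sample, arm and direction: qualifying bases are the summed
    lengths of segments past the gain/loss threshold (clipped to the arm);
    a broad call needs qualifying bases / arm length > ``broad_fraction``, a
    focal call needs >= 1 bp overlap between a qualifying segment and a focal
    region on the arm. The call level is upgraded to high_gain / homo_loss
    when the length-weighted mean CN of the qualifying span crosses 3.4 /
    0.6; call CCF is the length-weighted median CCF; LOH is flagged when the
    length-weighted mean BAF of the qualifying span is >= 0.8. At most one
    call per (sample, arm, direction), broad basis preferred over focal.
    Returns a frame of calls (one row per call).
    """
    if arms is None:
        arms = arm_table()
    if focal is None:
        focal = focal_regions()

    # acrocentric p-arm coordinates are not callable territory
    for r in arms[arms["acrocentric"].astype(bool)].itertuples(index=False):
        chrom = int(r.chromosome)
        on_chrom = segments[segments["chromosome"] == chrom]
        before_q = on_chrom[on_chrom["start"] < int(r.start)]
        if len(before_q):
            s = before_q.iloc[0]
            raise ValueError(
                f"segment {s['sample_id']}:{chrom}:{int(s['start'])}-"
                f"{int(s['end'])} lies on the acrocentric {chrom}p region")

    calls: list[ArmCall] = []
    seg_by_chrom = dict(tuple(segments.groupby("chromosome", sort=False)))
    for r in arms.itertuples(index=False):
        chrom, arm = int(r.chromosome), str(r.arm)
        arm_start, arm_end = int(r.start), int(r.end)
        arm_len = arm_end - arm_start
        chrom_segs = seg_by_chrom.get(chrom)
        if chrom_segs is None:
            continue
        inside = chrom_segs[(chrom_segs["end"] > arm_start)
                            & (chrom_segs["start"] < arm_end)]
        if not len(inside):
            continue
        regions = focal[(focal["chromosome"] == chrom) & (focal["arm"] == arm)]
        for sample, grp in inside.groupby("sample_id", sort=False):
            starts = grp["start"].clip(lower=arm_start).to_numpy()
            ends = grp["end"].clip(upper=arm_end).to_numpy()
            lengths = (ends - starts).astype(float)
            cn = grp["cn"].to_numpy(dtype=float)
            baf = grp["baf"].to_numpy(dtype=float)
            ccf = grp["ccf"].to_numpy(dtype=float)
            for direction, qual in (("gain", cn >= GAIN_CN), ("loss", cn <= LOSS_CN)):
                if not qual.any():
                    continue
                q_len = lengths[qual]
                if q_len.sum() <= 0:
                    continue
                basis = None
                if q_len.sum() / arm_len > broad_fraction:
                    basis = "broad"
                else:
                    for reg in regions.itertuples(index=False):
                        hits = (ends[qual] > int(reg.start)) & (starts[qual] < int(reg.end))
                        if hits.any():
                            basis = f"focal:{reg.name}"
                            break
                if basis is None:
                    continue
                wmean_cn = float(np.average(cn[qual], weights=q_len))
                if direction == "gain":
                    level = "high_gain" if wmean_cn >= HIGH_GAIN_CN else "gain"
                else:
                    level = "homo_loss" if wmean_cn <= HOMO_LOSS_CN else "loss"
                call_ccf = _weighted_median(ccf[qual], q_len)
                cls = clonality_class(call_ccf)
                if cls is None:
                    continue  # below the minor band: dropped entirely
                baf_q, w_q = baf[qual], q_len
                ok = ~np.isnan(baf_q)
                loh = bool(ok.any()
                           and np.average(baf_q[ok], weights=w_q[ok]) >= BAF_LOH)
                calls.append(ArmCall(str(sample), variable_name(direction, chrom, arm),
                                     chrom, arm, direction, level, basis,
                                     round(call_ccf, 4), cls, loh))

    return calls_frame(calls)


def calls_frame(calls: list[ArmCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.variable, c.chromosome, c.arm, c.direction, c.level,
          c.basis, c.ccf, c.clonality_class, c.loh) for c in calls],
        columns=["sample_id", "variable", "chromosome", "arm", "direction",
                 "level", "basis", "ccf", "clonality_class", "loh"])


def filter_major(calls: pd.DataFrame, min_ccf: float = 50.0) -> pd.DataFrame:
    """Keep only calls present in at least ``min_ccf``% of tumour cells
    (clonal + sub-clonal major events); input order preserved."""
    return calls[calls["ccf"] >= min_ccf].copy()
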