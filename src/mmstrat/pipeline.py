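"""End-to-end pipeline: simulate -> call -> matrix -> downstream analyses.

A single run seed fans out to per-stage sub-seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed order (simulate,
segments, ordination, group tests), so each stage is independently
reproducible. Every table written carries a leading comment line with the
configuration hash and seed; diagnostics are JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, cooccurrence, driverness, matrix as matrix_mod
from . import ordination, simulate as sim, stratify, survival

log = logging.getLogger("mmstrat")

ALL_STAGES = ("simulate", "call", "matrix", "cooccur", "ordinate", "drivers",
              "classify", "survive")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None          # GeneratorConfig fields or {"calibration": name}
    inputs: dict | None = None            # {"seg": ..., "tihg": ..., "clinical": ...}
    stages: tuple[str, ...] = ALL_STAGES
    ccf_threshold: float = 50.0
    landmark_months: float = 60.0
    nmds_dims: int = 2
    nmds_starts: int = 20

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs'")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 10 <= self.ccf_threshold <= 100:
            raise ValueError("ccf_threshold must lie in [10, 100]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"mmstrat config={config.hash()} seed={config.seed}"
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    stages = set(config.stages)
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_seg, seed_ord, seed_tests = (int(s.generate_state(1)[0] % (2 ** 31))
                                                for s in ss.spawn(4))

    seg = tihg = cohort = None
    stage = "setup"
    try:
        if config.simulate is not None and "simulate" in stages:
            stage = "simulate"
            block = dict(config.simulate or {})
            gen = sim.load_calibration(block.pop("calibration")) \
                if "calibration" in block else sim.GeneratorConfig()
            block.setdefault("seed", seed_sim)
            gen = sim.GeneratorConfig.from_dict({**gen.to_dict(), **block})
            patients = sim.generate_cohort(gen)
            segments = sim.emit_cohort_segments(patients, seed=seed_seg,
                                                focal_frac=gen.focal_frac)
            sim.write_cohort(patients, outdir, gen, segments)
            cohort = sim.cohort_frame(patients).set_index("patient_id")
            tihg = sim.tihg_frame(patients)
            seg = segments
            report["stages"]["simulate"] = {"patients": len(patients),
                                            "segments": len(segments)}
        elif config.inputs is not None:
            stage = "load"
            seg = calling.load_seg(config.inputs["seg"])
            tihg = matrix_mod.load_tihg(config.inputs["tihg"])
            if "clinical" in config.inputs:
                cohort = pd.read_csv(config.inputs["clinical"], sep="\t",
                                     comment="#").set_index("patient_id")
            report["stages"]["load"] = {"segments": len(seg), "patients": len(tihg)}

        calls = mat = labels = None
        if "call" in stages and seg is not None:
            stage = "call"
            calls = calling.call_arm_events(seg)
            major = calling.filter_major(calls, config.ccf_threshold)
            _write_tsv(major, outdir / "arm_calls.tsv", tag)
            report["stages"]["call"] = {"calls": len(calls),
                                        "calls_major": len(major),
                                        "calls_filtered": len(calls) - len(major)}

        if "matrix" in stages and calls is not None and tihg is not None:
            stage = "matrix"
            patients_idx = list(tihg["patient_id"].astype(str))
            mat = matrix_mod.build_matrix(calls, tihg, patients=patients_idx,
                                          min_ccf=config.ccf_threshold)
            _write_tsv(mat.clonality, outdir / "matrix.tsv", tag, index=True)
            report["stages"]["matrix"] = {"patients": len(mat.patients),
                                          "columns": len(mat.variables)}

        if "cooccur" in stages and mat is not None:
            stage = "cooccur"
            pear = cooccurrence.pearson_cooccurrence(mat)
            jac = cooccurrence.jaccard_cooccurrence(mat)
            _write_tsv(pear.long_format(), outdir / "cooccurrence_pearson.tsv", tag)
            _write_tsv(jac.long_format(), outdir / "cooccurrence_jaccard.tsv", tag)
            report["stages"]["cooccur"] = {"pairs": len(pear.long_format())}

        if "ordinate" in stages and mat is not None:
            stage = "ordinate"
            nmds = ordination.NMDS(n_components=config.nmds_dims,
                                   n_starts=config.nmds_starts,
                                   random_state=seed_ord)
            coords = pd.DataFrame(nmds.fit_transform(mat.binary.to_numpy()),
                                  index=mat.patients,
                                  columns=[f"NMDS{i+1}" for i in range(config.nmds_dims)])
            _write_tsv(coords, outdir / "nmds_coordinates.tsv", tag, index=True)
            (outdir / "nmds_diagnostics.json").write_text(json.dumps({
                "tag": tag, "stress": nmds.stress_, "n_iter": nmds.n_iter_,
                "converged": nmds.converged_, "n_starts": config.nmds_starts}))
            report["stages"]["ordinate"] = {"stress": nmds.stress_}

        if "drivers" in stages and mat is not None:
            stage = "drivers"
            drivers = driverness.rank_drivers(mat)
            _write_tsv(drivers, outdir / "drivers.tsv", tag, index=True)
            report["stages"]["drivers"] = {
                "top4": drivers.head(4)["variable"].tolist()}

        if "classify" in stages and mat is not None and tihg is not None:
            stage = "classify"
            labels = stratify.classify_1q13(mat)
            tihg_type = _tihg_type_series(tihg).reindex(labels.index)
            per_arm = driverness.complexity_per_arm(
                calls, tihg, patients=list(labels.index),
                min_ccf=config.ccf_threshold)
            strat = stratify.stratified_frame(
                mat, tihg_type, driverness.complexity_merged(mat), per_arm)
            _write_tsv(strat, outdir / "stratified.tsv", tag, index=True)
            counts = stratify.label_counts(labels)
            comp_test = stratify.group_complexity_test(per_arm, labels,
                                                       seed=seed_tests)
            (outdir / "group_tests.json").write_text(json.dumps({
                "tag": tag, "label_counts": counts,
                "kruskal_h": comp_test.kruskal_h, "kruskal_p": comp_test.kruskal_p,
                "medians": comp_test.medians}))
            report["stages"]["classify"] = {
                "patients_classified": sum(counts[k] for k in stratify.LABELS),
                **counts}

        if "survive" in stages and cohort is not None and labels is not None:
            stage = "survive"
            grouped = labels.reindex(cohort.index)
            km = survival.km_estimate(cohort["pfs_months"],
                                      cohort["pfs_event"].astype(bool), grouped,
                                      landmarks=(config.landmark_months,))
            _write_tsv(km.landmark, outdir / "km_landmark_pfs.tsv", tag, index=True)
            lr = survival.logrank(cohort["pfs_months"],
                                  cohort["pfs_event"].astype(bool), grouped)
            design, covs = survival.model_design(cohort, grouped, model=1)
            fit = survival.cox_fit(design, "pfs_months", "pfs_event", covs,
                                   strata="stratum" if "stratum" in design else None)
            _write_tsv(fit.summary, outdir / "cox_model1_pfs.tsv", tag, index=True)
            report["stages"]["survive"] = {
                "logrank_p": lr.p,
                "hr_1q13_pos": float(fit.summary.at["cls_1q13_pos", "HR"])}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed in {outdir}") from exc

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


def _tihg_type_series(tihg: pd.DataFrame) -> pd.Series:
    """Collapse the 0/1 translocation flags to one partner name (or None)."""
    t = tihg.set_index("patient_id") if "patient_id" in tihg.columns else tihg
    from .catalogue import TIHG_TYPES
    flags = t[list(TIHG_TYPES)].astype(int)
    out = pd.Series(None, index=flags.index, dtype=object, name="tihg_type")
    for name in TIHG_TYPES:
        out[(flags[name] == 1) & out.isna()] = name
    return out
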