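"""Synthetic newly-diagnosed multiple myeloma cohort generator.

The generator emulates the joint structure the downstream stages assume:

* a coupled (gain 1q, loss 13q) pair drawn from a 2x2 table with fixed
  marginals and odds ratio (Plackett construction), defining the 1q&13 class;
* hyperdiploidy (HD) drawn conditionally on that class (HD is depleted in
  1q/13 and enriched in 1q&13- patients, which is what produces the per-class
  genomic-complexity ordering seen in real cohorts);
* an IgH translocation drawn conditionally on HD (near mutual exclusivity),
  with the five partners split at their relative FISH frequencies;
* per-class passenger arm events, plus independent sub-clonal minor events
  (CCF 10-50) so the >=50% clonality filter is exercised;
* Weibull proportional-hazards PFS/OS with class log-hazard-ratios and
  independent exponential censoring.

Calibration constants ship as YAML files ("bo", n=513, 60-month landmark;
"commpass", n=752, 36-month landmark); the BO file is tuned so the cohort
reproduces the printed prevalences (loss 13q 44%, HD 57.5%, t-IgH 48%,
1q&13+ ~26%, high-gain 1q 6.8%) and 5-year PFS of 22/37/47% by class.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalogue import (ACROCENTRIC, CATALOGUE, CNA_VARIABLES, HD_CHROMOSOMES,
                        TIHG_TYPES, arm_table, focal_regions, parse_variable,
                        variable_name)

LABELS = ("1q&13+", "1q/13", "1q&13-")

#: Arms contributed by a trisomy of each HD chromosome (acrocentrics: q only).
_ODD_CHROMS = tuple(sorted(HD_CHROMOSOMES))
_ODD_ARMS = {c: (("p", "q") if c not in ACROCENTRIC else ("q",)) for c in _ODD_CHROMS}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class TruthEvent:
    """One true alteration of a synthetic patient."""
    name: str          # "Amp 9p" style arm variable name
    ccf: float         # cancer cell fraction, % in (0, 100]
    level: str         # gain | high_gain | loss | homo_loss

    @property
    def direction(self) -> str:
        return "gain" if self.level in ("gain", "high_gain") else "loss"


@dataclass
class SyntheticPatient:
    patient_id: str
    alterations: list[TruthEvent]
    tihg_type: str | None
    label: str                       # 1q&13 class implied by >=50% CCF events
    hd: bool
    stratum: str
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool

    def major_alterations(self) -> set[str]:
        """Names of alterations present in at least half the tumour cells."""
        return {ev.name for ev in self.alterations if ev.ccf >= 50}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the BO calibration. Probabilities are plain fractions;
    survival times are months.
    """

    n_patients: int = 513
    seed: int = 0
    # prevalence of the two index lesions (post >=50% CCF filter) + coupling
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"Amp 1q": 0.365, "Del 13q": 0.44})
    or_1q_13q: float = 5.685
    # HD conditional on the 1q&13 class; t-IgH conditional on HD
    hd_given_class: dict[str, float] = field(
        default_factory=lambda: {"1q&13+": 0.5525, "1q/13": 0.25, "1q&13-": 0.80})
    tihg_given_hd: float = 0.167
    tihg_given_no_hd: float = 0.9035
    tihg_partner_probs: dict[str, float] = field(
        default_factory=lambda: {"t(11;14)": 0.4416, "t(4;14)": 0.4156,
                                 "t(14;16)": 0.0983, "t(14;20)": 0.0315,
                                 "t(6;14)": 0.0130})
    # trisomy rates per odd chromosome given HD (>=2 distinct chromosomes
    # enforced by redraw) and the stray odd-gain rate for non-HD patients
    odd_gain_probs: dict[int, float] = field(
        default_factory=lambda: {19: 0.390, 9: 0.383, 15: 0.371, 11: 0.323,
                                 5: 0.321, 3: 0.309, 7: 0.244, 21: 0.191})
    odd_gain_rate_no_hd: float = 0.10
    # per-variable passenger rates by class and the sub-clonal minor rate
    passenger_rates: dict[str, float] = field(
        default_factory=lambda: {"1q&13+": 0.030, "1q/13": 0.009, "1q&13-": 0.012})
    # heterogeneity of passenger arms: per-variable multiplicative weights
    # follow a geometric ladder with this max/min ratio (mean 1, catalogue
    # order), emulating the uneven arm-event frequencies of real cohorts
    passenger_weight_spread: float = 6.0
    minor_rate: float = 0.02
    # clonality classes: clonal CCF (90,100], sub-clonal major [50,90],
    # sub-clonal minor [10,50); detectable events use the renormalised
    # (clonal, major) mix, minor events are generated at minor_rate
    clonality_mix: tuple[float, float, float] = (0.70, 0.20, 0.10)
    high_gain_frac_1q: float = 0.1863
    high_gain_frac_other: float = 0.05
    homo_loss_frac: float = 0.02
    focal_frac: float = 0.10
    # Weibull proportional-hazards outcome model
    weibull_shape: float = 1.2
    pfs_scale_months: float = 75.830
    os_scale_months: float = 191.463
    log_hr_pfs: dict[str, float] = field(
        default_factory=lambda: {"1q&13+": 0.69617, "1q/13": 0.27524})
    log_hr_os: dict[str, float] = field(
        default_factory=lambda: {"1q&13+": 1.02596, "1q/13": 0.19218})
    censor_rate: float = 0.008          # per-month exponential censoring
    cohort_strata: dict[str, float] = field(
        default_factory=lambda: {"BO-1": 0.7227, "BO-2": 0.1406, "BO-3": 0.1367})
    landmark_months: int = 60

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.or_1q_13q <= 0:
            raise ConfigError("or_1q_13q must be > 0")
        for fname in ("tihg_given_hd", "tihg_given_no_hd", "odd_gain_rate_no_hd",
                      "minor_rate", "high_gain_frac_1q", "high_gain_frac_other",
                      "homo_loss_frac", "focal_frac"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{fname} must be a probability in [0, 1]")
        for fname in ("prevalence", "hd_given_class", "tihg_partner_probs",
                      "passenger_rates", "odd_gain_probs", "cohort_strata"):
            for k, v in getattr(self, fname).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{fname}[{k!r}] must be in [0, 1]")
        for fname in ("tihg_partner_probs", "cohort_strata"):
            total = sum(getattr(self, fname).values())
            if getattr(self, fname) and abs(total - 1.0) > 1e-6:
                raise ConfigError(f"{fname} must sum to 1 (got {total:.6f})")
        if abs(sum(self.clonality_mix) - 1.0) > 1e-6:
            raise ConfigError("clonality_mix must sum to 1")
        if set(self.hd_given_class) != set(LABELS):
            raise ConfigError(f"hd_given_class must map exactly {LABELS}")
        if set(self.passenger_rates) != set(LABELS):
            raise ConfigError(f"passenger_rates must map exactly {LABELS}")
        for key in ("Amp 1q", "Del 13q"):
            if key not in self.prevalence:
                raise ConfigError(f"prevalence must include {key!r}")
        if any(c < 0 for c in self.clonality_mix):
            raise ConfigError("clonality_mix entries must be >= 0")
        if self.weibull_shape <= 0 or self.pfs_scale_months <= 0 or self.os_scale_months <= 0:
            raise ConfigError("weibull_shape and scale months must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clonality_mix"] = list(self.clonality_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "clonality_mix" in d:
            d["clonality_mix"] = tuple(d["clonality_mix"])
        if "odd_gain_probs" in d:
            d["odd_gain_probs"] = {int(k): float(v) for k, v in d["odd_gain_probs"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_calibration(name: str) -> GeneratorConfig:
    """Load a shipped calibration ("bo" or "commpass") or a YAML file path."""
    shipped = {"bo", "commpass"}
    if name in shipped:
        ref = resources.files("mmstrat").joinpath(f"calibrations/{name}.yaml")
        return GeneratorConfig.from_dict(yaml.safe_load(ref.read_text()))
    path = Path(name)
    if path.exists():
        return GeneratorConfig.from_yaml(path)
    raise ConfigError(f"unknown calibration {name!r}: not one of {sorted(shipped)} "
                      "and not an existing file")


def plackett_cell_probabilities(p1: float, p2: float, odds_ratio: float) -> np.ndarray:
    """Joint 2x2 cell probabilities [p11, p10, p01, p00] with given marginals
    and odds ratio (Plackett construction)."""
    if odds_ratio == 1.0:
        p11 = p1 * p2
    else:
        s = 1.0 + (p1 + p2) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p1 * p2
        p11 = (s - np.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = np.array([p11, p10, p01, p00])
    if np.any(cells < -1e-12):
        raise ConfigError("or_1q_13q is incompatible with the prevalence marginals")
    return np.clip(cells, 0.0, 1.0)


def passenger_weights(k: int, spread: float) -> np.ndarray:
    """Geometric ladder of k per-variable weights with max/min ratio
    ``spread``, normalised to mean 1."""
    if spread <= 0:
        raise ConfigError("passenger_weight_spread must be > 0")
    w = np.geomspace(1.0, spread, k)
    return w / w.mean()


def _draw_ccf_major(rng: np.random.Generator, shape, mix: tuple[float, float, float]):
    """CCF for detectable events: clonal (90,100] vs sub-clonal major [50,90]."""
    p_clonal = mix[0] / (mix[0] + mix[1])
    clonal = rng.random(shape) < p_clonal
    u = rng.random(shape)
    return np.where(clonal, 90.0 + 10.0 * u, 50.0 + 40.0 * u)


def generate_cohort(config: GeneratorConfig) -> list[SyntheticPatient]:
    """Draw a full synthetic cohort. Reproducible: identical config (including
    seed) yields an identical cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # (gain1q, loss13q) pair from the 2x2 Plackett table
    cells = plackett_cell_probabilities(config.prevalence["Amp 1q"],
                                        config.prevalence["Del 13q"],
                                        config.or_1q_13q)
    cell_idx = rng.choice(4, size=n, p=cells)
    has_1q = np.isin(cell_idx, (0, 1))
    has_13q = np.isin(cell_idx, (0, 2))
    labels = np.where(has_1q & has_13q, "1q&13+",
                      np.where(~has_1q & ~has_13q, "1q&13-", "1q/13"))

    # HD | class, then t-IgH | HD
    p_hd = np.vectorize(config.hd_given_class.get)(labels)
    hd = rng.random(n) < p_hd
    p_t = np.where(hd, config.tihg_given_hd, config.tihg_given_no_hd)
    has_t = rng.random(n) < p_t
    partners = list(config.tihg_partner_probs)
    partner_p = np.array([config.tihg_partner_probs[k] for k in partners])
    partner_idx = rng.choice(len(partners), size=n, p=partner_p / partner_p.sum())

    # odd-chromosome trisomies: HD patients redraw until >=2 distinct
    # chromosomes; non-HD patients may carry one stray odd gain
    odd_p = np.array([config.odd_gain_probs.get(c, 0.0) for c in _ODD_CHROMS])
    odd = rng.random((n, len(_ODD_CHROMS))) < odd_p
    for _ in range(1000):
        bad = hd & (odd.sum(axis=1) < 2)
        if not bad.any():
            break
        odd[bad] = rng.random((int(bad.sum()), len(_ODD_CHROMS))) < odd_p
    else:  # pragma: no cover - odds of not terminating are astronomically small
        raise RuntimeError("failed to draw >=2 odd trisomies for HD patients")
    stray = (~hd) & (rng.random(n) < config.odd_gain_rate_no_hd)
    stray_chrom = rng.integers(0, len(_ODD_CHROMS), size=n)
    odd[~hd] = False
    odd[stray, stray_chrom[stray]] = True

    # passenger arm events: per-class rate x per-variable weight ladder
    passenger_vars = [v for v in CNA_VARIABLES if v not in ("Amp 1q", "Del 13q")]
    weights = passenger_weights(len(passenger_vars), config.passenger_weight_spread)
    p_pass = np.vectorize(config.passenger_rates.get)(labels)
    passengers = rng.random((n, len(passenger_vars))) \
        < np.clip(p_pass[:, None] * weights[None, :], 0.0, 1.0)

    # clonality, level and minor-event draws (all length-n, then masked)
    ccf_1q = _draw_ccf_major(rng, n, config.clonality_mix)
    ccf_13q = _draw_ccf_major(rng, n, config.clonality_mix)
    ccf_odd = _draw_ccf_major(rng, (n, len(_ODD_CHROMS)), config.clonality_mix)
    ccf_pass = _draw_ccf_major(rng, (n, len(passenger_vars)), config.clonality_mix)
    hg_1q = rng.random(n) < config.high_gain_frac_1q
    hg_odd = rng.random((n, len(_ODD_CHROMS))) < config.high_gain_frac_other
    hg_pass = rng.random((n, len(passenger_vars))) < config.high_gain_frac_other
    homo_pass = rng.random((n, len(passenger_vars))) < config.homo_loss_frac
    homo_13q = rng.random(n) < config.homo_loss_frac

    minor = rng.random((n, len(CNA_VARIABLES))) < config.minor_rate
    ccf_minor = 10.0 + 40.0 * rng.random((n, len(CNA_VARIABLES)))
    hg_minor = rng.random((n, len(CNA_VARIABLES))) < config.high_gain_frac_other

    strata_names = list(config.cohort_strata)
    strata_p = np.array([config.cohort_strata[k] for k in strata_names])
    stratum_idx = rng.choice(len(strata_names), size=n, p=strata_p / strata_p.sum())

    # Weibull proportional hazards: T = scale * (-log U / exp(beta x))^(1/shape)
    def _survival(scale: float, log_hr: dict[str, float]):
        lp = np.array([log_hr.get(lab, 0.0) for lab in labels])
        u = rng.random(n)
        t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.weibull_shape)
        if config.censor_rate > 0:
            c = rng.exponential(1.0 / config.censor_rate, size=n)
        else:
            c = np.full(n, np.inf)
        time = np.minimum(t_event, c)
        return np.maximum(time, 1e-3), t_event <= c

    pfs_t, pfs_e = _survival(config.pfs_scale_months, config.log_hr_pfs)
    os_t, os_e = _survival(config.os_scale_months, config.log_hr_os)

    gain_level = lambda high: "high_gain" if high else "gain"
    loss_level = lambda homo: "homo_loss" if homo else "loss"
    pass_dir = ["gain" if v.startswith("Amp") else "loss" for v in passenger_vars]

    patients: list[SyntheticPatient] = []
    width = len(str(n))
    for i in range(n):
        events: dict[str, TruthEvent] = {}

        def _add(name: str, ccf: float, level: str) -> None:
            prev = events.get(name)
            if prev is None or ccf > prev.ccf:
                events[name] = TruthEvent(name, float(ccf), level)

        if has_1q[i]:
            _add("Amp 1q", ccf_1q[i], gain_level(hg_1q[i]))
        if has_13q[i]:
            _add("Del 13q", ccf_13q[i], loss_level(homo_13q[i]))
        for j, chrom in enumerate(_ODD_CHROMS):
            if odd[i, j]:
                for arm in _ODD_ARMS[chrom]:
                    _add(variable_name("gain", chrom, arm), ccf_odd[i, j],
                         gain_level(hg_odd[i, j]))
        for j, var in enumerate(passenger_vars):
            if passengers[i, j]:
                level = (gain_level(hg_pass[i, j]) if pass_dir[j] == "gain"
                         else loss_level(homo_pass[i, j]))
                _add(var, ccf_pass[i, j], level)
        for j, var in enumerate(CNA_VARIABLES):
            if minor[i, j] and var not in events:
                direction, _, _ = parse_variable(var)
                level = (gain_level(hg_minor[i, j]) if direction == "gain"
                         else "loss")
                events[var] = TruthEvent(var, float(ccf_minor[i, j]), level)

        patients.append(SyntheticPatient(
            patient_id=f"P{i + 1:0{width}d}",
            alterations=sorted(events.values(), key=lambda e: e.name),
            tihg_type=partners[partner_idx[i]] if has_t[i] else None,
            label=str(labels[i]),
            hd=bool(hd[i]),
            stratum=strata_names[stratum_idx[i]],
            pfs_months=float(pfs_t[i]), pfs_event=bool(pfs_e[i]),
            os_months=float(os_t[i]), os_event=bool(os_e[i]),
        ))
    return patients


# ---------------------------------------------------------------------------
# segment emission

def emit_segments(patient: SyntheticPatient,
                  arms: pd.DataFrame | None = None,
                  focal: pd.DataFrame | None = None,
                  rng: np.random.Generator | None = None,
                  focal_frac: float = 0.0) -> pd.DataFrame:
    """Render a patient's true alterations as purity-corrected CN segments.

    Unaltered arms emit a single diploid (CN 2.0) segment spanning the arm.
    Altered arms emit a qualifying segment: broad events cover >25% of the
    arm, focal events (probability ``focal_frac`` where the arm hosts a focal
    region) cover only that region. CCF is copied from the truth record.
    Segment coordinates are 0-based half-open.
    """
    if arms is None:
        arms = arm_table()
    if focal is None:
        focal = focal_regions()
    if rng is None:
        rng = np.random.default_rng(0)

    by_arm: dict[tuple[int, str], list[TruthEvent]] = {}
    arm_keys = {(int(r.chromosome), str(r.arm)) for r in arms.itertuples(index=False)}
    for ev in patient.alterations:
        _, chrom, arm = parse_variable(ev.name)  # raises listing the catalogue
        if (chrom, arm) not in arm_keys:
            raise ValueError(f"variable {ev.name!r} maps to arm {chrom}{arm} "
                             "absent from the arm table")
        by_arm.setdefault((chrom, arm), []).append(ev)

    cn_bands = {"gain": (2.3, 3.3), "high_gain": (3.45, 4.8),
                "loss": (1.0, 1.7), "homo_loss": (0.05, 0.55)}
    rows: list[tuple] = []

    def _baf(level: str) -> float:
        if level in ("loss", "homo_loss"):
            return float(rng.uniform(0.85, 1.0))
        return float(rng.uniform(0.58, 0.72))

    for r in arms.itertuples(index=False):
        chrom, arm = int(r.chromosome), str(r.arm)
        s, e = int(r.start), int(r.end)
        length = e - s
        events = by_arm.get((chrom, arm), [])
        if not events:
            rows.append((patient.patient_id, chrom, s, e, 2.0, 0.5, 100.0))
            continue
        arm_focal = focal[(focal["chromosome"] == chrom) & (focal["arm"] == arm)]
        spans: list[tuple[int, int, float, float, float]] = []
        for k, ev in enumerate(sorted(events, key=lambda x: x.name)):
            cn = float(rng.uniform(*cn_bands[ev.level]))
            use_focal = (len(events) == 1 and len(arm_focal) > 0
                         and rng.random() < focal_frac)
            if use_focal:
                reg = arm_focal.iloc[int(rng.integers(0, len(arm_focal)))]
                fs, fe = int(reg["start"]), int(reg["end"])
            else:
                frac = float(rng.uniform(0.30, 0.45))
                span = int(frac * length)
                if k == 0:
                    fs, fe = s, s + span
                else:  # second event on the arm: anchor at the telomeric end
                    fs, fe = e - span, e
            spans.append((fs, fe, cn, _baf(ev.level), ev.ccf))
        spans.sort()
        pos = s
        for fs, fe, cn, baf, ccf in spans:
            if fs > pos:
                rows.append((patient.patient_id, chrom, pos, fs, 2.0, 0.5, 100.0))
            rows.append((patient.patient_id, chrom, fs, fe, round(cn, 4),
                         round(baf, 4), round(ccf, 4)))
            pos = fe
        if pos < e:
            rows.append((patient.patient_id, chrom, pos, e, 2.0, 0.5, 100.0))

    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start", "end",
                                       "cn", "baf", "ccf"])


def emit_cohort_segments(patients: list[SyntheticPatient],
                         arms: pd.DataFrame | None = None,
                         focal: pd.DataFrame | None = None,
                         seed: int = 0,
                         focal_frac: float = 0.0) -> pd.DataFrame:
    """Emit segments for a whole cohort with per-patient derived seeds."""
    if arms is None:
        arms = arm_table()
    children = np.random.SeedSequence(seed).spawn(len(patients))
    frames = [emit_segments(p, arms, focal, np.random.default_rng(ss), focal_frac)
              for p, ss in zip(patients, children)]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# serialisation

def cohort_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """One row per patient: id, label, tihg_type, survival, stratum."""
    return pd.DataFrame({
        "patient_id": [p.patient_id for p in patients],
        "label": [p.label for p in patients],
        "tihg_type": [p.tihg_type or "none" for p in patients],
        "hd": [int(p.hd) for p in patients],
        "pfs_months": [round(p.pfs_months, 4) for p in patients],
        "pfs_event": [int(p.pfs_event) for p in patients],
        "os_months": [round(p.os_months, 4) for p in patients],
        "os_event": [int(p.os_event) for p in patients],
        "stratum": [p.stratum for p in patients],
    })


def alterations_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Long-format truth alterations: patient, variable, ccf, level."""
    rows = [(p.patient_id, ev.name, round(ev.ccf, 4), ev.level)
            for p in patients for ev in p.alterations]
    return pd.DataFrame(rows, columns=["patient_id", "variable", "ccf", "level"])


def tihg_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """FISH-style translocation table: patient plus one 0/1 flag per partner."""
    data = {"patient_id": [p.patient_id for p in patients]}
    for t in TIHG_TYPES:
        data[t] = [int(p.tihg_type == t) for p in patients]
    return pd.DataFrame(data)


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write segments as SEG-like TSV (1-based inclusive coordinates)."""
    out = segments.copy()
    out["start"] = out["start"] + 1  # half-open 0-based -> 1-based inclusive
    out.columns = ["Sample", "Chromosome", "Start", "End", "CN", "BAF", "CCF"]
    out.to_csv(path, sep="\t", index=False)


def write_cohort(patients: list[SyntheticPatient], outdir,
                 config: GeneratorConfig | None = None,
                 segments: pd.DataFrame | None = None) -> dict[str, str]:
    """Write cohort.tsv, alterations.tsv, tihg.tsv, truth.json (and seg.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    cohort_frame(patients).to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    paths["cohort"] = str(outdir / "cohort.tsv")
    alterations_frame(patients).to_csv(outdir / "alterations.tsv", sep="\t", index=False)
    paths["alterations"] = str(outdir / "alterations.tsv")
    tihg_frame(patients).to_csv(outdir / "tihg.tsv", sep="\t", index=False)
    paths["tihg"] = str(outdir / "tihg.tsv")
    truth = {
        "config": config.to_dict() if config is not None else None,
        "patients": [{
            "patient_id": p.patient_id, "label": p.label,
            "tihg_type": p.tihg_type, "hd": p.hd, "stratum": p.stratum,
            "alterations": [[e.name, round(e.ccf, 4), e.level] for e in p.alterations],
        } for p in patients],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = str(outdir / "truth.json")
    if segments is not None:
        write_seg(segments, outdir / "seg.tsv")
        paths["seg"] = str(outdir / "seg.tsv")
    return paths
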