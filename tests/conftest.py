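"""Shared fixtures: the calibrated seed-42 cohort run once per session
through the full segment -> call -> matrix path, plus small toy tables."""

import numpy as np
import pandas as pd
import pytest

from mmstrat import calling, matrix as matrix_mod, simulate as sim


@pytest.fixture(scope="session")
def bo_config():
    cfg = sim.load_calibration("bo")
    return sim.GeneratorConfig.from_dict({**cfg.to_dict(), "seed": 42})


@pytest.fixture(scope="session")
def bo_patients(bo_config):
    return sim.generate_cohort(bo_config)


@pytest.fixture(scope="session")
def bo_segments(bo_patients, bo_config):
    return sim.emit_cohort_segments(bo_patients, seed=1042,
                                    focal_frac=bo_config.focal_frac)


@pytest.fixture(scope="session")
def bo_calls(bo_segments):
    return calling.call_arm_events(bo_segments)


@pytest.fixture(scope="session")
def bo_major_calls(bo_calls):
    return calling.filter_major(bo_calls)


@pytest.fixture(scope="session")
def bo_tihg(bo_patients):
    return sim.tihg_frame(bo_patients)


@pytest.fixture(scope="session")
def bo_matrix(bo_major_calls, bo_tihg, bo_patients):
    return matrix_mod.build_matrix(bo_major_calls, bo_tihg,
                                   patients=[p.patient_id for p in bo_patients])


@pytest.fixture(scope="session")
def bo_cohort_frame(bo_patients):
    return sim.cohort_frame(bo_patients).set_index("patient_id")


def truth_matrix(patients):
    """Alteration matrix straight from generator truth (bypasses segments);
    equivalence with the called path is itself covered by a round-trip test."""
    from mmstrat.catalogue import CATALOGUE, HD_CHROMOSOMES, parse_variable
    rows = {}
    for p in patients:
        row = dict.fromkeys(CATALOGUE, 0.0)
        odd_ccfs = []
        for ev in p.alterations:
            if ev.ccf < 50:
                continue
            direction, chrom, _ = parse_variable(ev.name)
            if direction == "gain" and chrom in HD_CHROMOSOMES:
                odd_ccfs.append((chrom, ev.ccf))
                continue
            row[ev.name] = max(row[ev.name], ev.ccf)
        arms = [c for c, _ in odd_ccfs]
        if len(odd_ccfs) >= 2 and len(set(arms)) >= 2:
            row["HD"] = max(c for _, c in odd_ccfs)
        row["t-IgH"] = 100.0 if p.tihg_type else 0.0
        rows[p.patient_id] = row
    clon = pd.DataFrame.from_dict(rows, orient="index")[list(CATALOGUE)]
    clon.index.name = "patient_id"
    return matrix_mod.AlterationMatrix(clon, (clon > 0).mean(axis=0), "fixed")


@pytest.fixture
def toy_arms():
    """Two tiny arms (10 kb each) for exhaustive per-base checks."""
    return pd.DataFrame({
        "chromosome": [1, 1, 13],
        "arm": ["p", "q", "q"],
        "start": [0, 12000, 2000],
        "end": [10000, 22000, 12000],
        "acrocentric": [False, False, True],
    })


@pytest.fixture
def toy_focal():
    return pd.DataFrame({
        "name": ["RB1toy"], "chromosome": [13], "arm": ["q"],
        "start": [5000], "end": [5400],
    })


def seg_frame(rows):
    """rows: (sample, chrom, start, end, cn, baf, ccf) in internal 0-based."""
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start",
                                       "end", "cn", "baf", "ccf"])
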