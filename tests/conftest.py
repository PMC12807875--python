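import numpy as np
import pandas as pd
import pytest

import xiescape as xe


@pytest.fixture(scope="session")
def sim():
    """One default synthetic clone (study-design defaults, fixed seed)."""
    return xe.simulate_dataset(xe.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sim_deep():
    """High-depth clone used for recovery checks."""
    return xe.simulate_dataset(xe.SimulationConfig(seed=42, depth_mean=500.0))


@pytest.fixture(scope="session")
def pipeline_out(sim_deep):
    return xe.run_pipeline(
        sim_deep.counts, sim_deep.sheet, annotation=sim_deep.annotation,
        study_matrix=sim_deep.study_matrix, seed=7,
    )


@pytest.fixture()
def small_counts():
    """Three genes x two samples, hand-checkable numbers."""
    return pd.DataFrame({
        "gene_id": ["g1", "g1", "g2", "g2", "g3", "g3"],
        "sample_id": ["s1", "s2", "s1", "s2", "s1", "s2"],
        "count_hap1": [30, 5, 0, 2, 50, 40],
        "count_hap2": [70, 5, 0, 18, 50, 60],
        "chromosome": ["X"] * 6,
    })


@pytest.fixture()
def small_sheet():
    sheet = pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "dox_days": ["0", "3"],
        "washout_days": ["0", "0"],
        "auxin": ["false", "false"],
        "replicate": ["1", "1"],
        "xi_haplotype": ["hap1", "hap1"],
    })
    from xiescape.io import validate_sample_sheet
    return validate_sample_sheet(sheet)


def assert_frames_equal(a: pd.DataFrame, b: pd.DataFrame, **kwargs):
    pd.testing.assert_frame_equal(
        a.reset_index(drop=True), b.reset_index(drop=True), **kwargs
    )
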