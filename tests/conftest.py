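import numpy as np
import pandas as pd
import pytest

import metaboresponse as mr


@pytest.fixture(scope="session")
def default_study():
    """One default-size simulated plasma study shared across read-only tests."""
    return mr.simulate_study(n_features=120, seed=11)


@pytest.fixture(scope="session")
def null_study():
    """No effects, moderate noise: calibration substrate."""
    return mr.simulate_study(
        n_features=150, seed=5,
        effect=mr.EffectSpec.null(),
    )


@pytest.fixture
def toy_tables(tmp_path):
    """4-sample, 3-feature toy study written as CSVs; returns the paths."""
    values = pd.DataFrame(
        {
            "FA1": [100.0, 200.0, 150.0, 75.0],
            "FA2": [10.0, 10.0, 20.0, 5.0],
            "FA3": [1.5, 3.0, 2.5, 2.5],
        },
        index=pd.Index(["s1b", "s1w", "s2b", "s2w"], name="sample_id"),
    )
    samples = pd.DataFrame(
        {
            "subject_id": ["S1", "S1", "S2", "S2"],
            "group": ["SAL", "SAL", "VLCD", "VLCD"],
            "timepoint": ["baseline", "week4", "baseline", "week4"],
            "biofluid": ["plasma"] * 4,
        },
        index=values.index,
    )
    ann = pd.DataFrame(
        {
            "platform": ["lipidRPCpos"] * 3,
            "metabolite_class": ["fatty acid"] * 3,
            "name": ["FA(16:0)", "FA(18:1)", "FA(24:0)"],
            "annotated": [True] * 3,
        },
        index=pd.Index(["FA1", "FA2", "FA3"], name="feature_id"),
    )
    clinical = pd.DataFrame(
        {
            "delta_weight": [-2.0, -8.0],
            "delta_fasting_glucose": [-0.1, -0.9],
            "delta_fasting_insulin": [-2.0, -20.0],
            "delta_triglycerides": [0.0, -0.4],
            "delta_total_cholesterol": [0.1, -0.5],
        },
        index=pd.Index(["S1", "S2"], name="subject_id"),
    )
    paths = {
        "feature_csv": tmp_path / "intensities.csv",
        "sample_csv": tmp_path / "samples.csv",
        "annotation_csv": tmp_path / "annotation.csv",
        "clinical_csv": tmp_path / "clinical.csv",
    }
    values.to_csv(paths["feature_csv"], index_label="sample_id")
    samples.to_csv(paths["sample_csv"], index_label="sample_id")
    ann.to_csv(paths["annotation_csv"], index_label="feature_id")
    clinical.to_csv(paths["clinical_csv"], index_label="subject_id")
    return paths
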