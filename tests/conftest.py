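"""Shared fixtures.

The expensive session fixtures build the default 500-sample synthetic
cohort (generator -> morphometrics -> transport oracle) and the five-seed
suite of trained models once, and share them across the evaluation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vnqi.model import (
    ChainSpec,
    FEATURES,
    evaluate,
    fit_baseline,
    fit_chain,
    split_dataset,
)
from vnqi.pipeline import build_dataset
from vnqi.synthetic import GeneratorConfig, VesselMask, generate_cohort

COHORT_MASTER_SEED = 1
SPLIT_SEED = 1
TRAIN_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def cohort_masks():
    """500 default-jitter masks plus provenance (the study cohort)."""
    return generate_cohort(GeneratorConfig(), 500, master_seed=COHORT_MASTER_SEED)


@pytest.fixture(scope="session")
def cohort_records(cohort_masks):
    """The labeled modeling table: six metrics + oracle oxy_v / oxy_t."""
    masks, prov = cohort_masks
    return build_dataset(masks, prov)


@pytest.fixture(scope="session")
def shared_split(cohort_records):
    """The single 80/20 split shared by all architecture evaluations."""
    return split_dataset(cohort_records, 0.8, seed=SPLIT_SEED)


@pytest.fixture(scope="session")
def five_seed_suite(cohort_records, shared_split):
    """Chained + key baselines trained for five seeds on the shared split.

    Returns a dict with per-seed held-out R^2 lists for the chained,
    true-oxy_v-augmented and morphology-only oxy_t architectures, plus the
    five fitted chains and their all-sample VNQI vectors.
    """
    train, test = shared_split
    Xte = test[FEATURES].to_numpy(dtype=float)
    X_all = cohort_records[FEATURES].to_numpy(dtype=float)
    out = {
        "chained_r2": [],
        "augmented_r2": [],
        "morphology_only_r2": [],
        "chains": [],
        "vnqi_all": [],
    }
    for seed in TRAIN_SEEDS:
        spec = ChainSpec(rng_seed=seed)
        chain = fit_chain(train, spec)
        out["chains"].append(chain)
        out["chained_r2"].append(evaluate(test["oxy_t"], chain.predict(Xte)).r2)
        aug = fit_baseline(train, "oxy_t_with_true_oxy_v", spec)
        out["augmented_r2"].append(
            evaluate(
                test["oxy_t"], aug.predict(Xte, oxy_v=test["oxy_v"].to_numpy())
            ).r2
        )
        solo = fit_baseline(train, "single_oxy_t", spec)
        out["morphology_only_r2"].append(evaluate(test["oxy_t"], solo.predict(Xte)).r2)
        out["vnqi_all"].append(chain.predict(X_all))
    return out


@pytest.fixture
def fast_spec():
    """Single-candidate training spec for cheap unit tests."""
    return ChainSpec(search_budget=2, rng_seed=0)


@pytest.fixture
def feature_table():
    """200 rows of synthetic feature values on realistic scales (no labels)."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.uniform(0.0, 1.0, (200, 6)), columns=FEATURES)
    df["total_vessel_length"] *= 1.0e4
    df["segment_count"] = (df["segment_count"] * 150).round()
    df["branchpoint_count"] = (df["branchpoint_count"] * 80).round()
    df["mean_segment_length"] = df["mean_segment_length"] * 150 + 20
    df["mean_segment_diameter"] = df["mean_segment_diameter"] * 25 + 8
    df.insert(0, "sample_id", [f"s{i:03d}" for i in range(len(df))])
    return df


def bar_mask(shape=(200, 200), row=99, col0=50, length=100, width=3, pitch=1.0):
    px = np.zeros(shape, dtype=np.uint8)
    px[row : row + width, col0 : col0 + length] = 1
    return VesselMask(px, pitch)
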