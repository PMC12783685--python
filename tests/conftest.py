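"""Shared synthetic fixtures.

Heavy fixtures are session-scoped so the normalization and resampling work is
done once per run.  Three study regimes recur:

* ``strong`` — steep dose response with large maximal effects: every
  supra-EC50 condition is far above the detectability margin, sub-EC50
  conditions are essentially null.  Used for recovery tests.
* ``zero`` — emax = 0 everywhere (treatment wells identical in law to DMSO),
  at the study's full 8-plate x 7-replica dimensions so per-condition mAP
  distributions are well-resolved.  Used for calibration tests.
* ``batchy`` — a single dose with the default batch-offset scales.  Used for
  batch-correction tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lcd import (
    GeneratorConfig,
    NormalizationPlan,
    PairScheme,
    activity_matrix,
    aggregate_to_well,
    generate_dataset,
    normalize,
)
from lcd.schema import METADATA_COLUMNS, ProfileTable


def make_profile_frame(rows: list[dict], feature_names=("f0", "f1")) -> pd.DataFrame:
    """Small hand-built profile DataFrame with schema defaults filled in."""
    defaults = {
        "Metadata_plate": "plate01",
        "Metadata_replica": "R1",
        "Metadata_well": "A01",
        "Metadata_fov": 1,
        "Metadata_timepoint_h": 20.0,
        "Metadata_compound": "DMSO",
        "Metadata_dose_uM": np.nan,
        "Metadata_moa": np.nan,
        "Metadata_role": "negative_control",
    }
    full = []
    for r in rows:
        rec = {**defaults, **r}
        if rec["Metadata_compound"] != "DMSO":
            rec.setdefault("Metadata_role", "treatment")
            if rec["Metadata_role"] == "negative_control":
                rec["Metadata_role"] = "treatment"
        full.append(rec)
    df = pd.DataFrame(full)
    return df[list(METADATA_COLUMNS) + [c for c in df.columns if c not in METADATA_COLUMNS]]


@pytest.fixture(scope="session")
def strong_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_moa=5,
        compounds_per_moa=2,
        n_plates=2,
        n_replicas=3,
        doses_uM=(0.156, 0.625, 2.5, 10.0),
        timepoints_h=(8.0, 20.0),
        D=32,
        emax_range=(6.0, 9.0),
        ec50_uM=0.3,
        hill=8.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def strong_dataset(strong_config):
    return generate_dataset(strong_config)


@pytest.fixture(scope="session")
def strong_wells(strong_dataset):
    profiles, _, _ = strong_dataset
    plan = NormalizationPlan(method="mad_harmony_fov", seed=1)
    return aggregate_to_well(normalize(profiles, plan))


@pytest.fixture(scope="session")
def strong_activity(strong_wells, strong_dataset):
    _, _, truth = strong_dataset
    calls, summary = activity_matrix(strong_wells, PairScheme(seed=1), truth=truth)
    return calls, summary


@pytest.fixture(scope="session")
def zero_config() -> GeneratorConfig:
    # study-scale plate/replica dimensions: 112 wells per condition
    return GeneratorConfig(
        n_moa=3,
        compounds_per_moa=2,
        n_plates=8,
        n_replicas=7,
        doses_uM=(0.625, 2.5),
        timepoints_h=(8.0, 20.0),
        D=32,
        emax_range=(0.0, 0.0),
        seed=1,
    )


@pytest.fixture(scope="session")
def zero_wells(zero_config):
    profiles, _, truth = generate_dataset(zero_config)
    plan = NormalizationPlan(method="mad_harmony_fov", seed=1)
    return aggregate_to_well(normalize(profiles, plan)), truth


@pytest.fixture(scope="session")
def batchy_profiles() -> ProfileTable:
    config = GeneratorConfig(
        n_moa=3,
        compounds_per_moa=2,
        n_plates=2,
        n_replicas=3,
        doses_uM=(2.5,),
        timepoints_h=(8.0, 20.0),
        D=32,
        emax_range=(2.0, 5.0),
        seed=3,
    )
    profiles, _, _ = generate_dataset(config)
    return profiles


@pytest.fixture(scope="session")
def moa_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_moa=10,
        compounds_per_moa=3,
        n_plates=2,
        n_replicas=3,
        doses_uM=(0.156, 0.625, 2.5, 10.0),
        timepoints_h=(10.0, 20.0),
        D=64,
        emax_range=(6.0, 9.0),
        ec50_uM=0.3,
        hill=8.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def moa_dataset(moa_config):
    profiles, counts, truth = generate_dataset(moa_config)
    plan = NormalizationPlan(method="mad_harmony_fov", seed=7)
    wells = aggregate_to_well(normalize(profiles, plan))
    calls, _ = activity_matrix(wells, PairScheme(seed=7))
    return wells, calls, truth
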