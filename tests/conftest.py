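"""Shared fixtures: hand-built toy cohorts and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radpool import Cohort, FeatureSchema, GeneratorConfig, simulate_cohort


def build_cohort(patients, times=None, events=None,
                 additive=("siz",), intensive=("txa", "txb"),
                 extra_outcome_cols=None) -> Cohort:
    """Construct a cohort from explicit per-patient tumor tuples.

    ``patients`` maps patient id -> list of (volume, feature dict); feature
    dicts must cover every additive+intensive feature name.
    """
    rows = []
    for pid, tumors in patients.items():
        for j, (vol, feats) in enumerate(tumors):
            row = {"patient_id": pid, "tumor_id": f"{pid}_T{j:02d}",
                   "volume_cc": vol}
            row.update(feats)
            rows.append(row)
    names = list(additive) + list(intensive)
    tumors_df = pd.DataFrame(rows)[["patient_id", "tumor_id", "volume_cc"] + names]
    pids = list(patients)
    outcomes = pd.DataFrame({
        "patient_id": pids,
        "time_months": times if times is not None else np.arange(1.0, len(pids) + 1),
        "event": events if events is not None else [1] * len(pids),
    })
    if extra_outcome_cols:
        for col, vals in extra_outcome_cols.items():
            outcomes[col] = vals
    schema = FeatureSchema.from_dict(
        {**{a: "additive" for a in additive},
         **{i: "intensive" for i in intensive}})
    return Cohort(tumors_df, outcomes, schema)


def random_cohort(rng, n_patients=20, max_tumors=6, n_additive=1, n_intensive=3):
    """Random multifocal cohort for property-style tests."""
    additive = [f"add_{i}" for i in range(n_additive)]
    intensive = [f"int_{i}" for i in range(n_intensive)]
    patients = {}
    for i in range(n_patients):
        count = int(rng.integers(1, max_tumors + 1))
        tumors = []
        for _ in range(count):
            feats = {f: float(rng.standard_normal()) for f in additive + intensive}
            tumors.append((float(rng.lognormal(-1.5, 1.0)), feats))
        patients[f"P{i:03d}"] = tumors
    times = np.round(rng.uniform(1, 40, n_patients), 1)
    events = rng.integers(0, 2, n_patients)
    if events.sum() < 2:
        events[:2] = 1
    return build_cohort(patients, times=times, events=events,
                        additive=additive, intensive=intensive)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-shaped cohort: 831 patients."""
    return simulate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for distributional checks of the generator."""
    return simulate_cohort(GeneratorConfig(n_patients=10_000, seed=7))
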