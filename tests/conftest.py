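"""Shared fixtures: a small simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rosterits import RunConfig, TruthTable, SegmentTruth
from rosterits.outcomes import assemble_tables
from rosterits.pipeline import build_cohort
from rosterits.simclaims import simulate_dataset


def small_config(**overrides) -> RunConfig:
    """A fast configuration: 16 physicians with panels around 160 patients."""
    base = dict(
        n_physicians=16,
        panel_mean=160.0,
        panel_min=110,
        panel_max=400,
        absence_prob=0.0,
        exit_prob=0.0,
        frac_noncomprehensive=0.0,
    )
    base.update(overrides)
    return RunConfig(**base)


def flat_truth(upc_level: float = 75.0, ri_level: float = 76.0,
               fpsc_logit: float = -3.28) -> TruthTable:
    """Truth with constant trajectories, no covariates, no random effects."""
    return TruthTable(
        upc=SegmentTruth(upc_level, 0.0, 0.0, 0.0),
        ri=SegmentTruth(ri_level, 0.0, 0.0, 0.0),
        fpsc=SegmentTruth(fpsc_logit, 0.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(), seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    return build_cohort(small_dataset)


@pytest.fixture(scope="session")
def small_tables(small_dataset, small_cohort):
    return assemble_tables(
        small_dataset, small_cohort.rosters, small_cohort.statuses,
        small_cohort.retention, small_dataset.config, small_cohort.eligibility,
    )


@pytest.fixture()
def hand_claims():
    """Five patients with hand-computable visit patterns for one window.

    Fiscal years 2005-2006; physicians 1, 2, 3.  All fees 35 unless noted.
    """
    rows = []

    def add(pat, doc, year, n, fee=35.0, cat="C01", pc=True):
        for _ in range(n):
            rows.append((pat, doc, year, cat, fee, pc))

    # patient 1: 6 of 8 window visits to physician 1 -> UPC 75
    add(1, 1, 2005, 3)
    add(1, 1, 2006, 3)
    add(1, 2, 2006, 2)
    # patient 2: 2 visits only -> below the UPC minimum
    add(2, 1, 2006, 2)
    # patient 3: 5 of 5 to physician 2 -> UPC 100
    add(3, 2, 2005, 2)
    add(3, 2, 2006, 3)
    # patient 4: fee tie between 1 and 2; physician 2 has more visits
    add(4, 1, 2005, 2, fee=35.0)
    add(4, 2, 2006, 4, fee=17.5)
    # patient 5: only a non-visit fee item -> unattributed
    add(5, 3, 2006, 1, pc=False)
    return pd.DataFrame(rows, columns=[
        "patient_id", "physician_id", "fiscal_year", "service_category",
        "fee", "is_primary_care_visit",
    ])
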