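"""Shared fixtures: extinction table, probe geometry, replicate cohort batch.

The replicate batch runs 25 seeded cohorts through the full analysis path
(latent truth -> forward optics -> chromophore solve -> epoch summaries ->
predictors) once per session; the calibration, directional-statistics and
prediction-performance tests all consume it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fddos import (
    CohortConfig,
    ExtinctionTable,
    ProbeGeometry,
    forward_to_optical,
    generate_cohort,
    hemodynamics_series,
    subject_predictors,
    summarize_epochs,
)

N_REPLICATES = 25
BATCH_SEED_KEY = 1


@pytest.fixture(scope="session")
def ext() -> ExtinctionTable:
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def geom() -> ProbeGeometry:
    return ProbeGeometry()


def _replicate_seed(rep: int) -> int:
    return int(np.random.SeedSequence([BATCH_SEED_KEY, rep]).generate_state(1)[0] % 2**31)


def analyze_cohort(config: CohortConfig, ext: ExtinctionTable) -> pd.DataFrame:
    """One cohort through forward optics + inversion-free chromophore solve.

    Returns one row per subject with outcome, 10-min epoch family values and
    the nine candidate predictors.
    """
    cohort = generate_cohort(config)
    rows = []
    for s in cohort.subjects:
        hemo = hemodynamics_series(forward_to_optical(s, ext), ext, mie=False)
        summary = summarize_epochs(hemo, s.timeline)
        row = {"id": s.id, "rosc": s.rosc, "arm": s.arm}
        for p in ("hbo2", "hb", "thc", "sto2"):
            v10 = summary.loc[p, "cpr_10min"]
            v1 = summary.loc[p, "cpr_1min"]
            row[f"{p}_abs10"] = v10
            row[f"{p}_d10"] = v10 - v1
            row[f"{p}_r10"] = 100.0 * v10 / v1
        row.update(subject_predictors(hemo, s.timeline))
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def replicate_batch(ext) -> list[pd.DataFrame]:
    """25 independent calibrated cohorts analyzed end to end."""
    return [
        analyze_cohort(CohortConfig(seed=_replicate_seed(rep)), ext)
        for rep in range(N_REPLICATES)
    ]
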