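import logging

import numpy as np
import pandas as pd
import pytest

from mirquiescent import (
    CohortConfig,
    CtMatrix,
    RelExprMatrix,
    SampleTable,
    delta_ct,
    detection_filter,
    generate_cohort,
    relative_expression,
)

logging.getLogger("mirquiescent").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (321 miRNAs, 42 samples), shared read-only."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_rel(default_cohort):
    ct, samples, _truth = default_cohort
    rel = relative_expression(delta_ct(ct), samples)
    det = detection_filter(ct, samples)
    return rel, samples, det


def make_samples(n_controls=3, n_uc=0, n_cd=0, paired=False) -> SampleTable:
    rows = []
    for i in range(n_controls):
        rows.append((f"C{i}", f"C{i}", "control",
                     "right_colon" if i % 2 == 0 else "left_colon", 0))
    for grp, n in (("UC", n_uc), ("CD", n_cd)):
        for i in range(n):
            rows.append((f"{grp}{i}_Q", f"{grp}{i}", grp, "quiescent", 0))
            if paired:
                rows.append((f"{grp}{i}_I", f"{grp}{i}", grp, "inflamed", 3))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "group", "state", "grade"]
    ).set_index("sample_id")
    return SampleTable(frame)


def rel_from_log_fold(log_fold: pd.DataFrame, control_ids) -> RelExprMatrix:
    """Build a RelExprMatrix directly from chosen log-fold values (for rule tests)."""
    ddct = -log_fold / (10 * np.log10(2))
    return RelExprMatrix(
        delta_ct=ddct.copy(),
        delta_delta_ct=ddct,
        fold=np.power(10.0, log_fold / 10.0),
        log_fold=log_fold,
        control_sample_ids=list(control_ids),
    )
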