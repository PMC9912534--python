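"""Shared fixtures: desk-scale synthetic cohorts run once per session.

The strong cohort uses the generator defaults (30 subjects per diagnostic
group, 60-s recordings): posterior theta power rises and posterior mobility
falls along HC -> MCI -> AD, with planted brain-cognition-CSF couplings.
The null cohort has identical structure but no EEG effect at all.
"""

import numpy as np
import pandas as pd
import pytest

from eegdem.classify import classify_task
from eegdem.cohort import CohortConfig, generate_subject_table, iter_recordings, null_config
from eegdem.features import build_feature_matrix
from eegdem.preprocess import preprocess_recording

COHORT_SEED = 20240915


def _extract(cfg):
    table = generate_subject_table(cfg)
    epoch_sets = [preprocess_recording(rec)
                  for rec in iter_recordings(cfg, table)]
    fm_epoch = build_feature_matrix(epoch_sets, level="epoch", seed=0)
    value_cols = [c for c in fm_epoch.columns
                  if c not in ("subject_id", "epoch")]
    fm_subject = (fm_epoch.groupby("subject_id", sort=False)[value_cols]
                  .mean().reset_index())
    return table, fm_epoch, fm_subject


@pytest.fixture(scope="session")
def strong_cohort():
    cfg = CohortConfig(n_per_group={"HC": 30, "MCI": 30, "AD": 30},
                       duration=60.0, artifact_rate=0.01, seed=COHORT_SEED)
    table, fm_epoch, fm_subject = _extract(cfg)
    return {"config": cfg, "table": table, "fm_epoch": fm_epoch,
            "fm_subject": fm_subject}


@pytest.fixture(scope="session")
def null_cohort():
    cfg = null_config(n_per_group={"HC": 30, "MCI": 30, "AD": 30},
                      duration=60.0, seed=COHORT_SEED + 1)
    table, fm_epoch, fm_subject = _extract(cfg)
    return {"config": cfg, "table": table, "fm_epoch": fm_epoch,
            "fm_subject": fm_subject}


@pytest.fixture(scope="session")
def strong_reports(strong_cohort):
    """Three-class classification reports (LDA and SVM) on the strong cohort."""
    fm = strong_cohort["fm_epoch"]
    table = strong_cohort["table"]
    groups = fm["subject_id"].map(dict(zip(table["subject_id"],
                                           table["group"])))
    return {name: classify_task(fm, groups, fm["subject_id"],
                                task="hc-mci-ad", classifier=name,
                                seed=COHORT_SEED, max_features=40)
            for name in ("lda", "svm")}
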