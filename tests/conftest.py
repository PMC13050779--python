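"""Shared fixtures, including the session-scoped desk-scale recovery study.

The study fixtures are deliberately expensive (minutes): they generate a
synthetic cohort from planted network couplings and fit the constrained
model to every subject, providing the trained material for the
constraint-preservation, parameter-recovery, and baseline-contrast tests.
Study sizes (5 subjects, 4 s of samples, 1000 epochs of 100-sample
windows) are the package's desk-scale defaults; see docs/methods.md.
"""

import dataclasses

import pytest

from birnn.pipeline import fit_cohort
from birnn.synthetic import CohortSpec, generate_cohort
from birnn.training import TrainingConfig

STUDY_SEED = 7
STUDY_N_SUBJECTS = 5
STUDY_T = 4000
STUDY_EPOCHS = 1000
STUDY_WINDOW = 100


def study_config(seed: int = 5) -> TrainingConfig:
    """Desk-scale training configuration.

    Epoch-denominated settings (epoch budget and the two patiences) are
    scaled up relative to the reference-length defaults because a 4 s
    series yields ~40x fewer optimizer updates per epoch than a full-length
    recording; see docs/methods.md.
    """
    return TrainingConfig(
        seed=seed,
        max_epochs=STUDY_EPOCHS,
        window=STUDY_WINDOW,
        early_stop_patience=60,
        scheduler_patience=45,
    )


@pytest.fixture(scope="session")
def study_cohort():
    spec = CohortSpec(n_subjects=STUDY_N_SUBJECTS, T=STUDY_T, seed=STUDY_SEED)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rest_fits(study_cohort):
    """Per-subject fits of the resting-state condition (all subjects)."""
    return fit_cohort(study_cohort, study_config(), conditions=["rest"])


@pytest.fixture(scope="session")
def task_fits(study_cohort):
    """Per-subject fits of the task condition (three subjects: enough for
    the qualitative condition-contrast check at desk scale)."""
    return fit_cohort(
        study_cohort,
        study_config(),
        conditions=["task"],
        subjects=["sub00", "sub01", "sub02"],
    )
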