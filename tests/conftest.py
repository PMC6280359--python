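"""Session fixtures: the default synthetic bundle and its survey artifacts.

The expensive objects (the 1300-sequence bundle, the profile model, the
calibrated search and the full survey report with a 100-replicate bootstrap)
are built once per session and shared across test modules.
"""

from __future__ import annotations

import pytest

from epdrsurvey import (SurveyConfig, SyntheticConfig, build_profile,
                        calibrate_evalue, generate_family, run_survey,
                        search)
from epdrsurvey.synthetic import family_alignment


@pytest.fixture(scope="session")
def bundle7():
    """Default study bundle: 100 sequences per profile + 1000 decoys, seed 7."""
    config = SyntheticConfig(seed=7)
    sequences, truth = generate_family(config)
    return config, sequences, truth


@pytest.fixture(scope="session")
def family7(bundle7):
    _, sequences, _ = bundle7
    return [(sid, s) for sid, s in sequences if not sid.startswith("decoy")]


@pytest.fixture(scope="session")
def decoys7(bundle7):
    _, sequences, _ = bundle7
    return [(sid, s) for sid, s in sequences if sid.startswith("decoy")]


@pytest.fixture(scope="session")
def seed_alignment7(bundle7):
    """Seed alignment: the first 20 generated members of each profile."""
    _, sequences, truth = bundle7
    ids = [f"fam_p{p}_{i:03d}" for p in "123" for i in range(20)]
    return family_alignment(sequences, truth, ids)


@pytest.fixture(scope="session")
def hmm7(seed_alignment7):
    return build_profile(seed_alignment7)


@pytest.fixture(scope="session")
def search7(bundle7, hmm7):
    """Calibrated best-per-sequence search over the whole bundle."""
    _, sequences, _ = bundle7
    calibration = calibrate_evalue(
        hmm7, n_random=1000, length_model=(231.0, 15.0), seed=7,
        database_size=len(sequences),
    )
    hits = search(hmm7, sequences, calibration, cutoff=1e-5)
    return calibration, hits


@pytest.fixture(scope="session")
def survey_report7(bundle7, seed_alignment7):
    """Full default-config survey of the bundle (100 bootstrap replicates)."""
    _, sequences, truth = bundle7
    report = run_survey(sequences, seed_alignment7, SurveyConfig(seed=7),
                        taxa=truth.taxa())
    return report


@pytest.fixture(scope="session")
def small_survey():
    """A lighter bundle + survey for pipeline-behaviour tests."""
    config = SyntheticConfig(n_per_profile=30, n_decoys=100, seed=11)
    sequences, truth = generate_family(config)
    ids = [f"fam_p{p}_{i:03d}" for p in "123" for i in range(10)]
    seed_aln = family_alignment(sequences, truth, ids)
    survey_config = SurveyConfig(seed=11, calibration_n_random=200,
                                 bootstrap_reps=20)
    report = run_survey(sequences, seed_aln, survey_config, taxa=truth.taxa())
    return config, sequences, truth, seed_aln, survey_config, report
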