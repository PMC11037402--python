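"""Shared fixtures: synthetic study cohorts and the models derived from
them. The heavy end-to-end artefacts are session-scoped so the lighting
study is simulated, fitted and corrected once for the whole suite."""

import warnings

import numpy as np
import pytest

import purepupil as pp
from purepupil import lighting, pipeline, score as score_mod

MASTER_SEED = 11


@pytest.fixture(scope="session")
def lighting_study():
    return pp.simulate_lighting_study(pp.CohortConfig(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def lighting_table(lighting_study):
    return pipeline.extract_table(lighting_study.recordings, lighting_study.metadata)


@pytest.fixture(scope="session")
def correction_models(lighting_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lighting.fit_correction_models(lighting_table)


@pytest.fixture(scope="session")
def loso_corrected(lighting_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lighting.correct_dataset_loso(lighting_table)


@pytest.fixture(scope="session")
def mydriasis_scored(correction_models):
    """End-to-end scored mydriasis cohort: simulate, extract, correct with
    the lighting-study models, score, calibrate the 0-5 scaler on the same
    cohort's raw scores."""
    study = pp.simulate_mydriasis_study(
        pp.CohortConfig(n_subjects=15, seed=MASTER_SEED + 1)
    )
    tab = pipeline.extract_table(study.recordings, study.metadata)
    corrected = lighting.apply_correction_models(correction_models, tab)
    model = score_mod.PuReModel()
    scored = pipeline.score_table(corrected, model)
    model.scaler = pipeline.calibrate_scaler_on_cohort(scored)
    return pipeline.score_table(corrected, model)


@pytest.fixture()
def example_fit():
    return pp.WaveformFit(b=6.0, a1=2.0, t1=1.5, s1=0.08, a2=1.6, t2=2.8, s2=0.3)


@pytest.fixture()
def example_recording(example_fit):
    t = np.arange(300) / 60.0
    return pp.Pupillogram(
        "example", t, pp.eval_canonical(example_fit, t), flash_onset=1.0
    )
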