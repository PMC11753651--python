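from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import gaitrel as g

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return g.make_template()


@pytest.fixture(scope="session")
def noiseless_trial(template):
    """One deterministic trial with exact ground truth (no frame noise)."""
    design = g.StudyDesign(seed=1)
    return g.synthesize_trial(template, design)


@pytest.fixture(scope="session")
def recovery_study():
    """Full-size study with hierarchical variance but no frame noise, so
    every trial's truth is exactly recoverable."""
    design = g.StudyDesign(n_subjects=9, n_sessions=3, n_trials_collected=5,
                           n_trials_sampled=5, seed=7)
    vc = replace(g.VarianceComponents.default(), sd_frame_noise=0.0)
    return g.generate_study(design, g.make_template(), vc)


@pytest.fixture(scope="session")
def default_report():
    """Report from a full-size study under the default (noisy) conditions."""
    study = g.generate_study(g.StudyDesign(seed=42))
    return g.run_study(study, g.AnalysisConfig(sampling_seed=42))
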