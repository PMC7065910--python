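import numpy as np
import pytest

from forktrack.conditions import condition
from forktrack.pipeline import AnalysisConfig, analyze_trace
from forktrack.simulate import ForceSchedule, ImagingParams, simulate_trace
from forktrack.tether import TemplateSpec, template_preset


@pytest.fixture(scope="session")
def noiseless_polarity_bundle():
    """Single tensioned-strand fork on the nicked 6.4 kbp template, 30 pN."""
    template = template_preset("nicked_6p4kbp")
    cond = condition("nicked_6p4")
    imaging = ImagingParams(duration_s=160.0, noiseless=True)
    schedule = ForceSchedule.constant(30.0, 160.0)
    return simulate_trace(template, cond, imaging, schedule, seed=5)


@pytest.fixture(scope="session")
def noiseless_three_event_bundle():
    """Three well-separated, early-initiating nick events on a λ-size
    template, noiseless: every event is observed through a long clean phase."""
    template = TemplateSpec(48_502, (10_000, 25_000, 40_000), "lambda_3nicks")
    from forktrack.simulate import SimCondition

    cond = SimCondition(
        velocity_mean=60.0,
        velocity_sd=9.0,
        initiation_force_quantiles=((30.0, 1.0),),
        initiation_wait_mean_s=2.0,
    )
    imaging = ImagingParams(duration_s=80.0, noiseless=True)
    schedule = ForceSchedule.constant(30.0, 80.0)
    return simulate_trace(template, cond, imaging, schedule, seed=11)


@pytest.fixture(scope="session")
def noisy_single_event_bundle():
    """Default-noise single fork on the nicked 6.4 kbp template."""
    template = template_preset("nicked_6p4kbp")
    cond = condition("nicked_6p4")
    imaging = ImagingParams(duration_s=120.0)
    schedule = ForceSchedule.constant(30.0, 120.0)
    return simulate_trace(template, cond, imaging, schedule, seed=21)


@pytest.fixture(scope="session")
def analyzed_three_events(noiseless_three_event_bundle):
    b = noiseless_three_event_bundle
    cfg = AnalysisConfig.noiseless(b.imaging)
    return b, analyze_trace(b.kymo, b.series, cfg)
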