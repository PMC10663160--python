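import numpy as np
import pandas as pd
import pytest

from sleepbrain import synthetic as syn
from sleepbrain.registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_study(registry):
    """Two-cohort study with longitudinal follow-up, four regions."""
    cfg = [syn.CohortConfig("A", n_cross=300, n_long=150, followups=3,
                            n_obs_long=380),
           syn.CohortConfig("B", n_cross=200, n_long=100, followups=2)]
    model = syn.TrueModel(tau_region=0.3, icv_sleep_corr=0.2)
    df = syn.generate_cohorts(cfg, model, seed=11, registry=registry,
                              regions=["Hippocampus", "Thalamus",
                                       "Ventricles", "CC anterior"])
    return df


@pytest.fixture(scope="session")
def cross_study(registry):
    """Single-cohort cross-sectional study for peak estimation."""
    model = syn.TrueModel(sigma_resid=1.0, sigma_intercept=0.4)
    cfg = [syn.CohortConfig("solo", n_cross=1500, age_range=(30, 80))]
    return syn.generate_cohorts(cfg, model, seed=21, registry=registry,
                                regions=["Hippocampus", "Ventricles"])
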