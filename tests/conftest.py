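import numpy as np
import pytest

import ppgaf as p

GRID_RR_MS = (600, 800, 1000, 1200)


@pytest.fixture(scope="session")
def clean_grid():
    """Clean 60-s sinus strips at four heart rates, rendered in both
    modalities, keyed by (rr_ms, modality)."""
    out = {}
    for rr_ms in GRID_RR_MS:
        rr = p.simulate_rr_sinus(60, rr_ms, 30, 0.25, 20, seed=rr_ms)
        out[(rr_ms, "ECG")] = (rr, p.render_ecg(rr, seed=1))
        out[(rr_ms, "PPG")] = (rr, p.render_ppg(rr, seed=1))
    return out


@pytest.fixture(scope="session")
def clean_sinus_800():
    rr = p.simulate_rr_sinus(60, 800, 30, 0.25, 20, seed=11)
    return rr, p.render_ppg(rr, seed=3), p.render_ecg(rr, seed=4)


@pytest.fixture(scope="session")
def small_cohort():
    """A rendered 24-subject cohort with every error mode switched on."""
    cfg = p.CohortConfig(n_subjects=24, af_prevalence=0.5, ectopy_rate=2.0,
                         flutter_fraction=0.2, artifact_rate=0.15, seed=7)
    return p.simulate_cohort(cfg)


def constant_rr(n=75, rr_ms=800.0):
    from ppgaf.synth import _series_from_intervals

    return _series_from_intervals(np.full(n, rr_ms), "sinus")
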