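import numpy as np
import pytest

from autonomiq.pipeline import default_quality_models
from autonomiq.synth import (PvcSpec, SubjectSpec, gen_tachogram, inject_pvc,
                             render_waveforms)

FS = 250.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def quality_models():
    """Template library + ABP subspace fit once for the whole session."""
    return default_quality_models(FS, n_leads=2)


@pytest.fixture(scope="session")
def clean_record():
    """5-minute clean synthetic record with 5 injected PVCs and its truth."""
    spec = SubjectSpec(jitter_sd_ms=4.0, seed=2)
    tach = inject_pvc(gen_tachogram(spec, duration_s=300),
                      PvcSpec(count=5, min_spacing_beats=25))
    record, truth = render_waveforms(tach, fs=FS)
    return record, truth, tach


@pytest.fixture(scope="session")
def steady_record():
    """60-bpm metronomic record (no jitter, no modulation) and its truth."""
    spec = SubjectSpec(mean_rr_ms=1000.0, lf_amp_ms=0.0, hf_amp_ms=0.0,
                       jitter_sd_ms=0.0, seed=1)
    tach = gen_tachogram(spec, duration_s=300)
    record, truth = render_waveforms(tach, fs=FS)
    return record, truth
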