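import numpy as np
import pytest

import catrace as ct


@pytest.fixture()
def config():
    return ct.AnalysisConfig()


@pytest.fixture()
def clean_trace():
    """A default 1 Hz / 5-beat / 100 FPS noiseless trace with ground truth."""
    return ct.make_transient_trace(ct.WaveformSpec())


@pytest.fixture()
def make_trace():
    def _make(**kwargs):
        return ct.make_transient_trace(ct.WaveformSpec(**kwargs))

    return _make
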