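import numpy as np
import pytest

from adctrack import LesionMask, RunConfig
from adctrack.adc_mapping import ADCMap


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_map(values, spacing=(3.0, 3.0, 4.0), **kw):
    return ADCMap(values=np.asarray(values, dtype=float), voxel_spacing=spacing,
                  b_pair_used=(150.0, 500.0), **kw)


def make_mask(mask, spacing=(3.0, 3.0, 4.0), lesion_class="GTV-P", **kw):
    return LesionMask(patient_id="p01", lesion_id="P", lesion_class=lesion_class,
                      mask=np.asarray(mask, dtype=bool), voxel_spacing=spacing, **kw)
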