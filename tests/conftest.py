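import numpy as np
import pytest

from nodulescope import synth

BASELINE_COEFFS = [120.0, -40.0, 25.0, 0.0, 0.0, 10.0]


@pytest.fixture
def bone_truth():
    """Bone-like ground truth with a curved fluorescence background."""
    return synth.default_raman_truth(baseline_coeffs=BASELINE_COEFFS)


@pytest.fixture
def noisy_bone_truth():
    """Same spectrum at noise SD = 2% of the phosphate amplitude."""
    t = synth.default_raman_truth(baseline_coeffs=BASELINE_COEFFS)
    return synth.RamanGroundTruth(
        band_centers=t.band_centers,
        band_amplitudes=t.band_amplitudes,
        band_sigmas=t.band_sigmas,
        baseline_coeffs=t.baseline_coeffs,
        noise_sd=0.02 * t.band_amplitudes[t.po4_index],
    )


@pytest.fixture
def pyramid_truth():
    """Noiseless 2 GPa pyramidal-indentation ground truth."""
    return synth.ForceCurveGroundTruth()


@pytest.fixture
def axis():
    return synth.default_axis()
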