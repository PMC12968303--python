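"""Shared fixtures: small synthetic traces and cohorts, all seed-controlled."""

import numpy as np
import pytest

from breathvoc.chrom import ChromConfig
from breathvoc.synth import ChromSpec, make_chromatogram


@pytest.fixture
def cfg():
    return ChromConfig()


@pytest.fixture
def clean_peak():
    """Single noiseless Gaussian: area 100, sigma 2 s, apex 150 s."""
    spec = ChromSpec(duration_s=300, sampling_hz=5, peaks=((150.0, 100.0, 2.0),))
    chrom, truth = make_chromatogram(spec)
    return chrom, truth


def window_area(chrom, center, half_width):
    """Trapezoidal integral of a trace over [center - hw, center + hw]."""
    t, y = chrom.time_s, chrom.intensity
    m = (t >= center - half_width) & (t <= center + half_width)
    return float(np.trapezoid(y[m], t[m]))
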