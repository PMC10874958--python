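import warnings

import numpy as np
import pytest

from octlayers.preprocess import denoise, trim_optic_disc
from octlayers.synth import CohortParams, NoiseParams, generate_cohort, render_bscan

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Six rendered eyes (2 per group), horizontal scans, default noise."""
    cp = CohortParams(n_eyes={"normal": 2, "NPDR": 2, "PDR": 2}, seed=5)
    return generate_cohort(cp)


@pytest.fixture(scope="session")
def clean_scan(small_cohort):
    """One noise-free rendering with its ground truth, already denoised+trimmed."""
    scan = small_cohort[0]
    img = render_bscan(scan.truth, noise=NoiseParams(speckle_shape=None), seed=0,
                       laterality=scan.covariates["laterality"],
                       disc_side=scan.covariates["disc_side"])
    den = denoise(img)
    trimmed, offset = trim_optic_disc(den)
    return {"truth": scan.truth, "raw": img, "denoised": trimmed, "offset": offset,
            "covariates": scan.covariates}


@pytest.fixture(scope="session")
def noisy_scan(small_cohort):
    """The same eye rendered with default speckle, denoised and trimmed."""
    scan = small_cohort[0]
    den = denoise(scan.image)
    trimmed, offset = trim_optic_disc(den)
    return {"truth": scan.truth, "raw": scan.image, "denoised": trimmed,
            "offset": offset, "covariates": scan.covariates}


def polyline_si(x, y):
    """Independent arc-length oracle for the smoothness index."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ll = float(np.sqrt((x[-1] - x[0]) ** 2 + (y[-1] - y[0]) ** 2))
    cl = 0.0
    for i in range(len(x) - 1):
        cl += float(np.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2))
    return ll / cl
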