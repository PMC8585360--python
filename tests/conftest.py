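import numpy as np
import pytest

from boneplough import datasets


@pytest.fixture(scope="session")
def ref_models():
    """Published calibrated (normal-force, anisotropy) model pair."""
    return datasets.reference_coefficients()


@pytest.fixture(scope="session")
def replicate_fp():
    """Bundled replicate ploughing coefficients (theta_deg, fp, replicate)."""
    return datasets.load_replicate_ploughing_coefficients()


def naive_hampel(x, window, k=3.0):
    """Brute-force rolling median/MAD Hampel filter (independent oracle)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = x.copy()
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        seg = x[max(0, i - window) : min(n, i + window + 1)]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        if abs(x[i] - med) > k * 1.4826 * mad:
            out[i] = med
            mask[i] = True
    return out, mask
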