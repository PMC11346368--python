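import numpy as np
import pytest

from coroplaque import PhantomSpec, make_phantom, quantify_ct


@pytest.fixture(scope="session")
def tube_phantom():
    """Clean annular tube: lumen 1.5 mm, outer 2.5 mm, 20 mm, voxel 0.2 mm,
    no PSF, no noise. Shared across tests because rendering is the slow part."""
    spec = PhantomSpec(
        length_mm=20.0,
        lumen_radius_mm=1.5,
        outer_radius_mm=2.5,
        psf_sigma_mm=0.0,
        noise_sd_hu=0.0,
        voxel_spacing_mm=0.2,
        seed=42,
    )
    image, labels, centerline, truth = make_phantom(spec)
    return spec, image, labels, centerline, truth


@pytest.fixture(scope="session")
def tube_quantified(tube_phantom):
    spec, image, labels, centerline, truth = tube_phantom
    series, thresholds = quantify_ct(image, labels, centerline)
    return series, thresholds, truth


def brute_force_lesions(burden, spacing=1.0, threshold=40.0, min_length=2.0):
    """Independent lesion oracle: exhaustively enumerate contiguous windows
    of qualifying stations and keep the maximal ones of sufficient span."""
    n = len(burden)
    qual = [b >= threshold for b in np.nan_to_num(burden, nan=-np.inf)]
    out = []
    for i in range(n):
        for j in range(i, n):
            if not all(qual[i : j + 1]):
                continue
            maximal = (i == 0 or not qual[i - 1]) and (j == n - 1 or not qual[j + 1])
            if maximal and (j - i) * spacing >= min_length - 1e-9:
                out.append((i, j))
    return out
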