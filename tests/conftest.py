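import numpy as np
import pytest

from glyconet import synthetic_data as sd
from glyconet.spectral_networking import FragmentSpectrum


def spectrum(peaks, precursor_mz=500.0, rt=5.0, scan_id="s", sample_id=""):
    """Build a FragmentSpectrum from a {mz: intensity} dict."""
    mz = np.array(sorted(peaks))
    inten = np.array([peaks[m] for m in sorted(peaks)], dtype=float)
    return FragmentSpectrum(
        scan_id=scan_id, precursor_mz=precursor_mz, rt=rt, sample_id=sample_id,
        mz=mz, intensity=inten,
    )


@pytest.fixture(scope="session")
def library():
    """One family of each kind, fixed seed."""
    return sd.make_congener_library(3, seed=1)


@pytest.fixture(scope="session")
def noiseless_profiles(library):
    abund = {c.congener_id: 1.0 for c in library}
    return [sd.noiseless_profile("sampleA", abund), sd.noiseless_profile("sampleB", abund)]
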