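import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quenchbind import (GroundTruth, binding_density_curve, hill_fit,
                        match_levels, simulate_titration)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    """Default noiseless ground truth (study design: 2/4/8 uM protein,
    0-32 uM ligand in 2 uM steps, 288 K)."""
    return GroundTruth()


@pytest.fixture(scope="session")
def titrations(truth):
    """Observed + hidden-true + absorbance spectra, one series per
    protein concentration."""
    return simulate_titration(truth)


@pytest.fixture(scope="session")
def corrected_titrations(titrations):
    return [s.corrected() for s in titrations]


@pytest.fixture(scope="session")
def idf_pipeline(corrected_titrations):
    """Full noiseless IDF run: levels, binding-density curve, Hill model."""
    levels = match_levels(corrected_titrations, levels=20)
    curve = binding_density_curve(levels)
    hill = hill_fit(curve, max_classes=3)
    return levels, curve, hill


def flat_spectrum(value, kind="emission", lam=None, **meta):
    """Constant-valued emission spectrum helper."""
    from quenchbind import Spectrum
    if lam is None:
        lam = np.arange(305.0, 401.0, 1.0)
    meta.setdefault("excitation_nm", 295.0)
    return Spectrum(kind, lam, np.full(lam.size, float(value)), meta)
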