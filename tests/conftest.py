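import numpy as np
import pytest

from ramanpls import (
    POLYMORPHS,
    RunConfig,
    default_axis,
    default_library,
    make_design,
    noise_preset,
    simulate_replicates,
)
from ramanpls.synthetic import COMPONENTS, ComponentLibrary, Peak, PeakModel


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def library():
    return default_library(seed=7)


@pytest.fixture(scope="session")
def equal_area_library(library):
    """Default library rescaled so every component has unit integrated area.

    With equal component areas, area normalization is a constant scale and
    the noiseless pipeline is exactly linear in the tablet-mass weights —
    the analytic regime used by the machine-precision linearity tests.
    """
    axis = default_axis()
    comps = {}
    for name in COMPONENTS:
        model = library.components[name]
        y = np.zeros_like(axis)
        for p in model.peaks:
            y += p.profile(axis)
        area = np.trapezoid(y, axis)
        comps[name] = PeakModel(
            tuple(
                Peak(p.center, p.fwhm, p.amplitude / area, p.shape)
                for p in model.peaks
            )
        )
    return ComponentLibrary(comps)


@pytest.fixture(scope="session")
def noiseless_spectra(design, library, axis):
    """One noiseless replicate per designed tablet (replicates are identical)."""
    noise = noise_preset("none", seed=0, n_replicates=1)
    return {
        s.sample_id: simulate_replicates(s, library, noise, axis) for s in design
    }


@pytest.fixture(scope="session")
def noiseless_calibration(design, noiseless_spectra):
    """Preprocessed full-axis feature matrix and responses, calibration set."""
    from ramanpls.pipeline import _preprocessed_matrix

    cfg = RunConfig(seed=0, noise="none", replicates=1)
    cal = design.calibration
    X = _preprocessed_matrix(cal, noiseless_spectra, cfg.preprocess_spec())
    return X, cal.responses()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exact_rank_instance(rng, n=10, p=8, r=3, q=3):
    """Construct X of exact rank r (after centering) and Y exactly linear in X."""
    T = rng.normal(size=(n, r))
    P = rng.normal(size=(r, p))
    X = T @ P + rng.normal(size=p)  # row offset; centering removes it
    B = P.T @ rng.normal(size=(r, q))  # coefficients in the row space
    Y = X @ B + rng.normal(size=q)
    return X, Y
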