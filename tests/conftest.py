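import numpy as np
import pytest

from nanotwin import fixtures
from nanotwin.milling import SizeGrid, lognormal_psd
from nanotwin.surrogate import augment_profile, polyfit_profile


@pytest.fixture(scope="session")
def table2():
    """Pooled replicate D50(t) milling data (18 points)."""
    return fixtures.milling_training_frame()


@pytest.fixture(scope="session")
def dense_reference(table2):
    """Order-2 polynomial reference profile on a 61-point grid over 0-3600 s."""
    poly = polyfit_profile(table2, order=2)
    grid = np.linspace(0.0, 3600.0, 61)
    return augment_profile(poly, grid, allow_extrapolation=True).to_frame()


@pytest.fixture(scope="session")
def default_grid():
    return SizeGrid.geometric()


@pytest.fixture(scope="session")
def feed_psd(default_grid):
    """Feed PSD: lognormal, D50 = 1.5 um, on the default 20-bin grid."""
    return lognormal_psd(default_grid, median=1.5e-6, gsd=1.5)


@pytest.fixture(scope="session")
def breakage_fits(dense_reference):
    """Cascaded de Vegt / Kapur / Austin fits against the dense reference.

    Session-scoped: this is the expensive computation shared by the
    model-comparison checks.
    """
    from nanotwin.milling import fit_all_families

    return fit_all_families(dense_reference)
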