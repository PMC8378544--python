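import numpy as np
import pytest

from vne.geometry import ImageSlice, Modality, SliceGeometry
from vne.phantom import PhantomSpec, generate_study
from vne.quantify import RoiSet


@pytest.fixture
def axial_geometry():
    def make(n=16, spacing=1.0, position=(0.0, 0.0, 0.0),
             row=(1.0, 0.0, 0.0), col=(0.0, 1.0, 0.0)):
        return SliceGeometry(
            row_dir=np.asarray(row), col_dir=np.asarray(col),
            position_mm=np.asarray(position, dtype=float),
            pixel_spacing_mm=(spacing, spacing), n_rows=n, n_cols=n,
        )

    return make


@pytest.fixture(scope="session")
def small_study():
    """A small noisy study shared across tests (read-only)."""
    return generate_study(PhantomSpec(n_patients=4, image_size=32, seed=42))


@pytest.fixture(scope="session")
def noise_free_study():
    return generate_study(
        PhantomSpec(n_patients=4, image_size=32, noise_sd=0.0, seed=43))


@pytest.fixture
def square_annulus(axial_geometry):
    """Concentric squares, 10 px and 4 px sides aligned to pixel centres.

    Myocardial mask area is 10*10 - 4*4 = 84 pixels.  Contour vertices sit
    half a pixel outside the covered pixel centres so the even-odd test is
    unambiguous.
    """
    g = axial_geometry(n=16)
    epi = np.array([[2.5, 2.5], [2.5, 12.5], [12.5, 12.5], [12.5, 2.5]])
    endo = np.array([[5.5, 5.5], [5.5, 9.5], [9.5, 9.5], [9.5, 5.5]])
    remote = np.array([[3, 3], [3, 4], [4, 3]])
    blood = np.array([[7, 7], [7, 8], [8, 7], [8, 8]])
    roi = RoiSet(epicardial_contour=epi, endocardial_contour=endo,
                 remote_roi=remote, bloodpool_roi=blood)
    return g, roi


def make_image(pixels, geometry, modality=Modality.LGE):
    return ImageSlice(pixels=np.asarray(pixels, dtype=float),
                      geometry=geometry, modality=modality)
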