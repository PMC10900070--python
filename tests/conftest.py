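import numpy as np
import pytest

from pdtplan.geometry import LabelVolume, Region, build_four_region
from pdtplan.optics import OpticalProperties, OpticalVolume
from pdtplan.phantoms import PhantomSpec, SubjectOptics, make_cavity_mask


def make_homogeneous_volume(n: int, pitch_mm: float, mua: float, mus: float,
                            g: float) -> OpticalVolume:
    """All-INTERIOR grid with an absorbing outer shell — analytic-oracle medium."""
    labels = np.full((n, n, n), Region.INTERIOR, dtype=np.uint8)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        labels[tuple(sl)] = Region.BOUNDARY
        sl[ax] = -1
        labels[tuple(sl)] = Region.BOUNDARY
    lv = LabelVolume(labels, pitch_mm)
    return OpticalVolume(lv, {Region.INTERIOR: OpticalProperties(mua, mus, g)}, 0.0)


def radius_map_cm(shape, pitch_mm, center_mm) -> np.ndarray:
    """Per-voxel distance (cm) from voxel centers to a physical point."""
    idx = np.indices(shape).reshape(3, -1).T
    pos = (idx + 0.5) * pitch_mm
    return (np.linalg.norm(pos - np.asarray(center_mm), axis=1) / 10.0).reshape(shape)


@pytest.fixture(scope="session")
def sphere_lv() -> LabelVolume:
    """Four-region sphere cavity, r = 8 mm at 1 mm pitch."""
    mask, pitch = make_cavity_mask(
        PhantomSpec(shape="sphere", semi_axes_mm=(8, 8, 8), pitch_mm=1.0,
                    padding_mm=4.0, seed=1)
    )
    return build_four_region(mask, pitch)


@pytest.fixture(scope="session")
def rep_subject() -> SubjectOptics:
    """A subject with strongly absorbing post-photosensitizer wall optics."""
    return SubjectOptics(pre_mua=0.08, pre_musp=4.8, post_mua=49.4, post_musp=3.0,
                         power_mw=528.0)
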