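import numpy as np
import pytest

from biofilm4d import ImageStack, Track, VoxelGeometry
from biofilm4d.segmentation import Element


@pytest.fixture
def geometry():
    return VoxelGeometry(dx=0.5, dy=0.5, dz=0.42, frame_interval=20.0)


@pytest.fixture
def unit_geometry():
    return VoxelGeometry(dx=1.0, dy=1.0, dz=1.0, frame_interval=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(values, geometry, channel="bacteria"):
    return ImageStack(np.asarray(values), geometry, channel=channel)


def element_from_mask(mask, element_id=0):
    """Build an Element directly from a boolean mask (bypassing label3d)."""
    zz, yy, xx = np.nonzero(np.asarray(mask, dtype=bool))
    bbox = ((int(zz.min()), int(zz.max()) + 1),
            (int(yy.min()), int(yy.max()) + 1),
            (int(xx.min()), int(xx.max()) + 1))
    return Element(id=element_id, frame_time=0.0, voxels=(zz, yy, xx),
                   volume=float(len(zz)),
                   centroid=(float(xx.mean()), float(yy.mean()), float(zz.mean())),
                   bbox=bbox)


def element_from_voxels(zz, yy, xx, element_id=0):
    zz, yy, xx = (np.asarray(a) for a in (zz, yy, xx))
    bbox = ((int(zz.min()), int(zz.max()) + 1),
            (int(yy.min()), int(yy.max()) + 1),
            (int(xx.min()), int(xx.max()) + 1))
    return Element(id=element_id, frame_time=0.0, voxels=(zz, yy, xx),
                   volume=float(len(zz)),
                   centroid=(float(xx.mean()), float(yy.mean()), float(zz.mean())),
                   bbox=bbox)


def make_track(times, volumes, track_id=0):
    """A Track carrying only times and volumes (for growth-law tests)."""
    elements = []
    for v in volumes:
        el = Element(id=0, frame_time=0.0,
                     voxels=(np.array([0]), np.array([0]), np.array([0])),
                     volume=float(v), centroid=(0.0, 0.0, 0.0),
                     bbox=((0, 1), (0, 1), (0, 1)))
        elements.append(el)
    return Track(track_id=track_id, times=list(map(float, times)),
                 elements=elements)
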