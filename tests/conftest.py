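import numpy as np
import pytest

from qfib import Calibration, DualChannelSlide
from qfib.regions import RegionSet
from qfib.segmentation import MaskLayer


@pytest.fixture
def cal() -> Calibration:
    return Calibration()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201)


def make_slide(shg, tpef=None, cal=None, sample_id="s"):
    shg = np.asarray(shg, dtype=float)
    if tpef is None:
        tpef = np.full_like(shg, 100.0)
    return DualChannelSlide(shg=shg, tpef=tpef, calibration=cal or Calibration(),
                            sample_id=sample_id)


def make_regions(shape, portal=None, periportal=None, cal=None):
    """RegionSet from explicit masks; RPS is the remaining tissue."""
    cal = cal or Calibration()
    tissue = np.ones(shape, dtype=bool)
    portal = np.zeros(shape, bool) if portal is None else np.asarray(portal, bool)
    periportal = (
        np.zeros(shape, bool) if periportal is None else np.asarray(periportal, bool)
    )
    rps = tissue & ~portal & ~periportal
    rs = RegionSet(portal=portal, periportal=periportal, rps=rps, tissue=tissue,
                   calibration=cal)
    rs.validate()
    return rs


@pytest.fixture
def full_rps_regions(cal):
    """A 128x128 field that is all tissue, all of it RPS."""
    return make_regions((128, 128), cal=cal)


def layer(name, mask, cal=None):
    return MaskLayer(name, np.asarray(mask, bool), cal or Calibration())
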