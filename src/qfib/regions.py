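"""Periportal / reduced-perisinusoidal partition of the tissue mask.

The periportal region is a 100 um radial margin around the portal tract:
every tissue pixel whose Euclidean distance to the nearest portal-tract
pixel lies in (0, margin].  Distances are exact Euclidean distance
transforms on the pixel grid converted to micrometres through the
calibration; the margin boundary is inclusive.  Margins of nearby portal
tracts merge by set union.  What remains of the tissue after carving out
portal tracts and the periportal margin is the reduced perisinusoidal
(RPS) region, so portal, periportal and RPS tile the tissue exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .io import Calibration, DualChannelSlide
from .segmentation import MaskLayer

__all__ = ["RegionConfig", "RegionSet", "build_periportal", "build_rps", "partition",
           "portal_distance_um"]

#: Radial width of the periportal margin, micrometres.
DEFAULT_PERIPORTAL_MARGIN_UM = 100.0


@dataclass(frozen=True)
class RegionConfig:
    periportal_margin_um: float = DEFAULT_PERIPORTAL_MARGIN_UM

    def __post_init__(self) -> None:
        if not (self.periportal_margin_um > 0):
            raise ValueError("periportal_margin_um must be > 0")


@dataclass
class RegionSet:
    """Mutually exclusive portal / periportal / RPS masks tiling tissue."""

    portal: np.ndarray
    periportal: np.ndarray
    rps: np.ndarray
    tissue: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.portal = np.asarray(self.portal, dtype=bool)
        self.periportal = np.asarray(self.periportal, dtype=bool)
        self.rps = np.asarray(self.rps, dtype=bool)
        self.tissue = np.asarray(self.tissue, dtype=bool)

    def validate(self) -> None:
        if self.portal.shape != self.tissue.shape or self.periportal.shape != self.tissue.shape or self.rps.shape != self.tissue.shape:
            raise ValueError("region mask shapes differ")
        if (self.portal & self.periportal).any() or (self.portal & self.rps).any() or (self.periportal & self.rps).any():
            raise ValueError("region masks are not pairwise disjoint")
        if not np.array_equal(self.portal | self.periportal | self.rps, self.tissue):
            raise ValueError("portal + periportal + rps do not tile tissue")

    def mask(self, region: str) -> np.ndarray:
        try:
            return {"portal": self.portal, "periportal": self.periportal,
                    "rps": self.rps, "tissue": self.tissue}[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None

    def area_um2(self, region: str) -> float:
        return self.calibration.area_px_to_um2(int(self.mask(region).sum()))

    def labeled(self) -> np.ndarray:
        """Indexed map: 0 background, 1 portal, 2 periportal, 3 RPS."""
        out = np.zeros(self.tissue.shape, dtype=np.uint8)
        out[self.portal] = 1
        out[self.periportal] = 2
        out[self.rps] = 3
        return out


def portal_distance_um(portal: np.ndarray, calibration: Calibration) -> np.ndarray:
    """Euclidean distance (um) of every pixel to the nearest portal pixel.

    Portal pixels themselves have distance 0.  An empty portal mask
    yields +inf everywhere.
    """
    portal = np.asarray(portal, dtype=bool)
    if not portal.any():
        return np.full(portal.shape, np.inf)
    dist_px = ndi.distance_transform_edt(~portal)
    return dist_px * calibration.microns_per_pixel


def build_periportal(
    portal: MaskLayer, tissue: MaskLayer, cfg: RegionConfig | None = None
) -> np.ndarray:
    """Periportal mask: tissue pixels with 0 < d(portal) <= margin.

    The distance transform is evaluated on the portal bounding box
    padded by the margin, which is exact for every distance up to the
    margin and avoids transforming the whole frame.
    """
    cfg = cfg or RegionConfig()
    if portal.mask.shape != tissue.mask.shape:
        raise ValueError("portal and tissue masks must share shape")
    if not tissue.mask.any():
        raise ValueError("no tissue")
    pmask = portal.mask
    out = np.zeros(pmask.shape, dtype=bool)
    if not pmask.any():
        return out
    margin_px = int(np.ceil(tissue.calibration.um_to_px(cfg.periportal_margin_um))) + 2
    rows = np.any(pmask, axis=1).nonzero()[0]
    cols = np.any(pmask, axis=0).nonzero()[0]
    r0 = max(0, rows[0] - margin_px)
    r1 = min(pmask.shape[0], rows[-1] + margin_px + 1)
    c0 = max(0, cols[0] - margin_px)
    c1 = min(pmask.shape[1], cols[-1] + margin_px + 1)
    window = np.s_[r0:r1, c0:c1]
    dist_um = ndi.distance_transform_edt(~pmask[window]) * tissue.calibration.microns_per_pixel
    out[window] = (
        (dist_um > 0) & (dist_um <= cfg.periportal_margin_um) & tissue.mask[window]
    )
    return out


def build_rps(
    tissue: MaskLayer, portal: np.ndarray, periportal: np.ndarray
) -> np.ndarray:
    """Reduced perisinusoidal region: tissue minus portal minus periportal."""
    return tissue.mask & ~np.asarray(portal, dtype=bool) & ~np.asarray(periportal, dtype=bool)


def partition(
    slide: DualChannelSlide,
    tissue: MaskLayer,
    portal: MaskLayer,
    cfg: RegionConfig | None = None,
) -> RegionSet:
    """Compose the full region partition for one slide and validate it."""
    cfg = cfg or RegionConfig()
    portal_in_tissue = portal.mask & tissue.mask
    portal_layer = MaskLayer("portal", portal_in_tissue, portal.calibration)
    periportal = build_periportal(portal_layer, tissue, cfg)
    rps = build_rps(tissue, portal_in_tissue, periportal)
    rs = RegionSet(
        portal=portal_in_tissue,
        periportal=periportal,
        rps=rps,
        tissue=tissue.mask,
        calibration=slide.calibration,
    )
    rs.validate()
    return rs
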