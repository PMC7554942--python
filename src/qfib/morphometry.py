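"""Fiber-string extraction, measurement and classification.

A fiber string is one 8-connected component of the collagen mask.  Each
fiber carries:

* area: pixel count x (um/px)^2;
* length: arc length of its morphological skeleton, summing 1-px steps
  for orthogonal and sqrt(2)-px steps for diagonal skeleton adjacencies
  (a single-pixel skeleton counts as one pixel of length);
* width: area / length, i.e. mean width along the skeleton.

Dichotomous classes (all boundary-inclusive, thresholds configurable):
long vs short (length >= 20 um), thick vs thin (width >= 3 um),
aggregated vs distributed (component area >= 200 um^2).  Fibers are
assigned to the region (portal / periportal / RPS) holding the majority
of their pixels; ties prefer periportal, then portal, then RPS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .io import Calibration
from .regions import RegionSet
from .segmentation import STRUCTURE_8

__all__ = [
    "MorphometryConfig",
    "FiberString",
    "extract_fibers",
    "measure_length",
    "classify_fiber",
    "classify_aggregation",
    "count_intersections",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class MorphometryConfig:
    """Fiber-class thresholds (boundary inclusive) in physical units."""

    long_length_um: float = 20.0
    thick_width_um: float = 3.0
    aggregated_component_area_um2: float = 200.0
    intersection_merge_radius_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("long_length_um", "thick_width_um",
                     "aggregated_component_area_um2", "intersection_merge_radius_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


@dataclass
class FiberString:
    """One measured collagen fiber."""

    fiber_id: int
    pixel_count: int
    area_um2: float
    length_um: float
    width_um: float
    region: str = "rps"
    is_long: bool = False
    is_thick: bool = False
    is_aggregated: bool = False

    def __post_init__(self) -> None:
        if self.region not in ("portal", "periportal", "rps"):
            raise ValueError(f"invalid region {self.region!r}")


def _skeleton_arc_length_px(skeleton: np.ndarray) -> float:
    """Arc length (pixels) of a skeleton mask: orthogonal + sqrt(2) diagonal steps."""
    sk = np.asarray(skeleton, dtype=bool)
    n = int(sk.sum())
    if n == 0:
        return 0.0
    if n == 1:
        return 1.0
    # count each adjacent pair once: right, down, down-right, down-left
    orth = int((sk[:, :-1] & sk[:, 1:]).sum()) + int((sk[:-1, :] & sk[1:, :]).sum())
    diag = int((sk[:-1, :-1] & sk[1:, 1:]).sum()) + int((sk[:-1, 1:] & sk[1:, :-1]).sum())
    length = orth + diag * SQRT2
    # isolated fragments with no adjacencies still occupy one pixel each
    return max(length, 1.0)


def measure_length(component: np.ndarray, calibration: Calibration) -> float:
    """Skeleton arc length of one binary component, in micrometres."""
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("empty component")
    skel = skeletonize(component)
    if not skel.any():  # tiny blobs can skeletonize to nothing
        skel_len_px = 1.0
    else:
        skel_len_px = _skeleton_arc_length_px(skel)
    return calibration.px_to_um(skel_len_px)


def classify_fiber(fiber: FiberString, cfg: MorphometryConfig) -> FiberString:
    """Set the long/thick flags in place (short = not long, thin = not thick)."""
    fiber.is_long = fiber.length_um >= cfg.long_length_um
    fiber.is_thick = fiber.width_um >= cfg.thick_width_um
    return fiber


def classify_aggregation(
    fibers: list[FiberString], cfg: MorphometryConfig
) -> list[FiberString]:
    """Set the aggregated flag (distributed = not aggregated) in place."""
    for f in fibers:
        f.is_aggregated = f.area_um2 >= cfg.aggregated_component_area_um2
    return fibers


# region-assignment tie precedence: periportal is the region of interest
_REGION_PRECEDENCE = ("periportal", "portal", "rps")


def _assign_region(component_px: tuple[np.ndarray, np.ndarray], regions: RegionSet) -> str:
    counts = {
        name: int(regions.mask(name)[component_px].sum()) for name in _REGION_PRECEDENCE
    }
    best = max(counts.values())
    for name in _REGION_PRECEDENCE:
        if counts[name] == best:
            return name
    raise AssertionError("unreachable")


def extract_fibers(
    collagen: np.ndarray,
    regions: RegionSet,
    cfg: MorphometryConfig | None = None,
    calibration: Calibration | None = None,
) -> list[FiberString]:
    """Extract, measure and classify every fiber string in the collagen mask."""
    cfg = cfg or MorphometryConfig()
    cal = calibration or regions.calibration
    collagen = np.asarray(collagen, dtype=bool)
    if not collagen.any():
        return []
    labels, n = ndi.label(collagen, structure=STRUCTURE_8)
    skel = skeletonize(collagen)
    fibers: list[FiberString] = []
    objects = ndi.find_objects(labels)
    for fid, sl in enumerate(objects, start=1):
        comp = labels[sl] == fid
        px = int(comp.sum())
        area = cal.area_px_to_um2(px)
        comp_skel = skel[sl] & comp
        len_px = _skeleton_arc_length_px(comp_skel) if comp_skel.any() else 1.0
        length = cal.px_to_um(len_px)
        width = area / length
        where = np.nonzero(labels == fid)
        fiber = FiberString(
            fiber_id=fid,
            pixel_count=px,
            area_um2=area,
            length_um=length,
            width_um=width,
            region=_assign_region(where, regions),
        )
        classify_fiber(fiber, cfg)
        fibers.append(fiber)
    classify_aggregation(fibers, cfg)
    return fibers


def _branch_points(skeleton: np.ndarray) -> np.ndarray:
    """Skeleton pixels with >= 3 skeleton neighbours (8-neighbourhood)."""
    sk = np.asarray(skeleton, dtype=bool)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    neighbours = ndi.convolve(sk.astype(int), kernel, mode="constant")
    return sk & (neighbours >= 3)


def count_intersections(
    collagen: np.ndarray,
    region: np.ndarray,
    cfg: MorphometryConfig | None = None,
    calibration: Calibration | None = None,
) -> int:
    """Number of fiber intersections (merged skeleton branch points) in a region.

    Branch points closer than ``intersection_merge_radius_um`` are merged
    into one intersection; an intersection is counted for the region
    containing its (pixel-rounded) centroid.
    """
    cfg = cfg or MorphometryConfig()
    cal = calibration or Calibration()
    collagen = np.asarray(collagen, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if collagen.shape != region.shape:
        raise ValueError("collagen and region masks must share shape")
    if not collagen.any():
        return 0
    bp = _branch_points(skeletonize(collagen))
    pts = np.argwhere(bp)
    if len(pts) == 0:
        return 0
    radius_px = cal.um_to_px(cfg.intersection_merge_radius_um)
    # single-linkage clusters of branch points within the merge radius
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius_px, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    roots = np.array([find(i) for i in range(len(pts))])
    count = 0
    for root in np.unique(roots):
        centroid = pts[roots == root].mean(axis=0)
        r, c = int(round(centroid[0])), int(round(centroid[1]))
        r = min(max(r, 0), region.shape[0] - 1)
        c = min(max(c, 0), region.shape[1] - 1)
        if region[r, c]:
            count += 1
    return count
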