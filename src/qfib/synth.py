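"""Synthetic SHG/TPEF fixtures with exact ground truth.

The generator emulates the acquisition geometry of the real instrument
(isotropic 0.390625 um/px; default field 1024 x 1024 px = 400 x 400 um)
and the fibrosis-stage patterns of interest:

* F0-like: portal tract(s) present, essentially no stainable collagen;
* F1-like: sparse perisinusoidal fibers away from portal tracts, only a
  trace physiological background of periportal collagen;
* F2-like: perisinusoidal fibers plus a dense periportal collagen
  population around the portal tracts.

Two pathways share one stochastic model of the fiber population:

* the *truth* pathway samples portal-tract geometry and per-fiber
  measurements (Poisson fiber counts at the profile's rates per
  10^4 um^2 of region area; log-normal lengths and widths) and returns
  exact bookkeeping without rendering pixels — cheap enough for
  replicated cohort simulations;
* the *rendered* pathway additionally paints each fiber into the SHG
  channel as a smoothed random-walk polyline stroked to its target
  width (aggregated fibers as overlapping bundle strokes), rendering the
  TPEF channel as the tissue silhouette with bright portal disks, plus
  Gaussian noise on both channels.  Distinct fibers never touch, so an
  8-connected component of the noise-free collagen signal corresponds
  one-to-one to a ground-truth fiber.

All randomness flows from one seed; cohort members draw per-sample
sub-seeds from the master seed so any sample is individually
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .io import Calibration, DualChannelSlide
from .morphometry import FiberString, MorphometryConfig, count_intersections
from .parameters import ParameterVector, aggregate_parameters
from .regions import RegionConfig, RegionSet, build_periportal, build_rps
from .segmentation import MaskLayer

__all__ = [
    "StageProfile",
    "GroundTruth",
    "CohortSample",
    "F0LIKE",
    "F1LIKE",
    "F2LIKE",
    "PROFILES",
    "generate_slide",
    "generate_sample",
    "generate_cohort",
]

# rendering constants (intensity units on an 8-bit-like scale)
_TISSUE_INTENSITY = 180.0
_PORTAL_EXTRA = 60.0
_FIBER_INTENSITY = 210.0
# aggregated fibers draw from up-scaled size distributions (bundles)
_AGG_LENGTH_FACTOR = 2.0
_AGG_WIDTH_FACTOR = 6.0
# expected intersections per fiber (used for truth-level bookkeeping)
_INTERSECTIONS_PER_FIBER = 0.05


@dataclass(frozen=True)
class StageProfile:
    """Stage-dependent generative settings for one synthetic sample.

    Fiber rates are fibers per 10^4 um^2 of the region's area; length
    and width distributions are log-normal, given as (median um, log-sd).
    """

    name: str
    n_portal_tracts: int = 1
    portal_radius_um: tuple[float, float] = (30.0, 50.0)
    periportal_fiber_rate: float = 0.0
    rps_fiber_rate: float = 0.0
    fiber_length_um: tuple[float, float] = (15.0, 0.5)
    fiber_width_um: tuple[float, float] = (1.5, 0.35)
    aggregate_fraction: float = 0.0
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.periportal_fiber_rate < 0 or self.rps_fiber_rate < 0:
            raise ValueError("fiber rates must be >= 0")
        if not (0.0 <= self.aggregate_fraction <= 1.0):
            raise ValueError("aggregate_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


F0LIKE = StageProfile(name="F0like")
F1LIKE = StageProfile(
    name="F1like",
    periportal_fiber_rate=0.5,  # trace physiological periportal collagen
    rps_fiber_rate=3.0,
    aggregate_fraction=0.10,
)
F2LIKE = StageProfile(
    name="F2like",
    periportal_fiber_rate=6.0,
    rps_fiber_rate=4.5,
    aggregate_fraction=0.25,
)

PROFILES: dict[str, StageProfile] = {p.name: p for p in (F0LIKE, F1LIKE, F2LIKE)}


@dataclass
class GroundTruth:
    """Exact bookkeeping for one synthetic sample."""

    regions: RegionSet
    fibers: list[FiberString]
    intersections: dict[str, int]
    collagen: np.ndarray | None = None  # noise-free collagen mask (rendered path)

    def region_areas_um2(self) -> dict[str, float]:
        return {
            "periportal": self.regions.area_um2("periportal"),
            "rps": self.regions.area_um2("rps"),
        }

    def parameter_vector(
        self, sample_id: str = "", thresholds: MorphometryConfig | None = None
    ) -> ParameterVector:
        """The 56-parameter vector implied by the ground-truth fibers.

        Passing non-default ``thresholds`` re-derives the class flags
        from the stored measurements before aggregating.
        """
        fibers = self.fibers
        if thresholds is not None:
            fibers = [replace(f) for f in self.fibers]
            for f in fibers:
                f.is_long = f.length_um >= thresholds.long_length_um
                f.is_thick = f.width_um >= thresholds.thick_width_um
                f.is_aggregated = (
                    f.area_um2 >= thresholds.aggregated_component_area_um2
                )
        return aggregate_parameters(
            fibers,
            self.region_areas_um2(),
            self.intersections,
            sample_id=sample_id,
            thresholds=thresholds,
        )


def _make_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _tissue_mask(
    shape: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Elliptical tissue silhouette; returns (mask, (cy, cx, ry, rx))."""
    h, w = shape
    ry = (0.45 + 0.02 * rng.random()) * h
    rx = (0.45 + 0.02 * rng.random()) * w
    cy, cx = h / 2.0, w / 2.0
    yy = ((np.arange(h) - cy) / ry) ** 2
    xx = ((np.arange(w) - cx) / rx) ** 2
    mask = yy[:, None] + xx[None, :] <= 1.0
    return mask, (cy, cx, ry, rx)


def _ellipse_boundary_distance(
    r: float, c: float, ellipse: tuple[float, float, float, float]
) -> float:
    """Conservative distance (px) from an interior point to the ellipse edge."""
    cy, cx, ry, rx = ellipse
    rho = math.hypot((r - cy) / ry, (c - cx) / rx)
    return (1.0 - rho) * min(ry, rx)


def _place_portal_tracts(
    ellipse: tuple[float, float, float, float],
    shape: tuple[int, int],
    profile: StageProfile,
    cal: Calibration,
    rng: np.random.Generator,
) -> np.ndarray:
    """Non-overlapping portal disks fully inside the tissue ellipse."""
    portal = np.zeros(shape, dtype=bool)
    centers: list[tuple[float, float, float]] = []
    rmin, rmax = profile.portal_radius_um
    for _ in range(profile.n_portal_tracts):
        radius_um = rng.uniform(rmin, rmax)
        radius_px = cal.um_to_px(radius_um)
        placed = False
        for _attempt in range(300):
            r = rng.uniform(0, shape[0])
            c = rng.uniform(0, shape[1])
            if _ellipse_boundary_distance(r, c, ellipse) < radius_px + 8:
                continue
            if any(
                math.hypot(r - r0, c - c0) < radius_px + rad0 + 30 for r0, c0, rad0 in centers
            ):
                continue
            centers.append((r, c, radius_px))
            rr, cc = draw_disk((r, c), radius_px, shape=shape)
            portal[rr, cc] = True
            placed = True
            break
        if not placed:
            raise ValueError(
                f"profile {profile.name!r} infeasible for field {shape}: "
                "could not place portal tracts"
            )
    return portal


def _sample_fiber(
    profile: StageProfile,
    region: str,
    fiber_id: int,
    cal: Calibration,
    cfg: MorphometryConfig,
    rng: np.random.Generator,
) -> FiberString:
    aggregated_draw = rng.random() < profile.aggregate_fraction
    med_l, sd_l = profile.fiber_length_um
    med_w, sd_w = profile.fiber_width_um
    length = med_l * math.exp(sd_l * rng.standard_normal())
    width = med_w * math.exp(sd_w * rng.standard_normal())
    if aggregated_draw:
        length *= _AGG_LENGTH_FACTOR
        width *= _AGG_WIDTH_FACTOR
    area = length * width
    pixel_count = max(1, round(area / cal.um2_per_pixel))
    area = pixel_count * cal.um2_per_pixel  # quantise to the pixel grid
    width = area / length
    f = FiberString(
        fiber_id=fiber_id,
        pixel_count=pixel_count,
        area_um2=area,
        length_um=length,
        width_um=width,
        region=region,
    )
    f.is_long = f.length_um >= cfg.long_length_um
    f.is_thick = f.width_um >= cfg.thick_width_um
    f.is_aggregated = f.area_um2 >= cfg.aggregated_component_area_um2
    return f


def _truth_fibers(
    profile: StageProfile,
    regions: RegionSet,
    cal: Calibration,
    cfg: MorphometryConfig,
    rng: np.random.Generator,
) -> list[FiberString]:
    fibers: list[FiberString] = []
    fid = 1
    for region, rate in (
        ("periportal", profile.periportal_fiber_rate),
        ("rps", profile.rps_fiber_rate),
    ):
        n = rng.poisson(rate * regions.area_um2(region) / 1e4)
        for _ in range(n):
            fibers.append(_sample_fiber(profile, region, fid, cal, cfg, rng))
            fid += 1
    return fibers


def _truth_intersections(
    fibers: list[FiberString], rng: np.random.Generator
) -> dict[str, int]:
    out = {}
    for region in ("periportal", "rps"):
        n = sum(1 for f in fibers if f.region == region)
        out[region] = int(rng.poisson(_INTERSECTIONS_PER_FIBER * n))
    return out


def _walk_polyline(
    start: tuple[int, int],
    length_px: float,
    domain: np.ndarray,
    rng: np.random.Generator,
    step_px: float = 2.0,
) -> list[tuple[int, int]]:
    """Smoothed random walk of the requested arc length inside a domain."""
    h, w = domain.shape
    theta = rng.uniform(0, 2 * math.pi)
    pts = [(float(start[0]), float(start[1]))]
    walked = 0.0
    while walked < length_px:
        for _try in range(8):
            cand = theta + rng.normal(0, 0.35)
            nr = pts[-1][0] + step_px * math.sin(cand)
            nc = pts[-1][1] + step_px * math.cos(cand)
            ir, ic = int(round(nr)), int(round(nc))
            if 0 <= ir < h and 0 <= ic < w and domain[ir, ic]:
                theta = cand
                pts.append((nr, nc))
                walked += step_px
                break
        else:
            break  # boxed in: stop early
    return [(int(round(r)), int(round(c))) for r, c in pts]


def _stroke(points: list[tuple[int, int]], radius_px: int, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polyline thickened to the given radius.

    The painting happens in a local window around the polyline's
    bounding box so stroking stays cheap on large frames.
    """
    mask = np.zeros(shape, dtype=bool)
    rows = [p[0] for p in points]
    cols = [p[1] for p in points]
    pad = radius_px + 1
    r0w = max(0, min(rows) - pad)
    r1w = min(shape[0], max(rows) + pad + 1)
    c0w = max(0, min(cols) - pad)
    c1w = min(shape[1], max(cols) + pad + 1)
    win = np.zeros((r1w - r0w, c1w - c0w), dtype=bool)
    for (ra, ca), (rb, cb) in zip(points[:-1], points[1:]):
        rr, cc = draw_line(ra - r0w, ca - c0w, rb - r0w, cb - c0w)
        keep = (rr >= 0) & (rr < win.shape[0]) & (cc >= 0) & (cc < win.shape[1])
        win[rr[keep], cc[keep]] = True
    if len(points) == 1:
        win[points[0][0] - r0w, points[0][1] - c0w] = True
    if radius_px >= 1:
        win = ndi.binary_dilation(win, structure=disk_footprint(radius_px))
    mask[r0w:r1w, c0w:c1w] = win
    return mask


def _polyline_length_px(points: list[tuple[int, int]]) -> float:
    return sum(
        math.hypot(r1 - r0, c1 - c0)
        for (r0, c0), (r1, c1) in zip(points[:-1], points[1:])
    )


def _render_fiber(
    target: FiberString,
    region_interior_px: np.ndarray,
    forbidden: np.ndarray,
    cal: Calibration,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Paint one fiber inside its region without touching other fibers.

    ``region_interior_px`` is the region's interior distance transform
    (distance to the region border in pixels, precomputed once per
    region); ``forbidden`` is the running no-go mask (existing fibers
    dilated by the separation gap).  Returns the fiber's pixel mask, or
    None when no non-touching placement was found.
    """
    shape = forbidden.shape
    radius_px = max(0, int(round(cal.um_to_px(target.width_um) / 2 - 0.5)))
    # keep the stroke inside the region and clear of other fibers
    domain = (region_interior_px > radius_px + 2) & ~forbidden
    candidates = np.flatnonzero(domain)
    if candidates.size == 0:
        return None
    length_px = cal.um_to_px(target.length_um)
    for _try in range(20):
        flat = int(rng.choice(candidates))
        start = (flat // shape[1], flat % shape[1])
        pts = _walk_polyline(start, length_px, domain, rng)
        mask = _stroke(pts, radius_px, shape)
        if target.is_aggregated and len(pts) > 2:
            # overlapping side strokes give aggregated fibers a bundled look
            for sign in (-1, 1):
                off = max(1, radius_px)
                shifted = [(r + sign * off, c) for r, c in pts]
                mask |= _stroke(shifted, max(1, radius_px // 2), shape)
        if not (mask & forbidden).any():
            return mask
    return None


#: separation gap (px) kept between distinct rendered fibers
_FIBER_GAP_PX = 2


def _forbid(forbidden: np.ndarray, mask: np.ndarray) -> None:
    """Add a painted mask, dilated by the separation gap, to the no-go mask."""
    if not mask.any():
        return
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    pad = _FIBER_GAP_PX + 1
    r0 = max(0, rows[0] - pad)
    r1 = min(mask.shape[0], rows[-1] + pad + 1)
    c0 = max(0, cols[0] - pad)
    c1 = min(mask.shape[1], cols[-1] + pad + 1)
    window = ndi.binary_dilation(
        mask[r0:r1, c0:c1], structure=disk_footprint(_FIBER_GAP_PX)
    )
    forbidden[r0:r1, c0:c1] |= window


def _portal_rim_collagen(portal: np.ndarray, cal: Calibration) -> np.ndarray:
    """Collagen-rich rim just inside each portal tract's boundary."""
    inner = ndi.binary_erosion(portal, structure=disk_footprint(2))
    deeper = ndi.binary_erosion(portal, structure=disk_footprint(4))
    return inner & ~deeper


def generate_sample(
    profile: StageProfile,
    size_px: tuple[int, int] = (1024, 1024),
    calibration: Calibration | None = None,
    seed: int | np.random.SeedSequence = 0,
    render: bool = False,
    morph_cfg: MorphometryConfig | None = None,
    region_cfg: RegionConfig | None = None,
    sample_id: str = "synthetic",
) -> tuple[DualChannelSlide | None, GroundTruth]:
    """Generate one synthetic sample; ``render=False`` skips the pixels.

    Deterministic for a fixed seed.  The slide is None on the truth-only
    pathway.
    """
    cal = calibration or Calibration()
    morph_cfg = morph_cfg or MorphometryConfig()
    region_cfg = region_cfg or RegionConfig()
    rng = _make_rng(seed)
    rmax_px = cal.um_to_px(profile.portal_radius_um[1])
    if min(size_px) * 0.4 < rmax_px + 20:
        raise ValueError(f"field {size_px} too small for profile {profile.name!r}")
    tissue, ellipse = _tissue_mask(size_px, rng)
    portal = _place_portal_tracts(ellipse, size_px, profile, cal, rng)
    tissue_layer = MaskLayer("tissue", tissue, cal)
    portal_layer = MaskLayer("portal", portal, cal)
    periportal = build_periportal(portal_layer, tissue_layer, region_cfg)
    rps = build_rps(tissue_layer, portal, periportal)
    regions = RegionSet(portal=portal, periportal=periportal, rps=rps, tissue=tissue,
                        calibration=cal)
    regions.validate()

    planned = _truth_fibers(profile, regions, cal, morph_cfg, rng)

    if not render:
        truth = GroundTruth(
            regions=regions,
            fibers=planned,
            intersections=_truth_intersections(planned, rng),
        )
        return None, truth

    collagen = np.zeros(size_px, dtype=bool)
    rim = _portal_rim_collagen(portal, cal)
    collagen |= rim
    # interior distance of each target region, computed once
    interiors = {
        name: ndi.distance_transform_edt(regions.mask(name))
        for name in ("periportal", "rps")
    }
    forbidden = np.zeros(size_px, dtype=bool)
    _forbid(forbidden, rim)
    realized: list[FiberString] = []
    fid = 1
    for target in planned:
        mask = _render_fiber(target, interiors[target.region], forbidden, cal, rng)
        if mask is None:
            continue
        collagen |= mask
        _forbid(forbidden, mask)
        px = int(mask.sum())
        area = cal.area_px_to_um2(px)
        # arc length actually walked; width follows from the painted area
        where = np.nonzero(mask)
        counts = {
            name: int(regions.mask(name)[where].sum())
            for name in ("periportal", "portal", "rps")
        }
        region = max(("periportal", "portal", "rps"), key=lambda n: counts[n])
        f = FiberString(
            fiber_id=fid,
            pixel_count=px,
            area_um2=area,
            length_um=max(target.length_um, cal.microns_per_pixel),
            width_um=area / max(target.length_um, cal.microns_per_pixel),
            region=region,
        )
        f.is_long = f.length_um >= morph_cfg.long_length_um
        f.is_thick = f.width_um >= morph_cfg.thick_width_um
        f.is_aggregated = f.area_um2 >= morph_cfg.aggregated_component_area_um2
        realized.append(f)
        fid += 1
    if rim.any():
        realized.append(
            FiberString(
                fiber_id=fid,
                pixel_count=int(rim.sum()),
                area_um2=cal.area_px_to_um2(int(rim.sum())),
                length_um=cal.px_to_um(max(1.0, rim.sum() / 3.0)),
                width_um=3.0 * cal.microns_per_pixel,
                region="portal",
            )
        )

    intersections = {
        region: count_intersections(collagen, regions.mask(region), morph_cfg, cal)
        for region in ("periportal", "rps")
    }

    shg = np.zeros(size_px, dtype=float)
    shg[collagen] = _FIBER_INTENSITY
    tpef = np.zeros(size_px, dtype=float)
    tpef[tissue] = _TISSUE_INTENSITY
    tpef[portal] += _PORTAL_EXTRA
    if profile.noise_sd > 0:
        shg = shg + rng.normal(0, profile.noise_sd, size_px)
        tpef = tpef + rng.normal(0, profile.noise_sd, size_px)
    slide = DualChannelSlide(
        shg=np.clip(shg, 0, None),
        tpef=np.clip(tpef, 0, None),
        calibration=cal,
        sample_id=sample_id,
        acquisition_meta={"excitation_nm": 780, "shg_nm": 390, "tpef_nm": 550,
                          "synthetic": True},
    )
    truth = GroundTruth(
        regions=regions, fibers=realized, intersections=intersections, collagen=collagen
    )
    return slide, truth


def generate_slide(
    profile: StageProfile,
    size_px: tuple[int, int] = (1024, 1024),
    calibration: Calibration | None = None,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> tuple[DualChannelSlide, GroundTruth]:
    """Generate a fully rendered synthetic slide with its ground truth."""
    slide, truth = generate_sample(
        profile, size_px=size_px, calibration=calibration, seed=seed, render=True,
        **kwargs,
    )
    assert slide is not None
    return slide, truth


@dataclass
class CohortSample:
    sample_id: str
    group: str
    slide: DualChannelSlide | None
    truth: GroundTruth


def generate_cohort(
    n_per_group: int,
    profiles: tuple[StageProfile, StageProfile] = (F1LIKE, F2LIKE),
    seed: int = 0,
    size_px: tuple[int, int] = (1024, 1024),
    calibration: Calibration | None = None,
    render: bool = False,
    morph_cfg: MorphometryConfig | None = None,
    labels: tuple[str, str] | None = None,
) -> list[CohortSample]:
    """Generate a balanced two-group cohort with per-sample sub-seeds.

    ``labels`` names the two groups; required to be distinct, which
    matters for null cohorts drawing both groups from one profile.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if labels is None:
        labels = (profiles[0].name, profiles[1].name)
        if labels[0] == labels[1]:
            labels = (labels[0] + "-a", labels[1] + "-b")
    if labels[0] == labels[1]:
        raise ValueError("group labels must be distinct")
    master = np.random.SeedSequence(seed)
    samples: list[CohortSample] = []
    idx = 0
    for profile, label in zip(profiles, labels):
        for k in range(n_per_group):
            sub = np.random.SeedSequence(entropy=master.entropy, spawn_key=(idx,))
            sid = f"{label}-{k:03d}"
            slide, truth = generate_sample(
                profile, size_px=size_px, calibration=calibration, seed=sub,
                render=render, morph_cfg=morph_cfg, sample_id=sid,
            )
            samples.append(CohortSample(sid, label, slide, truth))
            idx += 1
    return samples


def truth_cohort_table(samples: list[CohortSample], morph_cfg: MorphometryConfig | None = None):
    """Build a CohortTable from ground-truth parameter vectors."""
    import pandas as pd

    from .stats import CohortTable

    rows = {
        s.sample_id: s.truth.parameter_vector(s.sample_id, morph_cfg).values
        for s in samples
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    group = pd.Series({s.sample_id: s.group for s in samples})
    return CohortTable(values=df, group=group)
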