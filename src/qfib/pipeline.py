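"""Per-sample quantification: slide + portal annotation -> 56 parameters."""

from __future__ import annotations

from .config import RunConfig
from .io import DualChannelSlide
from .morphometry import count_intersections, extract_fibers
from .parameters import compute_parameters
from .regions import partition
from .segmentation import (
    MaskLayer,
    detect_portal_tracts,
    load_portal_mask,
    segment_collagen,
    segment_tissue,
)

__all__ = ["quantify_slide"]


import numpy as np


def quantify_slide(
    slide: DualChannelSlide,
    portal_mask=None,
    config: RunConfig | None = None,
    return_intermediates: bool = False,
):
    """Run the full quantification pipeline on one slide.

    Segments tissue (TPEF) and collagen (SHG), builds the portal /
    periportal / reduced-perisinusoidal partition from the portal
    annotation (a mask file path, array or MaskLayer; or the
    experimental heuristic detector when no annotation is given and
    ``portal_source`` is "heuristic"), extracts and classifies fiber
    strings, counts intersections and aggregates the 56-parameter
    vector.
    """
    config = config or RunConfig()
    seg = config.segmentation
    tissue = segment_tissue(slide, seg)
    collagen = segment_collagen(slide, seg, tissue=tissue)
    if isinstance(portal_mask, MaskLayer):
        portal = MaskLayer("portal", portal_mask.mask & tissue.mask, slide.calibration)
    elif isinstance(portal_mask, np.ndarray):
        portal = MaskLayer("portal", portal_mask & tissue.mask, slide.calibration)
    elif portal_mask is not None:
        portal = load_portal_mask(portal_mask, slide, tissue=tissue)
    elif seg.portal_source == "heuristic":
        portal = detect_portal_tracts(slide, tissue, seg)
    else:
        raise ValueError(
            "no portal annotation given and portal_source != 'heuristic'"
        )
    regions = partition(slide, tissue, portal, config.regions)
    fibers = extract_fibers(collagen.mask, regions, config.morphometry)
    intersections = {
        name: count_intersections(
            collagen.mask, regions.mask(name), config.morphometry, slide.calibration
        )
        for name in ("periportal", "rps")
    }
    vector = compute_parameters(
        fibers, regions, intersections,
        sample_id=slide.sample_id, thresholds=config.morphometry,
    )
    if return_intermediates:
        return vector, {
            "tissue": tissue,
            "collagen": collagen,
            "portal": portal,
            "regions": regions,
            "fibers": fibers,
            "intersections": intersections,
        }
    return vector
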