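"""Calibrated image, mask, manifest and parameter-table I/O.

Images are dual-channel rasters: channel 1 is the second-harmonic
generation (SHG) collagen signal, channel 2 is the two-photon excited
fluorescence (TPEF) tissue autofluorescence.  The acquisition geometry is
a 512 x 512 px tile covering 200 x 200 um, i.e. 0.390625 um/px isotropic;
whole-section images are row-major mosaics of abutting tiles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Calibration",
    "DualChannelSlide",
    "SampleManifest",
    "ManifestRecord",
    "read_slide",
    "write_slide",
    "read_mask",
    "write_mask",
    "stitch_tiles",
    "split_into_tiles",
    "write_parameter_table",
    "read_parameter_table",
    "read_manifest",
    "write_manifest",
]

#: Default acquisition scale: 200 um tile edge / 512 px tile edge.
DEFAULT_MICRONS_PER_PIXEL = 200.0 / 512.0

STAGE_LABELS = frozenset({"F0", "F1", "F2", "F3", "F4"})


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel calibration of an acquisition.

    Parameters
    ----------
    microns_per_pixel : float
        Physical edge length of one pixel in micrometres.  Must be > 0.
    tile_pixels : int, optional
        Tile edge in pixels (default 512).
    tile_microns : float, optional
        Tile edge in micrometres (default 200.0).  When both tile fields
        are provided they must be consistent with ``microns_per_pixel``.
    """

    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    tile_pixels: int = 512
    tile_microns: float = 200.0

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be > 0")
        if self.tile_pixels is not None and self.tile_microns is not None:
            implied = self.tile_microns / self.tile_pixels
            if abs(implied - self.microns_per_pixel) > 1e-9 * max(implied, 1.0):
                raise ValueError(
                    f"inconsistent calibration: {self.tile_microns} um / "
                    f"{self.tile_pixels} px = {implied} != {self.microns_per_pixel}"
                )

    @property
    def um2_per_pixel(self) -> float:
        return self.microns_per_pixel**2

    def px_to_um(self, px: float) -> float:
        return px * self.microns_per_pixel

    def um_to_px(self, um: float) -> float:
        return um / self.microns_per_pixel

    def area_px_to_um2(self, n_pixels: float) -> float:
        return n_pixels * self.um2_per_pixel


@dataclass
class DualChannelSlide:
    """One calibrated SHG + TPEF raster pair for a biopsy section.

    ``shg`` and ``tpef`` are float arrays of identical shape with finite,
    non-negative intensities.  ``acquisition_meta`` carries descriptive
    metadata only (e.g. excitation 780 nm, SHG 390 nm, TPEF 550 nm).
    """

    shg: np.ndarray
    tpef: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    sample_id: str = ""
    acquisition_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shg = np.asarray(self.shg, dtype=float)
        self.tpef = np.asarray(self.tpef, dtype=float)
        if self.shg.ndim != 2 or self.tpef.ndim != 2:
            raise ValueError("channels must be 2-D")
        if self.shg.shape != self.tpef.shape:
            raise ValueError(
                f"channel shape mismatch: shg {self.shg.shape} vs tpef {self.tpef.shape}"
            )
        for name, arr in (("shg", self.shg), ("tpef", self.tpef)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite intensities")
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape


@dataclass(frozen=True)
class ManifestRecord:
    sample_id: str
    stage_label: str
    group_label: str = ""
    image_path: str = ""
    portal_mask_path: str = ""

    def __post_init__(self) -> None:
        if self.stage_label not in STAGE_LABELS:
            raise ValueError(
                f"stage_label {self.stage_label!r} not in {sorted(STAGE_LABELS)}"
            )


@dataclass
class SampleManifest:
    """Cohort manifest: one record per sample, unique sample ids."""

    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in manifest")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _as_float_channels(arr: np.ndarray) -> np.ndarray:
    """Coerce a tifffile array to (C, H, W) float, C first."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return arr[None].astype(float)
    if arr.ndim != 3:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    # channel axis = smallest axis (channels-last PNG/TIFF or pages-first TIFF)
    caxis = int(np.argmin(arr.shape))
    arr = np.moveaxis(arr, caxis, 0)
    return arr.astype(float)


def read_slide(
    image_path: str | Path,
    calibration: Calibration | None = None,
    *,
    tpef_path: str | Path | None = None,
    sample_id: str | None = None,
) -> DualChannelSlide:
    """Read a calibrated dual-channel slide.

    Either ``image_path`` holds a multi-channel image (SHG first, TPEF
    second), or ``tpef_path`` names a sibling single-channel file and
    ``image_path`` holds the SHG channel alone.
    """
    image_path = Path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(str(image_path))
    calibration = calibration or Calibration()
    if tpef_path is not None:
        tpef_path = Path(tpef_path)
        if not tpef_path.exists():
            raise FileNotFoundError(str(tpef_path))
        shg = _as_float_channels(tifffile.imread(image_path))[0]
        tpef = _as_float_channels(tifffile.imread(tpef_path))[0]
    else:
        channels = _as_float_channels(tifffile.imread(image_path))
        if channels.shape[0] < 2:
            raise ValueError(
                f"channel count < 2 in {image_path} (got {channels.shape[0]}); "
                "pass tpef_path for paired single-channel files"
            )
        shg, tpef = channels[0], channels[1]
    return DualChannelSlide(
        shg=shg,
        tpef=tpef,
        calibration=calibration,
        sample_id=sample_id or image_path.stem,
    )


def write_slide(slide: DualChannelSlide, path: str | Path) -> None:
    """Write a slide as a 2-page TIFF (page 0 = SHG, page 1 = TPEF)."""
    stack = np.stack([slide.shg, slide.tpef]).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (PNG or TIFF); nonzero means inside."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    if arr.ndim == 3:  # collapse any colour axis
        arr = arr.max(axis=int(np.argmin(arr.shape)))
    return np.asarray(arr) != 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    out = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), out)
    else:
        iio.imwrite(str(path), out)


def stitch_tiles(
    tiles: Sequence[DualChannelSlide], grid_shape: tuple[int, int]
) -> DualChannelSlide:
    """Assemble a row-major grid of abutting tiles into one mosaic.

    All tiles must share shape and calibration; no blending is applied.
    """
    rows, cols = grid_shape
    if len(tiles) != rows * cols:
        raise ValueError(f"expected {rows * cols} tiles, got {len(tiles)}")
    ref = tiles[0]
    for t in tiles[1:]:
        if t.shape != ref.shape:
            raise ValueError("tile shape mismatch")
        if t.calibration != ref.calibration:
            raise ValueError("tile calibration mismatch")
    shg = np.block([[tiles[r * cols + c].shg for c in range(cols)] for r in range(rows)])
    tpef = np.block(
        [[tiles[r * cols + c].tpef for c in range(cols)] for r in range(rows)]
    )
    return DualChannelSlide(
        shg=shg,
        tpef=tpef,
        calibration=ref.calibration,
        sample_id=ref.sample_id,
        acquisition_meta=dict(ref.acquisition_meta),
    )


def split_into_tiles(
    slide: DualChannelSlide, tile_shape: tuple[int, int]
) -> tuple[list[DualChannelSlide], tuple[int, int]]:
    """Inverse of :func:`stitch_tiles` for evenly divisible mosaics."""
    th, tw = tile_shape
    h, w = slide.shape
    if h % th or w % tw:
        raise ValueError("slide dimensions not divisible by tile shape")
    rows, cols = h // th, w // tw
    tiles = []
    for r in range(rows):
        for c in range(cols):
            sl = np.s_[r * th : (r + 1) * th, c * tw : (c + 1) * tw]
            tiles.append(
                DualChannelSlide(
                    shg=slide.shg[sl].copy(),
                    tpef=slide.tpef[sl].copy(),
                    calibration=slide.calibration,
                    sample_id=slide.sample_id,
                )
            )
    return tiles, (rows, cols)


def write_parameter_table(vectors: Iterable, path: str | Path) -> None:
    """Write parameter vectors to CSV: one row per sample, schema order.

    All vectors must share the same parameter schema; an empty list writes
    a header-only CSV with the canonical 56-name schema.
    """
    from .parameters import parameter_schema

    vectors = list(vectors)
    if vectors:
        schema = list(vectors[0].values.keys())
        for v in vectors[1:]:
            if list(v.values.keys()) != schema:
                raise ValueError("parameter schema mismatch between vectors")
        df = pd.DataFrame(
            [[v.values[name] for name in schema] for v in vectors],
            columns=schema,
            index=pd.Index([v.sample_id for v in vectors], name="sample_id"),
        )
    else:
        df = pd.DataFrame(
            columns=parameter_schema(), index=pd.Index([], name="sample_id")
        )
    df.to_csv(path)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a parameter table written by :func:`write_parameter_table`."""
    return pd.read_csv(path, index_col="sample_id")


_MANIFEST_COLUMNS = [
    "sample_id",
    "stage_label",
    "group_label",
    "image_path",
    "portal_mask_path",
]


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"sample_id", "stage_label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = [
        ManifestRecord(
            sample_id=row["sample_id"],
            stage_label=row["stage_label"],
            group_label=row.get("group_label", ""),
            image_path=row.get("image_path", ""),
            portal_mask_path=row.get("portal_mask_path", ""),
        )
        for _, row in df.iterrows()
    ]
    return SampleManifest(records)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in manifest.records])
    df = df.reindex(columns=_MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
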