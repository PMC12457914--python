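"""Plate-image processing: white balance, nut segmentation, kernel annotation.

A *plate* is a photograph of whole pistachio nuts laid out on a white
background.  Each plate of whole nuts is paired with a photograph of the same
nuts cut open in the same positions, from which the kernel status (filled or
blank) of every position is read off and copied onto the whole-nut records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

KERNEL_STATES = ("blank", "filled", "unknown")


@dataclass
class PixelEnsemble:
    """A nut's pixels: (x, y) integer positions paired with (r, g, b) colours.

    Coordinates are 0-based with x = column, y = row and the origin at the
    top-left of the source image; every pixel is a five-dimensional
    measurement (x, y, r, g, b).
    """

    coords: np.ndarray  # (n, 2) int, columns (x, y)
    colours: np.ndarray  # (n, 3) uint8

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.colours = np.asarray(self.colours, dtype=np.uint8).reshape(-1, 3)
        if len(self.coords) != len(self.colours):
            raise ValueError(
                f"coords ({len(self.coords)}) and colours ({len(self.colours)}) "
                "must be parallel"
            )

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class NutRecord:
    """One segmented nut: identifier, pixel ensemble and kernel status."""

    nut_id: str
    pixels: PixelEnsemble
    kernel_status: str = "unknown"
    centroid: tuple[float, float] | None = None  # (x, y)
    contour: np.ndarray | None = None  # (m, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        if self.kernel_status not in KERNEL_STATES:
            raise ValueError(f"kernel_status must be one of {KERNEL_STATES}")
        if len(self.pixels) == 0:
            raise ValueError(f"nut {self.nut_id}: empty pixel ensemble")


@dataclass
class PlateImage:
    """An H x W x 3 8-bit RGB photograph plus plate metadata."""

    pixels: np.ndarray
    plate_id: str = "plate"
    ct_label: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("plate image must be H x W x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("plate image must be nonempty")

    @classmethod
    def load(cls, path, plate_id: str | None = None, ct_label: str = "unknown") -> "PlateImage":
        from pathlib import Path

        img = Image.open(path).convert("RGB")
        pid = plate_id if plate_id is not None else Path(path).stem
        return cls(np.asarray(img, dtype=np.uint8), plate_id=pid, ct_label=ct_label)

    def save(self, path) -> None:
        Image.fromarray(self.pixels.astype(np.uint8)).save(path)


@dataclass
class SegmentationConfig:
    """Tunable segmentation parameters.

    block_size : odd window (pixels) of the local-mean adaptive threshold.
    offset : constant C subtracted from the local mean; a pixel is foreground
        when its luminance falls below ``local_mean - offset``.
    min_area_frac : minimum nut area as a fraction of the image area, used to
        reject specks.
    contour_epsilon_frac : Douglas-Peucker tolerance as a fraction of the
        contour perimeter.
    """

    block_size: int = 51
    offset: float = 5.0
    min_area_frac: float = 0.0005
    contour_epsilon_frac: float = 0.005

    def __post_init__(self) -> None:
        if self.block_size % 2 == 0 or self.block_size < 3:
            raise ValueError("block_size must be odd and >= 3")


def _luminance(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def white_balance(
    plate: PlateImage,
    min_background_luminance: float = 140.0,
    min_background_frac: float = 0.05,
) -> PlateImage:
    """Neutralize a colour cast using the white plate background.

    A diagonal (von Kries) per-channel scaling is estimated from the mean RGB
    of the brightest-quartile background pixels, so that the background maps
    to a neutral grey of the same luminance.  The gain vector is recorded in
    the returned plate's metadata under ``"wb_gains"``.

    Raises
    ------
    ValueError
        If fewer than ``min_background_frac`` of the pixels are bright enough
        (luminance >= ``min_background_luminance``) to act as a white
        background estimate.
    """
    img = plate.pixels.astype(np.float64)
    lum = _luminance(img)
    candidates = lum >= min_background_luminance
    if candidates.mean() < min_background_frac:
        raise ValueError(
            "no near-white background found: only "
            f"{candidates.mean():.1%} of pixels have luminance >= "
            f"{min_background_luminance} (need >= {min_background_frac:.0%})"
        )
    # brightest quartile of the background candidates -> white estimate
    cand_lum = lum[candidates]
    q75 = np.quantile(cand_lum, 0.75)
    white_mask = candidates & (lum >= q75)
    white = img[white_mask].mean(axis=0)  # mean RGB of the white estimate
    target = white.mean()
    gains = target / np.maximum(white, 1e-9)
    corrected = np.clip(img * gains, 0, 255).astype(np.uint8)
    meta = dict(plate.metadata)
    meta["wb_gains"] = tuple(float(g) for g in gains)
    return PlateImage(corrected, plate_id=plate.plate_id, ct_label=plate.ct_label, metadata=meta)


def _simplify_contour(contour_xy: np.ndarray, epsilon_frac: float) -> np.ndarray:
    """Douglas-Peucker simplification with tolerance relative to perimeter."""
    if len(contour_xy) < 3:
        return contour_xy
    perim = np.linalg.norm(np.diff(contour_xy, axis=0), axis=1).sum()
    return measure.approximate_polygon(contour_xy, tolerance=epsilon_frac * perim)


def segment_plate(plate: PlateImage, cfg: SegmentationConfig | None = None) -> list[NutRecord]:
    """Detect nuts on a white-balanced plate and extract their pixel ensembles.

    Foreground is found by adaptive thresholding of the luminance channel
    (local mean over ``cfg.block_size``, offset ``cfg.offset``); interior
    holes are filled and connected components become candidate nuts.
    Components touching the image border are discarded, as are components
    smaller than ``cfg.min_area_frac`` of the image.  Surviving nuts are
    labelled 1..N top-to-bottom by centroid row (ties broken left-to-right
    by centroid column).
    """
    cfg = cfg or SegmentationConfig()
    lum = _luminance(plate.pixels)
    local_mean = ndimage.uniform_filter(lum, size=cfg.block_size, mode="nearest")
    mask = lum < (local_mean - cfg.offset)
    mask = ndimage.binary_fill_holes(mask)
    # 8-connectivity so thin diagonal structures (nut tips) stay attached
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n_comp == 0:
        logger.warning("plate %s: zero detections", plate.plate_id)
        return []

    h, w = lum.shape
    min_area = cfg.min_area_frac * h * w
    regions = measure.regionprops(labels)
    kept = []
    for r in regions:
        minr, minc, maxr, maxc = r.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            continue  # touches the border: plate edge or clipped nut
        if r.area < min_area:
            continue
        kept.append(r)
    if not kept:
        logger.warning("plate %s: zero detections after filtering", plate.plate_id)
        return []

    # label 1..N by centroid row, ties by centroid column
    kept.sort(key=lambda r: (r.centroid[0], r.centroid[1]))

    records: list[NutRecord] = []
    for ordinal, r in enumerate(kept, start=1):
        rows, cols = np.nonzero(labels == r.label)
        coords = np.column_stack([cols, rows])  # x = column, y = row
        colours = plate.pixels[rows, cols]
        sub = (labels[r.bbox[0]:r.bbox[2], r.bbox[1]:r.bbox[3]] == r.label)
        cs = measure.find_contours(sub.astype(float), 0.5)
        contour = None
        if cs:
            c = max(cs, key=len)  # (row, col) in bbox frame
            contour = np.column_stack([c[:, 1] + r.bbox[1], c[:, 0] + r.bbox[0]])
            contour = _simplify_contour(contour, cfg.contour_epsilon_frac)
        records.append(
            NutRecord(
                nut_id=f"{plate.plate_id}-{ordinal}",
                pixels=PixelEnsemble(coords, colours),
                centroid=(float(r.centroid[1]), float(r.centroid[0])),
                contour=contour,
            )
        )
    return records


def annotate_kernel_status(
    whole: list[NutRecord],
    open_plate: list[NutRecord] | None,
    open_labels: list[str],
) -> list[NutRecord]:
    """Copy kernel status from the opened plate onto whole-nut records.

    The two plates photograph the same nuts in the same positions, so records
    match by ordinal.  ``open_labels`` gives blank/filled per opened-nut
    ordinal; ``open_plate`` may be None when labels were scored by eye.
    """
    if open_plate is not None and len(whole) != len(open_plate):
        n = min(len(whole), len(open_plate))
        missing = list(range(n + 1, max(len(whole), len(open_plate)) + 1))
        raise ValueError(
            f"whole plate has {len(whole)} nuts but open plate has "
            f"{len(open_plate)}; unmatched ordinals: {missing}"
        )
    if len(whole) != len(open_labels):
        n = min(len(whole), len(open_labels))
        missing = list(range(n + 1, max(len(whole), len(open_labels)) + 1))
        raise ValueError(
            f"{len(whole)} whole nuts vs {len(open_labels)} labels; "
            f"unmatched ordinals: {missing}"
        )
    bad = sorted({lab for lab in open_labels} - {"blank", "filled"})
    if bad:
        raise ValueError(f"labels must be 'blank' or 'filled'; got {bad}")
    return [
        NutRecord(
            nut_id=rec.nut_id,
            pixels=rec.pixels,
            kernel_status=lab,
            centroid=rec.centroid,
            contour=rec.contour,
        )
        for rec, lab in zip(whole, open_labels)
    ]
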