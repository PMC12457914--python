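"""Tip localisation by principal-axis analysis of a nut's pixel coordinates.

A pistachio is nearly elliptical with a pointed tip protruding along its
long axis.  PCA of the (x, y) pixel ensemble gives the approximating
ellipse; rotating the long axis to horizontal exposes two extreme pixels on
either side of the centre, and the one farther from the centre is the tip.
Every pixel is then ranked by its Euclidean distance to the tip, which
downstream feature extraction uses to carve tip-closest / tip-farthest
regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hullscape.imaging import PixelEnsemble

logger = logging.getLogger(__name__)


@dataclass
class AxisFrame:
    """Principal-axis frame of a pixel ensemble (approximating ellipse)."""

    centre: tuple[float, float]
    long_axis_dir: tuple[float, float]  # unit vector
    long_len: float  # semi-axis, pixels
    short_len: float
    rotation_angle: float  # radians; rotating by this maps the long axis to horizontal


@dataclass
class TipResult:
    tip: tuple[int, int]  # (x, y) in the original image frame
    tip_distances: np.ndarray  # per-pixel Euclidean distance to the tip
    rank: np.ndarray  # permutation of 1..n, ascending distance


def principal_axes(pixels: PixelEnsemble) -> AxisFrame:
    """PCA of the coordinate ensemble -> centre, axes and rotation.

    Semi-axis lengths are ``2 * sqrt(eigenvalue)`` (two coordinate standard
    deviations, matching a uniform-filled ellipse closely); only the axis
    direction matters downstream.

    Raises ``ValueError`` for ensembles of fewer than 3 pixels or with
    (near-)collinear coordinates.
    """
    xy = pixels.coords.astype(np.float64)
    if len(xy) < 3:
        raise ValueError("need at least 3 pixels for principal axes")
    centre = xy.mean(axis=0)
    cov = np.cov((xy - centre).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("degenerate (collinear) pixel ensemble")
    long_vec = evecs[:, 1]
    if long_vec[0] < 0 or (long_vec[0] == 0 and long_vec[1] < 0):
        long_vec = -long_vec  # canonical sign: point into +x half-plane
    angle = float(np.arctan2(long_vec[1], long_vec[0]))
    return AxisFrame(
        centre=(float(centre[0]), float(centre[1])),
        long_axis_dir=(float(long_vec[0]), float(long_vec[1])),
        long_len=float(2.0 * np.sqrt(evals[1])),
        short_len=float(2.0 * np.sqrt(evals[0])),
        rotation_angle=-angle,
    )


def locate_tip(pixels: PixelEnsemble, frame: AxisFrame) -> TipResult:
    """Find the tip pixel and rank all pixels by distance to it.

    In the rotated frame the candidates are the minimum-x and maximum-x
    pixels; the tip is the one farther from the centre.  An exact tie is
    broken toward the candidate with larger rotated \\|x\\| and then smaller
    original y.  Distances and ranks are computed in original coordinates;
    distance ties rank in row-major pixel order so that region partitions
    are deterministic.
    """
    xy = pixels.coords.astype(np.float64)
    centre = np.array(frame.centre)
    c, s = np.cos(frame.rotation_angle), np.sin(frame.rotation_angle)
    rot = np.array([[c, -s], [s, c]])
    rxy = (xy - centre) @ rot.T  # rotated, centred

    cand = [int(np.argmin(rxy[:, 0])), int(np.argmax(rxy[:, 0]))]
    dist_c = [float(np.hypot(*rxy[i])) for i in cand]
    if dist_c[0] > dist_c[1]:
        tip_idx = cand[0]
    elif dist_c[1] > dist_c[0]:
        tip_idx = cand[1]
    else:
        # exact tie: larger rotated |x|, then smaller original y
        key = [(abs(rxy[i, 0]), -xy[i, 1]) for i in cand]
        tip_idx = cand[0] if key[0] >= key[1] else cand[1]
        logger.info("tip tie between %s broken to index %d", cand, tip_idx)

    tip = (int(pixels.coords[tip_idx, 0]), int(pixels.coords[tip_idx, 1]))
    d = np.hypot(xy[:, 0] - tip[0], xy[:, 1] - tip[1])
    # stable argsort: distance ties keep row-major (input) pixel order
    order = np.argsort(d, kind="stable")
    rank = np.empty(len(d), dtype=np.int64)
    rank[order] = np.arange(1, len(d) + 1)
    return TipResult(tip=tip, tip_distances=d, rank=rank)
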