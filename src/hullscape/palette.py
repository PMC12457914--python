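"""Reference colour spectrum: hierarchical clustering of hull pixel colours.

A set of reference nuts (the study used 10, chosen to span both filled and
blank nuts across developmental stages) contributes its pooled RGB pixels to
a Ward-D2 hierarchical clustering cut at nine clusters.  The darkest cluster
is the black background/edge cluster and is flagged for exclusion; the
remaining eight are the *major colours* against which every pixel of every
nut is subsequently classified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from hullscape.imaging import NutRecord, PixelEnsemble

BACKGROUND_CODE = 0  # classification code for background-assigned pixels


@dataclass
class ColourCluster:
    id: int  # 0 = background, 1..8 major colours by descending luminance
    centroid: np.ndarray  # (3,) float RGB
    member_sample: np.ndarray  # (m, 3) uint8 sample of member pixels
    is_background: bool = False


@dataclass
class Palette:
    clusters: list[ColourCluster]
    reference_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if sum(c.is_background for c in self.clusters) != 1:
            raise ValueError("palette must flag exactly one background cluster")

    @property
    def n_major(self) -> int:
        return len(self.clusters) - 1

    def centroid_matrix(self, include_background: bool = True) -> np.ndarray:
        """Centroids stacked in cluster-id order (background first if included)."""
        cl = sorted(self.clusters, key=lambda c: c.id)
        if not include_background:
            cl = [c for c in cl if not c.is_background]
        return np.stack([c.centroid for c in cl])

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "reference_ids": self.reference_ids,
            "clusters": [
                {
                    "id": c.id,
                    "centroid": [float(v) for v in c.centroid],
                    "is_background": bool(c.is_background),
                    "member_sample": np.asarray(c.member_sample).tolist(),
                }
                for c in self.clusters
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Palette":
        with open(path) as fh:
            payload = json.load(fh)
        clusters = [
            ColourCluster(
                id=int(c["id"]),
                centroid=np.asarray(c["centroid"], dtype=np.float64),
                member_sample=np.asarray(c["member_sample"], dtype=np.uint8),
                is_background=bool(c["is_background"]),
            )
            for c in payload["clusters"]
        ]
        return cls(clusters, reference_ids=payload.get("reference_ids", []),
                   seed=payload.get("seed"))

    @classmethod
    def from_centroids(cls, centroids: np.ndarray, background_id: int = 0) -> "Palette":
        """Build a palette directly from known centroids (id order: 0..8)."""
        centroids = np.asarray(centroids, dtype=np.float64)
        clusters = [
            ColourCluster(
                id=i,
                centroid=c,
                member_sample=np.asarray([np.clip(c, 0, 255)], dtype=np.uint8),
                is_background=(i == background_id),
            )
            for i, c in enumerate(centroids)
        ]
        return cls(clusters)


def _luminance(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def build_palette(
    reference: list[NutRecord],
    n_clusters: int = 9,
    subsample_per_nut: int = 2000,
    seed: int = 0,
    member_sample_size: int = 200,
) -> Palette:
    """Cluster pooled reference-nut pixel colours into the colour spectrum.

    Pixels are pooled across the reference nuts (subsampled to
    ``subsample_per_nut`` per nut so the O(n^2) linkage stays tractable),
    clustered with Euclidean distance and Ward-D2 linkage, and cut at
    ``n_clusters``.  The minimum-luminance cluster is flagged as background
    (code 0); the rest are re-indexed 1..n-1 by descending centroid
    luminance so colour codes are stable across runs.
    """
    if len(reference) < 2:
        raise ValueError("need at least 2 reference nuts")
    rng = np.random.default_rng(seed)
    pools = []
    for rec in reference:
        cols = rec.pixels.colours
        if len(cols) > subsample_per_nut:
            idx = rng.choice(len(cols), size=subsample_per_nut, replace=False)
            cols = cols[idx]
        pools.append(cols)
    pooled = np.concatenate(pools).astype(np.float64)
    if len(pooled) < n_clusters:
        raise ValueError("fewer pooled pixels than requested clusters")
    if len(np.unique(pooled, axis=0)) < n_clusters:
        raise ValueError("fewer distinct colours than requested clusters")

    Z = linkage(pooled, method="ward")
    assign = fcluster(Z, t=n_clusters, criterion="maxclust")

    raw = []
    for k in range(1, n_clusters + 1):
        members = pooled[assign == k]
        centroid = members.mean(axis=0)
        m = min(member_sample_size, len(members))
        sample_idx = rng.choice(len(members), size=m, replace=False)
        raw.append((centroid, members[sample_idx].astype(np.uint8)))

    lum = np.array([_luminance(c) for c, _ in raw])
    bg = int(np.argmin(lum))
    majors = sorted(
        (i for i in range(n_clusters) if i != bg),
        key=lambda i: -lum[i],
    )
    clusters = [
        ColourCluster(id=0, centroid=raw[bg][0], member_sample=raw[bg][1],
                      is_background=True)
    ]
    for new_id, i in enumerate(majors, start=1):
        clusters.append(
            ColourCluster(id=new_id, centroid=raw[i][0], member_sample=raw[i][1])
        )
    return Palette(clusters, reference_ids=[r.nut_id for r in reference], seed=seed)


def classify_pixels(
    pixels: PixelEnsemble | np.ndarray,
    palette: Palette,
    mode: str = "centroid",
) -> np.ndarray:
    """Assign each pixel the id of its nearest colour cluster.

    ``mode="centroid"`` (default) measures Euclidean RGB distance to the
    cluster centroids; ``mode="member"`` measures distance to the nearest
    stored member pixel of each cluster.  Equidistant ties go to the lower
    cluster id.  Background-assigned pixels receive ``BACKGROUND_CODE`` (0).
    """
    if isinstance(pixels, PixelEnsemble):
        cols = pixels.colours.astype(np.float64)
    else:
        cols = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    clusters = sorted(palette.clusters, key=lambda c: c.id)
    if mode == "centroid":
        cents = np.stack([c.centroid for c in clusters])
        d2 = ((cols[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    elif mode == "member":
        d2 = np.empty((len(cols), len(clusters)))
        for j, c in enumerate(clusters):
            mem = np.asarray(c.member_sample, dtype=np.float64)
            dd = ((cols[:, None, :] - mem[None, :, :]) ** 2).sum(axis=2)
            d2[:, j] = dd.min(axis=1)
    else:
        raise ValueError("mode must be 'centroid' or 'member'")
    ids = np.array([c.id for c in clusters])
    return ids[np.argmin(d2, axis=1)]  # argmin takes first == lowest id on ties
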