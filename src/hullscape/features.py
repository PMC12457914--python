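"""Tip-anchored colour-proportion features and their categorization.

Each nut yields 56 features: for each of 7 regions (the full hull plus the
tip-closest-k and tip-farthest-k bands, k = 30/50/70 % of non-background
pixels) the proportions of pixels in each of the 8 major colours.  Features
with negligible variation across nuts are filtered out; the survivors are
binarized at a cutoff (the per-feature median by default) and, for order-2
analysis, paired into joint categories.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hullscape.imaging import NutRecord, PixelEnsemble
from hullscape.palette import BACKGROUND_CODE, Palette, classify_pixels
from hullscape.tipgeom import TipResult, locate_tip, principal_axes

REGION_NAMES = (
    "full",
    "tip-closest-30",
    "tip-closest-50",
    "tip-closest-70",
    "tip-farthest-30",
    "tip-farthest-50",
    "tip-farthest-70",
)

N_COLOURS = 8

FEATURE_COLUMNS = tuple(
    f"{region}-c{c}" for region in REGION_NAMES for c in range(1, N_COLOURS + 1)
)

META_COLUMNS = ("nut_id", "ct", "kernel_status")


@dataclass
class FeatureTable:
    """Nuts x 56 colour-proportion features plus kernel labels and metadata.

    ``data`` holds one row per nut with the metadata columns ``nut_id``,
    ``ct``, ``kernel_status`` followed by the feature columns (all in
    [0, 1]).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        vals = self.data[self.feature_names].to_numpy(dtype=float)
        if vals.size and ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise ValueError("feature values must lie in [0, 1]")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def response(self) -> pd.Series:
        return self.data["kernel_status"]

    @property
    def n_nuts(self) -> int:
        return len(self.data)

    def values(self, feature: str) -> np.ndarray:
        return self.data[feature].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class CategorizedFeature:
    """A binarized feature (order 1) or joint pair of them (order 2)."""

    features: tuple[str, ...]
    cutoffs: tuple[float, ...]
    codes: np.ndarray  # per-nut category code: "0"/"1" or "00".."11"
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=object)
        if not self.categories:
            self.categories = sorted(set(self.codes))

    @property
    def order(self) -> int:
        return len(self.features)

    @property
    def name(self) -> str:
        return "&".join(self.features)


def region_partition(tips: TipResult, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Index masks for the tip-closest-k% and tip-farthest-k% pixel sets.

    With n ranked pixels, the closest set is ranks 1..ceil(k/100 * n) and the
    farthest set is the top ceil(k/100 * n) ranks.  By construction
    closest-k and farthest-(100-k) partition the pixel set exactly.
    """
    n = len(tips.rank)
    if n == 0:
        raise ValueError("empty pixel ensemble")
    m = math.ceil(k / 100 * n)
    closest = tips.rank <= m
    farthest = tips.rank > n - m
    return closest, farthest


def colour_proportions(
    codes: np.ndarray, n_colours: int = N_COLOURS
) -> tuple[np.ndarray, bool]:
    """Per-major-colour pixel fractions from classification codes.

    ``codes`` are palette assignments (0 = background, already expected to
    be excluded).  Returns the 8-vector of fractions (summing to 1) and a
    degenerate flag; a subset that is entirely background yields the zero
    vector with the flag set.
    """
    codes = np.asarray(codes)
    codes = codes[codes != BACKGROUND_CODE]
    if len(codes) == 0:
        return np.zeros(n_colours), True
    counts = np.bincount(codes, minlength=n_colours + 1)[1 : n_colours + 1]
    return counts / counts.sum(), False


def feature_vector(
    nut: NutRecord,
    palette: Palette,
    tips: TipResult | None = None,
    mode: str = "centroid",
) -> np.ndarray:
    """The 56-feature vector of one nut, in fixed column order.

    Background-classified pixels are removed before the tip-distance regions
    are carved, so every region is a fraction of the nut's hull pixels.
    Column order is ``FEATURE_COLUMNS``: regions in ``REGION_NAMES`` order,
    colours 1..8 within each region.
    """
    codes = classify_pixels(nut.pixels, palette, mode=mode)
    hull = codes != BACKGROUND_CODE
    if not hull.any():
        raise ValueError(f"nut {nut.nut_id}: all pixels classified as background")
    hull_pixels = PixelEnsemble(nut.pixels.coords[hull], nut.pixels.colours[hull])
    hull_codes = codes[hull]
    if tips is None:
        frame = principal_axes(hull_pixels)
        tips = locate_tip(hull_pixels, frame)

    out = np.empty(len(FEATURE_COLUMNS))
    pos = 0
    for region in REGION_NAMES:
        if region == "full":
            sel = np.ones(len(hull_codes), dtype=bool)
        else:
            k = int(region.rsplit("-", 1)[1])
            closest, farthest = region_partition(tips, k)
            sel = closest if "closest" in region else farthest
        vec, _ = colour_proportions(hull_codes[sel])
        out[pos : pos + N_COLOURS] = vec
        pos += N_COLOURS
    return out


def build_feature_table(
    nuts: list[NutRecord],
    palette: Palette,
    ct_label: str = "unknown",
    mode: str = "centroid",
) -> FeatureTable:
    """Feature-extract a list of nuts into one table."""
    rows = []
    for nut in nuts:
        vec = feature_vector(nut, palette, mode=mode)
        rows.append([nut.nut_id, ct_label, nut.kernel_status, *vec])
    df = pd.DataFrame(rows, columns=[*META_COLUMNS, *FEATURE_COLUMNS])
    return FeatureTable(df)


def variability_filter(
    table: FeatureTable, min_sd: float = 0.01
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features whose sample standard deviation falls below ``min_sd``.

    Features that are constant (or nearly so) typically flag the absence of
    a major colour at that time point and carry no associative information.
    Returns the filtered table and a retention report laid out region x
    colour with the retained time-point label (or "" when dropped).
    """
    if table.n_nuts < 2:
        raise ValueError("need at least 2 nuts to compute a sample SD")
    keep = []
    for f in table.feature_names:
        sd = float(np.std(table.values(f), ddof=1))
        if sd >= min_sd:
            keep.append(f)
    cols = list(META_COLUMNS) + keep
    filtered = FeatureTable(table.data[cols].copy())

    ct = table.data["ct"].iloc[0] if table.n_nuts else ""
    report = pd.DataFrame(
        "",
        index=list(REGION_NAMES),
        columns=[str(c) for c in range(1, N_COLOURS + 1)],
    )
    for f in keep:
        region, _, colour = f.rpartition("-c")
        if region in report.index and colour in report.columns:
            report.loc[region, colour] = str(ct)
    return filtered, report


def categorize(
    table: FeatureTable, feature: str, cutoff: float | str = "median"
) -> CategorizedFeature:
    """Binarize a feature at a cutoff (the median by default).

    Code 0 means value <= cutoff, code 1 means value > cutoff; values that
    sit exactly on the cutoff go to category 0.
    """
    vals = table.values(feature)
    if np.all(vals == vals[0]):
        raise ValueError(f"feature {feature}: all values identical, cannot split")
    cut = float(np.median(vals)) if cutoff == "median" else float(cutoff)
    codes = np.where(vals <= cut, "0", "1")
    return CategorizedFeature(
        features=(feature,), cutoffs=(cut,), codes=codes, categories=["0", "1"]
    )


def categorize_pair(
    table: FeatureTable,
    features: tuple[str, str],
    cutoffs: tuple[float | str, float | str] = ("median", "median"),
) -> CategorizedFeature:
    """Joint (order-2) categorization: the four cells 00/01/10/11."""
    a = categorize(table, features[0], cutoffs[0])
    b = categorize(table, features[1], cutoffs[1])
    codes = np.array([x + y for x, y in zip(a.codes, b.codes)], dtype=object)
    return CategorizedFeature(
        features=(features[0], features[1]),
        cutoffs=(a.cutoffs[0], b.cutoffs[0]),
        codes=codes,
        categories=sorted(set(codes)),
    )


def pair_features(retained: list[str]) -> list[tuple[str, str]]:
    """All unordered pairs of retained features (n choose 2)."""
    if len(retained) < 2:
        raise ValueError("need at least 2 features to pair")
    return list(itertools.combinations(retained, 2))
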