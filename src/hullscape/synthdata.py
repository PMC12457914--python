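"""Synthetic plates, feature tables and landscapes with known ground truth.

Real plate photographs are not needed to exercise the pipeline: this module
renders elliptical nuts with protruding tips on a white background (with a
truth manifest recording centres, tip apices, kernel status and per-region
colour mixtures), plants controllable feature-response associations into
feature tables, and builds block-structured binary landscapes.  Colour
fields are radial mixtures keyed to tip distance, so the tip-closest /
tip-farthest feature contrast is controllable — notably the extra tip
redness of blank nuts that motivates the whole analysis.  The printed
reference contingency tables and the nearest-neighbour distance table ship
as CSV fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from hullscape.ceda import ContingencyTable
from hullscape.features import FEATURE_COLUMNS, META_COLUMNS, FeatureTable
from hullscape.imaging import PlateImage
from hullscape.landscape import Landscape, _safe_linkage
from hullscape.palette import Palette

FIXTURE_FILES = {
    "T2": "table_ct1_tip_closest_50_c8.csv",
    "T3": "table_ct1_tip_closest_70_c8.csv",
    "T4": "table_ct2_tip_closest_30_c1.csv",
    "T5": "table_ct3_full_c1.csv",
}

FIXTURE_NAMES = {
    "T2": "tip-closest-50-c8",
    "T3": "tip-closest-70-c8",
    "T4": "tip-closest-30-c1",
    "T5": "full-c1",
}


def fixtures() -> dict:
    """The packaged reference tables.

    Keys "T2".."T5" are the four published feature-vs-kernel contingency
    tables (CT1 tip-closest-50 colour 8, CT1 tip-closest-70 colour 8, CT2
    tip-closest-30 colour 1, CT3 full-hull colour 1).  Key "T6" is the
    worked GSD example: a dict with the 10 candidate ids, the 10x10 matrix
    of each candidate's own ranked nearest-neighbour distances
    (column-wise) and the query nut's distances to the candidates.
    """
    out = {}
    data_dir = resources.files("hullscape") / "data"
    for key, fname in FIXTURE_FILES.items():
        df = pd.read_csv(str(data_dir / fname))
        out[key] = ContingencyTable(
            df[["blank", "filled"]].to_numpy(),
            row_labels=[str(c) for c in df["category"]],
            name=FIXTURE_NAMES[key],
        )
    df6 = pd.read_csv(str(data_dir / "gsd_ncn_distances.csv"))
    candidates = [c for c in df6.columns if c != "rank"]
    nn = df6[df6["rank"] != "query"][candidates].to_numpy(dtype=float)
    query = df6[df6["rank"] == "query"][candidates].to_numpy(dtype=float)[0]
    out["T6"] = {
        "candidates": candidates,
        "neighbour_distances": nn,
        "query_distances": query,
        "query_id": "CT2-A1-full-22",
    }
    return out


# ---------------------------------------------------------------------------
# plate rendering


@dataclass
class NutSpec:
    """Geometry and colouring of one synthetic nut."""

    centre: tuple[float, float]  # (x, y)
    angle: float  # long-axis orientation, radians
    semi_axes: tuple[float, float]  # (a, b), a >= b
    tip_length: float = 12.0  # protrusion beyond the ellipse
    tip_width: float = 10.0
    kernel_status: str = "filled"
    # mixture weights over major colours 1..8 (must each sum to 1)
    tip_mixture: np.ndarray | None = None
    body_mixture: np.ndarray | None = None

    def apex(self) -> tuple[float, float]:
        a = self.semi_axes[0] + self.tip_length
        return (
            self.centre[0] + a * math.cos(self.angle),
            self.centre[1] + a * math.sin(self.angle),
        )


def default_palette() -> Palette:
    """A well-separated 9-cluster palette (id 0 = black background)."""
    centroids = np.array(
        [
            [10, 10, 10],      # 0 background black
            [235, 225, 180],   # 1 pale yellow
            [210, 200, 120],   # 2 straw
            [190, 150, 90],    # 3 tan
            [170, 190, 90],    # 4 yellow-green
            [200, 80, 80],     # 5 red
            [120, 150, 70],    # 6 green
            [150, 90, 120],    # 7 purple-pink
            [90, 110, 60],     # 8 dark green
        ],
        dtype=float,
    )
    return Palette.from_centroids(centroids, background_id=0)


def random_nut_specs(
    n_nuts: int,
    canvas: tuple[int, int],
    rng: np.random.Generator,
    blank_fraction: float = 0.1,
    blank_effect: float = 0.5,
    n_colours: int = 8,
    red_colour: int = 5,
    max_tries: int = 200,
) -> list[NutSpec]:
    """Place non-overlapping nuts with status-dependent tip colouring.

    Blank nuts receive ``blank_effect`` extra mixture weight on
    ``red_colour`` in the tip region, emulating the red tip colouration
    seen in kernel-less nuts.
    """
    h, w = canvas
    specs: list[NutSpec] = []
    for i in range(n_nuts):
        status = "blank" if rng.random() < blank_fraction else "filled"
        for _ in range(max_tries):
            a = rng.uniform(38, 50)
            b = rng.uniform(24, 32)
            margin = a + 20
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            clearance = a + 22
            if all(
                math.hypot(cx - s.centre[0], cy - s.centre[1])
                > clearance + s.semi_axes[0]
                for s in specs
            ):
                break
        else:
            raise RuntimeError(
                f"could not place nut {i + 1} of {n_nuts} without overlap; "
                "enlarge the canvas or reduce n_nuts"
            )
        body = rng.dirichlet(np.full(n_colours, 2.0))
        tip = rng.dirichlet(np.full(n_colours, 2.0))
        if status == "blank":
            tip = (1 - blank_effect) * tip
            tip[red_colour - 1] += blank_effect
        specs.append(
            NutSpec(
                centre=(cx, cy),
                angle=rng.uniform(0, math.pi),
                semi_axes=(a, b),
                tip_length=rng.uniform(10, 16),
                tip_width=rng.uniform(8, 12),
                kernel_status=status,
                tip_mixture=tip,
                body_mixture=body,
            )
        )
    return specs


def _nut_mask(spec: NutSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the pixels of one nut (ellipse plus tip wedge)."""
    h, w = shape
    a, b = spec.semi_axes
    reach = a + spec.tip_length + 2
    x0 = max(int(spec.centre[0] - reach), 0)
    x1 = min(int(spec.centre[0] + reach) + 1, w)
    y0 = max(int(spec.centre[1] - reach), 0)
    y1 = min(int(spec.centre[1] + reach) + 1, h)
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    dx = xs - spec.centre[0]
    dy = ys - spec.centre[1]
    c, s = math.cos(spec.angle), math.sin(spec.angle)
    u = dx * c + dy * s  # along the long axis
    v = -dx * s + dy * c
    in_ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # tip wedge: tapers from tip_width toward the apex but stays blunt
    # (>= ~3 px wide) so it rasterizes as a connected protrusion
    lam = (u - a * 0.6) / (a * 0.4 + spec.tip_length)
    half_w = np.maximum(spec.tip_width / 2 * (1 - lam), 1.6)
    in_tip = (lam >= 0) & (lam <= 1) & (np.abs(v) <= half_w)
    mask = in_ellipse | in_tip
    return ys[mask], xs[mask]


def make_plate(
    n_nuts: int,
    palette: Palette | None = None,
    specs: list[NutSpec] | None = None,
    seed: int = 0,
    canvas: tuple[int, int] = (1500, 2000),
    background: tuple[int, int, int] = (252, 252, 250),
    colour_noise: float = 6.0,
    blank_fraction: float = 0.1,
    blank_effect: float = 0.5,
) -> tuple[PlateImage, pd.DataFrame]:
    """Render a synthetic plate and its ground-truth manifest.

    Each nut's pixels take colours sampled from its tip/body mixtures over
    the palette's major-colour centroids (tip mixture within 30% of the
    nut's length from the apex), with Gaussian RGB noise.  The manifest
    records, per nut in top-to-bottom reading order: centre, tip apex,
    kernel status and the mixtures, which is sufficient to score
    segmentation, tip detection and feature extraction without
    re-inspecting the image.
    """
    rng = np.random.default_rng(seed)
    palette = palette or default_palette()
    if specs is None:
        specs = random_nut_specs(
            n_nuts, canvas, rng, blank_fraction=blank_fraction,
            blank_effect=blank_effect,
        )
    if len(specs) != n_nuts:
        raise ValueError("specs length must equal n_nuts")

    img = np.empty((*canvas, 3), dtype=np.uint8)
    img[:] = background
    centroids = palette.centroid_matrix(include_background=False)

    # top-to-bottom reading order so manifest ordinals match segmentation labels
    order = sorted(range(n_nuts), key=lambda i: (specs[i].centre[1], specs[i].centre[0]))
    rows = []
    for ordinal, i in enumerate(order, start=1):
        spec = specs[i]
        yy, xx = _nut_mask(spec, canvas)
        apex = spec.apex()
        d_apex = np.hypot(xx - apex[0], yy - apex[1])
        tip_zone = d_apex <= np.quantile(d_apex, 0.3)
        codes = np.empty(len(xx), dtype=np.int64)
        for zone, mix in ((tip_zone, spec.tip_mixture),
                          (~tip_zone, spec.body_mixture)):
            k = int(zone.sum())
            if k:
                codes[zone] = rng.choice(len(centroids), size=k, p=mix)
        cols = centroids[codes] + rng.normal(0, colour_noise, size=(len(xx), 3))
        img[yy, xx] = np.clip(cols, 0, 255).astype(np.uint8)
        rows.append(
            [
                ordinal,
                spec.centre[0],
                spec.centre[1],
                apex[0],
                apex[1],
                spec.angle,
                spec.semi_axes[0],
                spec.semi_axes[1],
                spec.kernel_status,
            ]
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "ordinal", "centre_x", "centre_y", "tip_x", "tip_y",
            "angle", "semi_a", "semi_b", "kernel_status",
        ],
    )
    plate = PlateImage(img, plate_id=f"synth-{seed}", metadata={"seed": seed})
    return plate, manifest


# ---------------------------------------------------------------------------
# planted feature tables


@dataclass
class PlantedEffect:
    """A feature whose high/low bin depends on kernel status.

    ``p_high_blank`` / ``p_high_filled`` are the probabilities that a blank
    (resp. filled) nut falls in the upper half of the feature's range; a
    strong association is e.g. 10:1 vs 1:10 bin-conditional odds, i.e.
    p_high_blank = 10/11, p_high_filled = 1/11.
    """

    feature: str
    p_high_blank: float
    p_high_filled: float


@dataclass
class PlantedFeatureSpec:
    """Design of a synthetic feature table.

    Defaults mirror the study layout: 90 nuts per time point, ~10 blanks
    (the CT1/CT2 design; CT3 had 21), 56 feature columns.  Non-planted
    features are independent uniform noise on [0, 1].
    """

    n_nuts: int = 90
    n_blank: int = 10
    effects: list[PlantedEffect] = field(default_factory=list)
    features: tuple[str, ...] = FEATURE_COLUMNS
    noise_sd: float = 0.05
    ct_label: str = "synthetic"
    seed: int = 0


def make_feature_table(spec: PlantedFeatureSpec) -> FeatureTable:
    """Generate a feature table with planted response associations.

    Planted features draw the high/low bin from the status-conditional
    probabilities and then a value uniform within the bin half ([0, 0.5] or
    (0.5, 1]), jittered by ``noise_sd`` and clipped to [0, 1]; all other
    features are independent uniform noise, carrying no association.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nuts
    if not 0 <= spec.n_blank <= n:
        raise ValueError("n_blank must be within [0, n_nuts]")
    status = np.array(["blank"] * spec.n_blank + ["filled"] * (n - spec.n_blank),
                      dtype=object)
    rng.shuffle(status)
    data = {f: rng.uniform(0, 1, size=n) for f in spec.features}
    for eff in spec.effects:
        if eff.feature not in data:
            raise ValueError(f"unknown planted feature {eff.feature}")
        p_high = np.where(status == "blank", eff.p_high_blank, eff.p_high_filled)
        high = rng.random(n) < p_high
        vals = np.where(
            high, rng.uniform(0.55, 1.0, size=n), rng.uniform(0.0, 0.45, size=n)
        )
        vals = np.clip(vals + rng.normal(0, spec.noise_sd, size=n), 0, 1)
        data[eff.feature] = vals
    df = pd.DataFrame(
        {
            "nut_id": [f"{spec.ct_label}-{i + 1}" for i in range(n)],
            "ct": spec.ct_label,
            "kernel_status": status,
            **data,
        },
        columns=[*META_COLUMNS, *spec.features],
    )
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# planted landscapes


def make_block_landscape(
    n_categories: int = 12,
    block_sizes: tuple[int, int] = (10, 80),
    blank_rates: tuple[float, float] = (1.0, 0.0),
    flip_prob: float = 0.0,
    ct_label: str = "synthetic",
    seed: int = 0,
) -> Landscape:
    """Two-block binary landscape with block-specific blank rates.

    Nuts in block 1 carry the first half of the categories, nuts in block 2
    the second half; ``flip_prob`` adds independent bit noise.  Used to
    validate dendrogram cuts, K-NN profiles and prevalence estimation
    against known structure.
    """
    rng = np.random.default_rng(seed)
    half = n_categories // 2
    n1, n2 = block_sizes
    cols, labels, ids = [], [], []
    for b, (nb, rate) in enumerate(zip(block_sizes, blank_rates), start=1):
        proto = np.zeros(n_categories, dtype=np.int64)
        if b == 1:
            proto[:half] = 1
        else:
            proto[half:] = 1
        for i in range(nb):
            v = proto.copy()
            flips = rng.random(n_categories) < flip_prob
            v[flips] = 1 - v[flips]
            cols.append(v)
            labels.append("blank" if rng.random() < rate else "filled")
            ids.append(f"b{b}-{i + 1}")
    matrix = np.array(cols).T
    ls = Landscape(
        matrix=matrix,
        category_names=[f"cat{i + 1}" for i in range(n_categories)],
        nut_ids=ids,
        labels=labels,
        ct_label=ct_label,
    )
    ls.row_linkage = _safe_linkage(matrix)
    ls.col_linkage = _safe_linkage(matrix.T)
    return ls
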