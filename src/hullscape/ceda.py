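"""Categorical exploratory data analysis (CEDA) of feature-category vs kernel status.

Each categorized feature is cross-tabulated against the binary kernel
response (blank / filled).  Whether a row (a feature category) carries a
real associative pattern is judged by simulation: an *alternative* ensemble
of tables resamples each column from its observed within-column row
proportions, a *null* ensemble resamples each column from the marginal row
proportions (independence).  The overlap of the row statistic's two
distributions estimates the minimum sum of Type-I and Type-II errors; a
category is *major* when that overlap does not exceed a chosen threshold.

Entropies are natural-log Shannon entropies of a row's conditional
blank/filled distribution; odds are blank/filled count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hullscape.features import (
    CategorizedFeature,
    FeatureTable,
    categorize,
    categorize_pair,
    pair_features,
)

RESPONSE_LEVELS = ("blank", "filled")


def row_entropy(counts) -> float:
    """Shannon entropy (nats) of a row's conditional distribution.

    0 * ln 0 is taken as 0; a zero row sum is an error.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum()
    if n <= 0:
        raise ValueError("zero row sum has no conditional distribution")
    p = counts / n
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def row_odds(counts) -> float:
    """Blank/filled odds of a row; +inf when the filled count is zero."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.sum() <= 0:
        raise ValueError("zero row sum has no odds")
    blank, filled = counts
    if filled == 0:
        return float("inf")
    return float(blank / filled)


@dataclass
class ContingencyTable:
    """Feature-category x (blank, filled) counts with row statistics."""

    counts: np.ndarray  # (R, 2) non-negative ints, columns (blank, filled)
    row_labels: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be R x 2 (blank, filled)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.row_labels:
            self.row_labels = [str(i) for i in range(self.counts.shape[0])]
        if len(self.row_labels) != self.counts.shape[0]:
            raise ValueError("row_labels length mismatch")

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_entropies(self) -> np.ndarray:
        return np.array([row_entropy(r) for r in self.counts])

    @property
    def row_odds(self) -> np.ndarray:
        return np.array([row_odds(r) for r in self.counts])

    @property
    def baseline_entropy(self) -> float:
        """Entropy of the marginal response distribution (column sums)."""
        return row_entropy(self.col_sums)

    @property
    def baseline_odds(self) -> float:
        return row_odds(self.col_sums)


def make_table(cat: CategorizedFeature, labels) -> ContingencyTable:
    """Cross-tabulate a categorized feature against blank/filled labels."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(cat.codes):
        raise ValueError("membership and labels must be aligned")
    bad = sorted(set(labels) - set(RESPONSE_LEVELS))
    if bad:
        raise ValueError(f"labels must be in {RESPONSE_LEVELS}; got {bad}")
    rows = []
    for c in cat.categories:
        in_cat = cat.codes == c
        rows.append(
            [int(((labels == "blank") & in_cat).sum()),
             int(((labels == "filled") & in_cat).sum())]
        )
    return ContingencyTable(np.array(rows), row_labels=list(cat.categories),
                            name=cat.name)


@dataclass
class EnsemblePair:
    """M simulated tables under the alternative and under the null."""

    alternative: np.ndarray  # (M, R, 2)
    null: np.ndarray  # (M, R, 2)
    seed: int

    @property
    def M(self) -> int:
        return self.alternative.shape[0]


def simulate_ensembles(table: ContingencyTable, M: int = 1000, seed: int = 0) -> EnsemblePair:
    """Column-multinomial resampling of a contingency table.

    Alternative: column j ~ multinomial(col_sum_j, observed within-column
    row proportions) — retains the observed association.  Null: column j ~
    multinomial(col_sum_j, marginal row proportions) — enforces
    independence.  Every simulated table preserves the observed column sums
    exactly.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if table.n_rows < 2:
        raise ValueError("need at least 2 rows to simulate")
    col = table.col_sums
    if (col <= 0).any():
        raise ValueError("both column sums must be positive")
    rng = np.random.default_rng(seed)
    marg = table.row_sums / table.total
    alt = np.zeros((M, table.n_rows, 2), dtype=np.int64)
    nul = np.zeros((M, table.n_rows, 2), dtype=np.int64)
    for j in range(2):
        p_alt = table.counts[:, j] / col[j]
        alt[:, :, j] = rng.multinomial(int(col[j]), p_alt, size=M)
        nul[:, :, j] = rng.multinomial(int(col[j]), marg, size=M)
    return EnsemblePair(alternative=alt, null=nul, seed=seed)


def _row_statistic(tables: np.ndarray, row: int, statistic: str) -> np.ndarray:
    """Vector of a row's statistic across simulated tables.

    Degenerate rows (zero row sum, possible under the null at tiny margins)
    contribute 0.0 so the ensemble vector stays finite in length.
    """
    counts = tables[:, row, :].astype(np.float64)
    n = counts.sum(axis=1)
    if statistic == "entropy":
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / np.where(n > 0, n, 1)[:, None]
            terms = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1)), 0.0)
        out = terms.sum(axis=1)
        out[n == 0] = 0.0
        return out
    if statistic == "odds":
        blank, filled = counts[:, 0], counts[:, 1]
        out = np.full(len(counts), np.inf)
        ok = filled > 0
        out[ok] = blank[ok] / filled[ok]
        out[n == 0] = 0.0
        return out
    raise ValueError("statistic must be 'entropy' or 'odds'")


def overlap_area(sample_a, sample_b, bins: int = 50) -> float:
    """Histogram overlap of two samples: the minimum-error mass they share.

    Both samples are histogrammed on a shared equal-width grid spanning
    their joint finite range; the overlap is the sum over bins of the
    minimum of the two normalized frequencies.  Infinite values (overflowed
    odds) are routed to a dedicated extra bin shared by both samples.
    Identical samples give 1.0, disjoint supports give 0.0.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    a_inf, b_inf = np.isinf(a), np.isinf(b)
    a_fin, b_fin = a[~a_inf], b[~b_inf]
    overlap = min(a_inf.mean(), b_inf.mean())  # shared overflow-bin mass
    if len(a_fin) == 0 or len(b_fin) == 0:
        return float(overlap)
    lo = min(a_fin.min(), b_fin.min())
    hi = max(a_fin.max(), b_fin.max())
    if lo == hi:  # joint point mass occupies a single bin
        return float(overlap + min((~a_inf).mean(), (~b_inf).mean()))
    edges = np.linspace(lo, hi, bins + 1)
    ha, _ = np.histogram(a_fin, bins=edges)
    hb, _ = np.histogram(b_fin, bins=edges)
    overlap += np.minimum(ha / len(a), hb / len(b)).sum()
    return float(overlap)


@dataclass
class CategoryVerdict:
    """Ensemble-overlap assessment of one feature category."""

    name: str  # feature (or pair) name
    category: str  # row label, e.g. "0", "1", "01"
    statistic: str
    overlap: float
    tau: float
    is_major: bool
    M: int
    seed: int
    counts: tuple[int, int] = (0, 0)


def assess_category(
    table: ContingencyTable,
    row: int,
    statistic: str = "odds",
    M: int = 1000,
    seed: int = 0,
    tau: float = 0.1,
    bins: int = 50,
) -> CategoryVerdict:
    """Overlap of one row's statistic between the two ensembles.

    The row's statistic is computed for every simulated table of each
    ensemble; the two distributions' histogram overlap estimates the
    minimum sum of Type-I and Type-II errors for declaring that category
    associated with kernel status.  ``is_major`` iff overlap <= tau.
    """
    pair = simulate_ensembles(table, M=M, seed=seed)
    s_alt = _row_statistic(pair.alternative, row, statistic)
    s_nul = _row_statistic(pair.null, row, statistic)
    ov = overlap_area(s_alt, s_nul, bins=bins)
    return CategoryVerdict(
        name=table.name,
        category=table.row_labels[row],
        statistic=statistic,
        overlap=ov,
        tau=tau,
        is_major=bool(ov <= tau),
        M=M,
        seed=seed,
        counts=(int(table.counts[row, 0]), int(table.counts[row, 1])),
    )


def select_major(
    table: FeatureTable,
    order: int = 1,
    statistic: str = "odds",
    M: int = 1000,
    seed: int = 0,
    tau: float = 0.1,
    bins: int = 50,
    cutoff: float | str = "median",
) -> tuple[list[CategoryVerdict], list[tuple[CategorizedFeature, CategoryVerdict]]]:
    """Assess every retained feature category (order 1) or joint cell (order 2).

    Returns all verdicts and, separately, the major subset paired with the
    categorized feature each verdict came from (what the landscape module
    consumes).  Seeds per feature are drawn from a seeded sequence so the
    whole selection is reproducible.
    """
    labels = table.response.to_numpy(dtype=object)
    rng = np.random.default_rng(seed)
    verdicts: list[CategoryVerdict] = []
    majors: list[tuple[CategorizedFeature, CategoryVerdict]] = []

    if order == 1:
        units: list[CategorizedFeature] = []
        for f in table.feature_names:
            try:
                units.append(categorize(table, f, cutoff))
            except ValueError:
                continue  # constant feature cannot be split
    elif order == 2:
        units = []
        for pairf in pair_features(table.feature_names):
            try:
                units.append(categorize_pair(table, pairf, (cutoff, cutoff)))
            except ValueError:
                continue
    else:
        raise ValueError("order must be 1 or 2")

    for cat in units:
        ct = make_table(cat, labels)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pair = simulate_ensembles(ct, M=M, seed=sub_seed)
        for row in range(ct.n_rows):
            if ct.row_sums[row] == 0:
                continue  # empty joint cell
            s_alt = _row_statistic(pair.alternative, row, statistic)
            s_nul = _row_statistic(pair.null, row, statistic)
            ov = overlap_area(s_alt, s_nul, bins=bins)
            v = CategoryVerdict(
                name=ct.name,
                category=ct.row_labels[row],
                statistic=statistic,
                overlap=ov,
                tau=tau,
                is_major=bool(ov <= tau),
                M=M,
                seed=sub_seed,
                counts=(int(ct.counts[row, 0]), int(ct.counts[row, 1])),
            )
            verdicts.append(v)
            if v.is_major:
                majors.append((cat, v))
    return verdicts, majors
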