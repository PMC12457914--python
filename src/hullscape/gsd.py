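"""Growth-stage determination (GSD) and blank-prevalence estimation.

A nut of unknown developmental stage is expressed as a binary colour
landscape against each critical time point's confirmed major categories.
Within each reference landscape, the query's K nearest candidate
neighbours (NcN) are found, and each candidate *votes* for the query if it
would accept the query into its own K-neighbourhood — i.e. if the query's
distance to it does not exceed its K-th nearest-neighbour radius.  The
OddsG score for that time point is the best, over admitting candidates, of
the fraction of the candidate's neighbourhood shared with the candidate
set; no admitting candidate means OddsG = 0 (the query is an outlier in
that landscape).  The triplet (OddsG1, OddsG2, OddsG3) is matched against
six stage patterns; a batch is staged by majority vote, and blank
prevalence is estimated by annotating each query with the branch-specific
blank rate of its nearest admitting neighbour.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hullscape.landscape import Landscape, branch_blank_rates

STAGES = (
    "before-CT1",
    "at-CT1",
    "between-CT1-CT2",
    "at-CT2",
    "between-CT2-CT3",
    "at-CT3",
)

# (pattern over {0, 1, "delta"}, stage); delta entries pair up as (d, 1-d)
_STAGE_PATTERNS = (
    ((0, 0, 0), "before-CT1"),
    ((1, 0, 0), "at-CT1"),
    (("d", "1-d", 0), "between-CT1-CT2"),
    ((0, 1, 0), "at-CT2"),
    ((0, "d", "1-d"), "between-CT2-CT3"),
    ((0, 0, 1), "at-CT3"),
)


@dataclass
class QueryNut:
    """An unknown nut's binary landscape vectors, one per reference landscape."""

    nut_id: str
    vectors: dict[str, np.ndarray]  # ct label -> binary vector

    def vector_for(self, landscape: Landscape) -> np.ndarray:
        v = np.asarray(self.vectors[landscape.ct_label], dtype=float)
        if len(v) != landscape.matrix.shape[0]:
            raise ValueError(
                f"query {self.nut_id}: vector length {len(v)} does not match "
                f"landscape {landscape.ct_label} with "
                f"{landscape.matrix.shape[0]} categories"
            )
        return v


@dataclass
class StageTriplet:
    nut_id: str
    odds: tuple[float, float, float]
    stage: str
    ambiguous: bool = False


@dataclass
class NeighbourhoodSystem:
    """Reference K-neighbourhoods: members and K-th NN radius per nut."""

    K: int
    neighbours: dict[str, list[str]]  # nut id -> its K nearest reference nuts
    radius: dict[str, float]  # nut id -> K-th NN distance

    @classmethod
    def build(cls, landscape: Landscape, K: int = 10) -> "NeighbourhoodSystem":
        n = landscape.n_nuts
        if K >= n:
            raise ValueError(f"K={K} must be < number of reference nuts ({n})")
        X = landscape.matrix.T.astype(float)
        neighbours, radius = {}, {}
        for i in range(n):
            d = np.linalg.norm(X - X[i], axis=1)
            order = sorted((d[j], j) for j in range(n) if j != i)[:K]
            neighbours[landscape.nut_ids[i]] = [landscape.nut_ids[j] for _, j in order]
            radius[landscape.nut_ids[i]] = float(order[-1][0])
        return cls(K=K, neighbours=neighbours, radius=radius)


def candidate_neighbours(
    x: QueryNut, L: Landscape, K: int = 10
) -> tuple[list[str], np.ndarray]:
    """The query's K nearest reference nuts (NcN), ascending distance.

    Ties are broken by reference-nut position on the landscape's column
    axis.
    """
    v = x.vector_for(L)
    X = L.matrix.T.astype(float)
    d = np.linalg.norm(X - v, axis=1)
    order = sorted((d[j], j) for j in range(L.n_nuts))[:K]
    return [L.nut_ids[j] for _, j in order], np.array([dj for dj, _ in order])


def odds_g(
    x: QueryNut,
    L: Landscape,
    K: int = 10,
    system: NeighbourhoodSystem | None = None,
) -> float:
    """Neighbourhood-support score of a query within one reference landscape.

    A candidate z admits x iff d(x, z) <= r_K(z), z's K-th nearest-neighbour
    radius (z would count x among its own K nearest).  OddsG is 0 when no
    candidate admits x; otherwise it is the maximum over admitting
    candidates of \\|N[z] ∩ CandiG\\| / K.
    """
    system = system or NeighbourhoodSystem.build(L, K)
    candi, dists = candidate_neighbours(x, L, K)
    candi_set = set(candi)
    best = 0.0
    for z, d in zip(candi, dists):
        if d <= system.radius[z]:
            support = len(candi_set.intersection(system.neighbours[z])) / K
            best = max(best, support)
    return best


def classify_stage(triplet, tol: float = 0.2) -> tuple[str, bool]:
    """Match an (OddsG1, OddsG2, OddsG3) triplet to one of six stage patterns.

    Entries <= tol count as 0 and >= 1 - tol count as 1; a pair of
    intermediate entries matches the (delta, 1 - delta) between-stage
    patterns.  The best-scoring pattern wins; ``ambiguous`` flags a tied
    best score.
    """
    g = np.clip(np.asarray(triplet, dtype=float), 0.0, 1.0)

    def entry_score(value, slot):
        if slot == 0:
            return 1.0 if value <= tol else 0.0
        if slot == 1:
            return 1.0 if value >= 1 - tol else 0.0
        # delta slot: any clearly nonzero value qualifies
        return 1.0 if value > tol else 0.0

    scores = []
    for pattern, stage in _STAGE_PATTERNS:
        s = sum(entry_score(v, slot) for v, slot in zip(g, pattern))
        scores.append((s, stage))
    best = max(s for s, _ in scores)
    winners = [stage for s, stage in scores if s == best]
    return winners[0], len(winners) > 1


def stage_triplet(
    x: QueryNut,
    landscapes: list[Landscape],
    K: int = 10,
    tol: float = 0.2,
    systems: list[NeighbourhoodSystem] | None = None,
) -> StageTriplet:
    if len(landscapes) != 3:
        raise ValueError("need the three critical-time-point landscapes")
    systems = systems or [NeighbourhoodSystem.build(L, K) for L in landscapes]
    odds = tuple(
        odds_g(x, L, K=K, system=sys) for L, sys in zip(landscapes, systems)
    )
    stage, ambiguous = classify_stage(odds, tol=tol)
    return StageTriplet(nut_id=x.nut_id, odds=odds, stage=stage, ambiguous=ambiguous)


@dataclass
class BatchStageReport:
    batch_stage: str
    triplets: list[StageTriplet]
    vote_distribution: dict[str, int] = field(default_factory=dict)


def batch_stage(
    batch: list[QueryNut],
    landscapes: list[Landscape],
    K: int = 10,
    tol: float = 0.2,
) -> BatchStageReport:
    """Stage a batch: per-nut triplets plus the majority-vote batch stage."""
    if not batch:
        raise ValueError("empty batch")
    systems = [NeighbourhoodSystem.build(L, K) for L in landscapes]
    triplets = [stage_triplet(x, landscapes, K=K, tol=tol, systems=systems)
                for x in batch]
    votes = Counter(t.stage for t in triplets)
    # majority, ties broken by developmental order
    best = max(votes.values())
    stage = next(s for s in STAGES if votes.get(s, 0) == best)
    return BatchStageReport(batch_stage=stage, triplets=triplets,
                            vote_distribution=dict(votes))


def blank_prevalence(
    batch: list[QueryNut],
    landscape: Landscape,
    K: int = 10,
    n_branches: int = 2,
) -> pd.DataFrame:
    """Annotate each query with its nearest admitting neighbour's branch blank rate.

    The reference landscape's column dendrogram is cut into ``n_branches``
    branches and each branch's blank fraction computed; a query inherits
    the rate of the branch of its nearest *admitting* neighbour (a
    candidate whose K-NN radius covers the query).  Queries admitted by no
    candidate are flagged as outliers and excluded from the weighted mean.
    Returns a frame (nut_id, annotated_rate, neighbour_id, outlier) whose
    ``attrs["mean_rate"]`` is the mean annotated rate over non-outliers.
    """
    rates = branch_blank_rates(landscape, n_branches=n_branches)
    assign = rates.attrs["assignments"]
    branch_rate = {int(r.branch): float(r.blank_rate)
                   for r in rates.itertuples() if r.branch != 0}
    nut_branch = {nid: int(b) for nid, b in zip(landscape.nut_ids, assign)}
    system = NeighbourhoodSystem.build(landscape, K)

    rows = []
    for x in batch:
        candi, dists = candidate_neighbours(x, landscape, K)
        admitted = [(d, z) for z, d in zip(candi, dists) if d <= system.radius[z]]
        if not admitted:
            rows.append([x.nut_id, np.nan, "", True])
            continue
        _, z = min(admitted)
        rows.append([x.nut_id, branch_rate[nut_branch[z]], z, False])
    df = pd.DataFrame(rows, columns=["nut_id", "annotated_rate", "neighbour_id",
                                     "outlier"])
    ok = df[~df["outlier"]]
    df.attrs["mean_rate"] = float(ok["annotated_rate"].mean()) if len(ok) else np.nan
    df.attrs["n_outliers"] = int(df["outlier"].sum())
    return df


def votes_from_distance_table(
    neighbour_distances: np.ndarray, query_distances: np.ndarray, K: int = 10
) -> tuple[int, float]:
    """Vote count and OddsG from a printed NcN distance table.

    ``neighbour_distances`` is K x K: column k lists candidate k's own K
    ranked nearest-neighbour distances; ``query_distances`` is the query's
    distance to each candidate.  Candidate k votes (admits the query) iff
    the query's distance does not exceed its K-th, i.e. largest, neighbour
    distance.  Zero votes means OddsG = 0 — the query is an outlier.  When
    votes exist, the exact OddsG needs the neighbourhood memberships, which
    a distance table does not carry; the admitted fraction votes/K is
    returned as a summary score in that case.
    """
    nd = np.asarray(neighbour_distances, dtype=float)
    qd = np.asarray(query_distances, dtype=float)
    if nd.shape != (K, K) or len(qd) != K:
        raise ValueError(f"expected a {K}x{K} table and {K} query distances")
    votes = int((qd <= nd.max(axis=0)).sum())
    return votes, 0.0 if votes == 0 else votes / K
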