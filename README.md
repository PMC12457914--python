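# hullscape

Image-based assessment of pistachio nut maturity and blank-kernel incidence
from hull colour patterns.

Pistachio (*Pistacia vera*) hulls change colour as nuts ripen, and specific
patterns — notably red colouration near the nut tip — are associated with
*blank* nuts (shells with no kernel). `hullscape` turns plate photographs of
nuts on a white background into quantitative hull-colour features, screens
those features against kernel status with contingency-table ensemble
statistics, organizes the confirmed associations into topological *colour
landscapes*, and uses those landscapes to (i) place a nut of unknown age at
one of six developmental stages anchored to three critical time points
(CT1 ≈ 1800, CT2 ≈ 2100, CT3 ≈ 2500 growing degree days) and (ii) estimate
the prevalence of blank nuts in a batch. It is aimed at plant scientists and
growers who want objective, camera-based harvest-timing and quality
decisions.

## Method

The pipeline, module by module:

1. **imaging** — white-balance the plate with diagonal von-Kries gains
   estimated from the white background, adaptive-threshold the luminance
   channel, and extract each nut as a *pixel ensemble* of five-dimensional
   measurements (x, y, r, g, b). Kernel status (blank/filled) is copied from
   the paired opened-nut plate by position.
2. **tipgeom** — PCA of the pixel coordinates gives the approximating
   ellipse; of the two extreme pixels along the long axis, the one farther
   from the centre is the tip. All pixels are ranked by distance to the tip.
3. **palette** — pooled pixels of reference nuts are clustered (Euclidean,
   Ward-D2) into 9 colour profiles; the darkest is the black
   background/edge cluster and is excluded, leaving 8 *major colours*.
4. **features** — for 7 tip-anchored regions (full hull, tip-closest-k and
   tip-farthest-k for k = 30/50/70 % of hull pixels) the per-major-colour
   pixel proportions give 56 features f ∈ [0, 1] per nut; features with
   sample SD < 0.01 are discarded; the rest are binarized at their median
   (and paired into C(56,2) = 1540 order-2 variables).
5. **ceda** — each feature category is cross-tabulated against Y ∈
   {blank, filled}. Row entropies (−Σ p ln p, nats) and blank/filled odds
   are compared between an *alternative* ensemble (columns resampled from
   observed within-column proportions) and a *null* ensemble (columns
   resampled from marginal proportions, i.e. independence), both
   multinomial with column sums fixed. The histogram overlap of the two
   distributions estimates the minimum sum of Type-I and Type-II errors;
   categories with overlap ≤ τ are *major*.
6. **landscape** — major categories × nuts form a binary matrix; Ward-D2
   dendrograms on both axes give the block heatmap, and each nut's column
   is its individual colour landscape. K-nearest-neighbour distance
   profiles (K = 10) summarize the local geometry.
7. **gsd** — a query nut's OddsG score in a reference landscape is the best
   neighbourhood-support fraction among candidates that *admit* it (query
   distance ≤ candidate's K-th-NN radius); no admitting candidate ⇒
   OddsG = 0 (outlier). The triplet (OddsG1, OddsG2, OddsG3) is matched to
   six stage patterns, batches are staged by majority, and blank prevalence
   is estimated from dendrogram-branch blank rates of admitting neighbours.
8. **phenology** — growing degree days,
   GDD[n] = Σ max((Tmax + Tmin)/2 − 7 °C, 0), anchor the critical time
   points.
9. **synthdata** — seed-deterministic synthetic plates, planted feature
   tables and block landscapes with ground-truth manifests, plus the
   published reference tables as packaged fixtures.

## Worked example

The published CT3 contingency table for the full-hull colour-1 feature,
analysed with the odds statistic:

```python
import hullscape as hs
from hullscape import synthdata

fx = synthdata.fixtures()
t5 = fx["T5"]
print(t5.counts)                 # [[19 26]
                                 #  [ 2 43]]
print(t5.row_odds)               # [0.73077 0.04651]
print(t5.baseline_odds)          # 0.30435
v0 = hs.assess_category(t5, row=0, statistic="odds", M=1000, seed=1, tau=0.1)
v1 = hs.assess_category(t5, row=1, statistic="odds", M=1000, seed=1, tau=0.1)
print(v0.overlap, v0.is_major)   # 0.0190 True
print(v1.overlap, v1.is_major)   # 0.0110 True
```

Of the 21 blank nuts at harvest, 19 sit in category 0 (below-median
colour-1 proportion): the blank odds there (0.731) is well above the
marginal odds (0.304), while category 1's odds (0.047) is well below.
Both categories' alternative-vs-null odds distributions barely overlap
(≈ 0.02 and ≈ 0.01, i.e. a minimum Type-I + Type-II error of 1–2 %), so
both are major feature-categories at τ = 0.1 — hull colour at harvest
carries strong information about kernel status.

The growth-stage vote rule on the published nearest-neighbour distance
table (a CT2 nut tested against the CT3 landscape):

```python
from hullscape.gsd import votes_from_distance_table
t6 = fx["T6"]
votes, odds = votes_from_distance_table(
    t6["neighbour_distances"], t6["query_distances"], K=10)
print(votes, odds)               # 0 0.0
```

Every query distance (9.27–10.44) exceeds every candidate's own 10th-NN
radius (at most 8.00), so no candidate admits the query: OddsG3 = 0 and the
CT2 nut is correctly flagged as an outlier in the CT3 landscape.

A full image-to-landscape run from the command line:

```sh
hullscape simulate plate --n-nuts 30 --seed 1 --out plate/
hullscape segment --plate plate/plate.png --out nuts/
hullscape palette build --manifest nuts/manifest.tsv --seed 1 --out palette.json
hullscape features --manifest nuts/manifest.tsv --palette palette.json --out features.tsv
hullscape filter --features features.tsv --min-sd 0.01 --out filtered.tsv
hullscape ceda --features filtered.tsv --order 1 --stat odds --tau 0.1 --seed 5 --out verdicts.tsv
hullscape landscape --verdicts verdicts.tsv --features filtered.tsv --out landscape/
```

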