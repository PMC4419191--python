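# Methods

This note documents the statistical procedures implemented in `pathsea`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## Data model

A study is a set of feature tables (`OmicsDataSet`) sharing one ordered
condition list.  The sample design is a sidecar CSV
(`sample_id,condition,biounit,dataset`) rather than being encoded in the
column headers: it makes the replicate structure explicit and testable.
Every sample belongs to exactly one *biological unit*; samples sharing a
unit are technical replicates and must share the unit's condition.
Condition order is first-seen order in the design file and is used by all
profile matrices and exports.  Missing intensities are rejected rather
than imputed — there is no principled imputation rule for non-targeted MS
intensities, and silent imputation would distort the permutation null.

Microarray-style expression tables are typically quantile-normalized
before analysis; `quantile_normalize` maps each column to the per-rank
means of the column-sorted matrix, ties receiving the mean of the
rank-means they span (deterministic, order-invariant).

## Signal-to-noise ranking and permutation FDR

For a feature with intensities `x_cj` (condition `c`, replicate `j`),

```
signal  = aggA(condition means over A) − aggB(condition means over B)
noise   = sqrt( Σ_c Σ_j (x_cj − m_c)² / (N − C) )
SNR     = signal / noise
```

The default signal is the full range (max − min over all condition
means); customized signals take the max/min/mean over two disjoint
condition subsets, which turns the score into a targeted pattern search.
`0/0` scores 0; a positive signal with zero noise scores `+inf` (such
features sort first, ties broken by input order).  The score is invariant
under global intensity scaling, and no log-transform is applied by
default: the permutation test below makes no distributional assumption,
which is what lets heterogeneous metabolome and transcriptome tables run
through one framework.

Significance: condition labels are permuted uniformly over biological
units (condition sizes preserved, identity permutation allowed, sampling
with replacement), so technical replicates always move as a block.  Units
with the same id in different data sets are the same biological sample
and are relabeled together; explicit link groups can merge further units.
From `P` permuted score vectors the q-value at observed score `t` is

```
q(t) = min(1,  mean_π #{permuted ≥ t} / #{observed ≥ t} )
```

monotonized to be non-increasing in `t` (each q becomes the minimum raw
FDR at or above its threshold).  The numerator uses the mean over
permutations (the common SAM variant; switchable via `monotonize` and
documented here rather than hidden).  Defaults: `P = 1000`, pass
threshold `q < 0.05`.  Features whose customized SNR exceeds a ratio
threshold (default τ = 2, strict) can be tagged with a profile label for
downstream inspection.

## Adduct and isotope correction

Each rule maps an observed m/z of a singly charged ion back to a neutral
monoisotopic mass, `M = m/z − δ − k·1.003355` (k = extra neutrons).
Default positive-mode rules: [M+H]+ (+1.007276), [M+Na]+ (+22.989218),
[M+K]+ (+38.963158), [M+NH4]+ (+18.033823); negative mode: [M−H]−
(−1.007276), [M+Cl]− (+34.969402), [M+HCOO]− (+44.998201); isotope
offsets k ∈ {0,1,2} on each.  These are the common ESI species; the set
is user-overridable via a rules CSV, and charge states z > 1 and
in-source fragments are out of scope.

Grouping is deterministic: features are processed in canonical order
(descending maximum intensity, ties by feature id); the strongest
unassigned feature seeds a group under the mode-default rule ([M+H]+ /
[M−H]−), then any unassigned feature with some rule candidate within the
mass tolerance of the running representative mass and the rt tolerance
of the seed's retention time is absorbed (best candidate by smallest
mass error, then smaller isotope offset, then rule order).  The
representative mass is the intensity-weighted mean of member corrected
masses.  Defaults: mass tolerance 0.01 Da, rt tolerance 0.05 min.  The
greedy strongest-ion-anchors heuristic is O(F²) worst case and is
order-invariant by construction; with noise-free m/z and metabolites
separated by more than twice the tolerances, recovery of the true groups
is exact (asserted in the tests).

## 1D-SOM profile clustering

Replicate intensities are averaged per condition (arithmetic mean) and
each profile normalized to unit Euclidean length (all-zero profiles are
excluded and reported).  The map is a chain of K prototypes (default 30)
trained in batch mode: assign each profile to its nearest prototype,
then update `w_k = Σ_i h(k,k*(i)) x_i / Σ_i h(k,k*(i))` with Gaussian
neighborhood `h(a,b) = exp(−(a−b)²/2σ²)`.  σ decays geometrically from
K/4 to 0.5 over 50 epochs (all overridable); at σ → 0 the update is
exactly batch k-means, which gives a testable anchor (quantization error
non-increasing per epoch, agreement with Lloyd's algorithm from the same
initialization).  Initialization interpolates linearly between the two
most distant profiles of a seeded subsample (≤ 1000), so training is
reproducible bit-for-bit given the seed.  Empty clusters keep their
previous prototype.  Ties in assignment go to the lowest index.  The
prototype index is the cluster order used in all exports; interactive
heatmap browsing is out of scope — exports are static CSV.

## Pathway databases and mapping

Databases are flat CSVs, one row per entry–pathway membership
(`entry_id,entry_name,entry_type,formula,mass,pathway_id,pathway_name,
database_label`).  Compound entries need a monoisotopic mass, either
given or computed from the molecular formula over {C,H,N,O,P,S} (the
atomic-mass table is extensible).  MS features match compounds by
|corrected mass − entry mass| ≤ 0.01 Da; transcript features match gene
entries by case-insensitive exact id (fuzzy name matching is deliberately
omitted).  All matches are kept — ambiguity is data, not an error.

Accurate-mass matching cannot separate isobaric compounds, so before the
entry-based test the compound entries are collapsed into *mass clusters*:
single-linkage chains over the sorted mass list with gaps ≤ the
tolerance.  Single linkage is order-independent and captures exactly the
"one feature hit reaches all isobaric entries" dependence the clustering
is meant to absorb.  Genes are never mass-clustered.  Clusters are
computed over the union of entries of all loaded pathways after the
pathway-size exclusion (below).

## Enrichment analysis

Pathways with more than 500 associated entries (unspecific "global"
maps) are excluded before any testing.  Per-pathway p-values are
computed separately per data set and then combined (below).  The
enrichment inputs are the *full* ranked data sets with the FDR-passing
features as the selection; running on pre-filtered tables would make the
selection equal the universe and degenerate the hypergeometric tests.

**Entry-based (E-SEA).**  Counting units are mass clusters (compounds)
plus individual genes.  With `N` units matchable by any feature of the
data set, `K` of them matched by selected features, and a pathway
containing `n` matchable units of which `k` are selected-matched, the
p-value is the exact hypergeometric upper tail `P(X ≥ k)`,
`X ~ HG(N, K, n)`.  The universe could alternatively be *all* database
entries; the matchable-by-any-feature universe is the default because it
conditions on what the instrument could actually see.  Compound clusters
and genes are counted in one combined test.

**Marker/feature-based (M-SEA).**  The member features of a pathway are
those matching any of its entries, with adduct-group deduplication:
features in the same adduct group matching the same entry are redundant
ion species of one putative metabolite and only the best-ranked
representative is counted.  Statistics on the member ranks (1 = best
SNR): static hypergeometric on the top-`n_selected` cut; iterative
hypergeometric (iGA) `min_j P(X ≥ j | n = r_j)` over the sorted member
ranks — reported as a ranking *score*, since the prefix minimum is not
corrected for the number of prefixes tried; one-sided exact Mann–Whitney
(normal approximation above 10⁶ pair comparisons); and a one-sided
Kolmogorov–Smirnov statistic `D⁺ = max_j (j/m − (r_j − j)/(F−m))` with
the asymptotic tail `exp(−2 D² m(F−m)/F)`.

**Sample-based (S-SEA).**  Member sets are fixed from the observed
mapping — using a rank-independent representative (the strongest ion)
for adduct deduplication, since a best-observed-rank choice would leak
ranking information into the permutation test — and only the SNR ranking
is recomputed per permutation of condition labels (biological units as
blocks, data sets linked).  With `T` the rank-sum or KS statistic
oriented so larger = more enriched, the p-value is the smoothed
permutation tail `p = (1 + #{T_π ≥ T_obs}) / (1 + P)`, never zero by
construction.  This mode assumes neither independent features nor
independent entries, at the cost of replicates and computation.

## Meta-analysis and FDR

Per-data-set p-values are combined per pathway with Fisher's method
(χ² upper tail of −2Σln p, 2D df) or Stouffer's z (equal weights;
boundary p-values clamped with a warning).  Pathways with no matched
entries in a data set contribute p = 1 rather than being dropped, so a
pathway visible in only one platform is penalized, not privileged
(switchable by passing an explicit selection).

FDR over the pathway list: Benjamini–Hochberg step-up by default.  For
the sample-based mode the permutation rounds additionally yield null
meta-p-values — each round's statistic is ranked leave-one-out against
the other P−1 rounds plus the observed statistic, with the same
+1/(P+1) smoothing, which makes observed and null p-values exchangeable
under the global null — and the reported FDR is the plug-in estimate
`FDR(p₀) = mean_π #{null meta-p ≤ p₀} / #{observed ≤ p₀}`, monotonized
and capped at 1.  The Fisher combination of linked (hence dependent)
per-data-set p-values is not χ²-calibrated; the permutation FDR, which
inherits the dependence, is the authoritative error estimate in that
mode.

## Synthetic studies

The generator plants a known truth in a realistic design: 6 conditions ×
3 biological replicates; MS intensities measured twice per sample
(technical replicates), transcripts once.  Each metabolite appears as
several adduct features (relative ion yields ~1 : 0.4 : 0.2 for
H/Na/K) with Gaussian m/z error (σ = 0.002 Da) and a shared retention
time; metabolite masses sit on a jittered 0.5-Da grid so true identities
are unambiguous.  Intensities are multiplicative: base level ×
condition multiplier × log-normal biological noise (σ = 0.3) ×
log-normal technical noise (σ = 0.1).  Members of enriched pathways get
the induction template [1, e, e, 1, 1, 1] with e = 5 (induction at
conditions 2–3); enriched-pathway members are drawn exclusively so null
pathways stay null.  Null features are exchangeable across conditions by
construction — the basis of every calibration test.

What the generator does **not** emulate: chromatographic peak shapes,
isotope-pattern intensities, batch effects, missing values, correlated
features beyond the adduct structure, and heavy-tailed contamination.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not robustness to every artifact
of real LC/MS data.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use studies of 150–500
features per data set, 20–50 pathways, and 100–200 permutations (5–20
seeds where rates are estimated).  These sizes give stable estimates of
the calibration and recovery rates while keeping a full run in the
minutes range on one CPU; all of them scale up linearly via the
`StudySpec` and config parameters, and the analysis defaults
(P = 1000) are unchanged by the test settings.

## Known limitations

- The adduct grouping is greedy; a dominant wrong-rule seed can split a
  group (rare under the default rule sets, impossible with noise-free
  masses and well-separated metabolites).
- iGA scores are not multiplicity-corrected p-values; treat their
  absolute scale with care (ranking is fine).
- The marker-mode KS p-value is asymptotic; for very small pathways the
  rank-sum or hypergeometric statistics are preferable.
- Mass clustering at a fixed tolerance is a hard threshold; compounds
  just beyond 0.01 Da count as distinct evidence even though the
  instrument may not separate them.
- Quantile normalization assumes comparable global intensity
  distributions across samples; it is applied per data set, never across
  platforms.
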