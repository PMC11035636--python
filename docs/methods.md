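# Methods

## Data model

An MS² spectrum holds a precursor m/z, charge, retention time, adduct
label (`M+H`, `M+NH4` or `unknown`) and an m/z-sorted peak list with
finite non-negative intensities; fragments may exceed the precursor by
at most 1 Th (isotope overshoot). The feature table is a features ×
samples matrix of non-negative peak-area responses with per-feature
metadata (precursor m/z, adduct, retention time) and per-sample
metadata (group, timepoint in hours, replicate). All m/z values are
64-bit floats with no internal rounding. MGF parsing and writing are
delegated to pyteomics; both GNPS-style (`FEATURE_ID=`, `SCANS=`) and
generic `TITLE`-keyed blocks are accepted, a block without `PEPMASS` is
a parse error naming the block index, and a missing charge defaults
to 1. Whether deposited MGF intensities are raw or normalized is not
assumed anywhere — the cosine is scale-invariant per spectrum.

## Modified cosine and network topology

Two fragment peaks are match candidates when they agree directly
(|Δm/z| ≤ tol) or when they agree after shifting by the precursor mass
difference; the fragment tolerance defaults to 0.01 Th (appropriate for
Orbitrap-resolution data) and is configurable. Each peak may be used
once. The reported score is the **exact maximum** of the matched
intensity-product sum over all admissible one-to-one pairings, found by
a Hungarian assignment on the candidate weight matrix, normalized by
the product of the two spectra's Euclidean intensity norms — so the
score is 1.0 for identical spectra and provably within [0, 1]
(rearrangement/Cauchy–Schwarz). We chose exact assignment over the
common greedy best-first pairing because greedy can lose on crossing
candidate pairs (weights 2.0/1.9/1.9) and spectra are small enough that
O(n³) assignment is negligible; the test suite checks equality against
an exhaustive permutation oracle on ≤ 8-peak spectra. Intensities are
used raw; a square-root transform can be applied by the caller before
scoring if desired.

Network construction: candidate edges are all spectrum pairs with
|Δprecursor| ≤ 500 Th, cosine ≥ 0.5 and ≥ 5 matched peaks; an edge
survives only if each endpoint ranks the other within its top-10
candidates (ranked by cosine descending, partner id ascending —
thresholding before or after the mutual filter yields the same edge
set); then, while any connected component exceeds 100 nodes, its
lowest-cosine edge is removed (ties broken by the sorted edge-id pair).
All tie-breaks use ascending feature id, making every run
deterministic. Self-loops and duplicate edges cannot arise. Nodes carry
the feature's mean relative abundance across samples as a size
attribute. Singletons are degree-0 nodes; the summary partitions nodes
into singletons and members of similarity groupings.

## Annotation rules

Rules are data (`data/default_rules.json`), matched first-to-last,
most-specific first: a rule fires when all its required fragment ions
are present within tolerance (and the precursor falls in the rule's
window, when one is given); the first firing rule assigns class and
core; otherwise the class is `unknown`. The only physically anchored
masses are the ones the system prints: the AR core ion 653.681
(C43H89O3+), lysoAR-glycerol 373.368 (C23H49O3+), and one exemplar
precursor per class (1G-AR 832.760, 2G-AR 994.813, bacterioruberin
741.581, CL-AR-AR 1522.313, MK(8:8) 717.560, PG-AR 807.684, PGP-Me-AR
901.666, PG-PG-AR 961.687). The head-group reporter ions and
family-shared fragment sets below those anchors are synthetic template
values: they serve rule matching and spectrum simulation, and were
chosen so that no two classes share a reporter within twice the
matching tolerance and no reporter set of one class maps onto
another's by a constant mass offset that equals an achievable precursor
difference (otherwise the shifted matching would bridge classes — the
glycosyl step 1G→2G and the methylation ladder MK→MMK→DMMK are real
traps here).

Structural decoding inverts integer mass increments: for menaquinones,
precursor = MK(8:8) anchor + (n−8)·68.0626 (isoprenoid unit C5H8) +
(n−m)·2.01565 (H2 per saturated bond), searched over n ∈ [2, 20],
m ∈ {n−1, n, n+1}; the decomposition is unique in that range because
the largest saturation contribution stays below one isoprenoid unit.
For archaeol cores, chain extension (C5H10, 70.0783, C20→C25 marking
EXT-AR) and methylation steps (14.0157) are decoded the same way. The
saturation summary reports abundance-weighted mean double-bond counts
per class per sample, and bins menaquinone-family abundance into
relative-saturation categories {n:n−1, n:n, n:n+1}.

The shipped rules cover only the printed exemplar anchors; a richer
curated rule table can be dropped in as JSON without code changes.

## Composition conventions

Processing order is recovery correction → adduct merging → closure to
relative abundances, mirroring the laboratory narrative. Recovery
correction divides each sample column by its internal-standard
response and removes the standard row; a non-positive standard is an
error naming the sample. Adduct merging pairs an `M+H` feature with an
`M+NH4` feature when the precursor gap is 17.02655 Th (monoisotopic
NH3) within tolerance and retention times agree within 10 s (default);
many-to-many ambiguities resolve greedily by smallest mass error, then
smallest Δrt; the merged component keeps the protonated feature's id
and the summed abundances, so totals are conserved exactly. Presence in
a condition group is called on the replicate-mean relative abundance
(configurable to any-replicate), with the boundary convention that a
value exactly at the 0.01% threshold counts as present (absence is
defined as *less than* the threshold). UpSet counting censuses features
over exact membership patterns, so the counts partition the features
present in at least one group.

## Information-theory indices

Base-2 logarithms throughout; all indices are in bits; 0·log2(0) := 0
by continuity. Lipids absent from every sample are dropped before
specificity (their mean frequency makes the ratio undefined) with a
warning. The per-lipid-per-sample term S_ij is exposed un-averaged,
S_i is its mean over samples. The lipid universe defaults to annotated
lipids plus class-linked unknowns in the pipeline (all-features mode is
available); the published index values depend on that choice, so no
specific universe is claimed to reproduce any particular figure.
Group error bars are replicate mean ± sample sd (sd is reported missing
— never zero — for single-replicate groups), with an optional seeded
bootstrap over replicates.

## Multivariate and univariate statistics

The Hellinger transform closes each sample row to proportions and takes
square roots, putting samples on the unit sphere so that Euclidean
distance equals Hellinger distance and double zeros stop inflating
similarity. PCA is column-mean-centered with no unit-variance scaling
(the transform already equalizes scale), keeps all min(n−1, p)
components so the explained-variance ratios sum to 1 on full-rank data,
and fixes each component's sign by forcing its largest-magnitude
loading positive. All-identical input is flagged `zero_variance` rather
than erroring. Class heatmap rows are Z-scored with the sample (n−1)
standard deviation — zero-variance rows become 0 with a warning — and
clustered agglomeratively (Euclidean, average linkage by default);
clipping to ±3 applies to the display copy only, never to the
clustering input. Tukey HSD runs on the studentized-range distribution
of the one-way layout (scipy) and is two-sided by default; a
`one_sided` flag halves each pair's p-value in the observed direction,
a pragmatic convention adopted because a directional HSD is not
standard and no direction is otherwise defined. Letters come from the
insert-and-absorb compact-letter-display algorithm, so groups sharing
no letter differ at the chosen alpha and vice versa.

## Synthetic study design

The default design mirrors the study scale: 246 lipid species over 16
classes (AR 8, PG 25, PGS 13, PA 4, PGP-Me 22, PGPG 11, CL 41, 1G 2,
2G 2, S 3, MK 39, DMK 25, MMK 20, DMMK 14, bacterioruberin 15,
squalene 2 — the published class taxonomy details ~184 of the 246; the
remainder is allocated here to the menaquinone subtypes, PA and
squalene), three culture conditions (host, symbiont, co-culture) × 5
timepoints × 3 replicates = 45 samples. Group-exclusivity blocks plant
the species-count structure: 86 species common to all cultures, 20 in
host+co-culture only, 14 host+symbiont, 45 host-private, 71
co-culture-private, 7 symbiont+co-culture and 3 symbiont-private —
giving 165 host, 110 symbiont and 184 co-culture species. Species are
assigned to blocks class-by-class with a deterministic
largest-remainder rule so every class spreads over the membership
patterns. Planted class-share vectors give the symbiont its PGP-Me
dominance (44% after normalization) and near-exclusion of
bacterioruberin (0.2%), with host and co-culture at intermediate,
distinct profiles; within a class, species weights are drawn once per
design from U(0.5, 1.5) and normalized, with a floor of 1.5×10⁻⁴
relative abundance (rebalanced inside the class) so every planted
species sits above the 0.01% presence threshold at zero noise.

Sample abundances are total_abundance × planted share × exp(σz) with
σ = 0.25 by default (log-normal multiplicative noise at a level typical
of peak-area reproducibility in replicate cultures) plus a per-sample
log-normal depth factor; at σ = 0 the realized relative abundances
equal the planted shares exactly. Half the species (probability 0.5)
appear as [M+H]⁺/[M+NH₄]⁺ pairs split 70/30, and a spiked
internal-standard row is included. Spectra are built from the class
rule templates: family-shared core fragments, class reporter ions, a
water-loss peak tracking the precursor, and two low-mass peaks whose
intensities rotate (cos φ, sin φ with φ spanning 1.4 rad across the
class) along the within-class species series — this makes same-class
similarity decay smoothly with structural distance, so mutual-top-K
networks stay connected per class instead of collapsing into tie-broken
cliques. Fragment m/z jitter is Gaussian (sd 0.002 Th) and spurious
peaks are Poisson (mean 1 per spectrum) at uniform random m/z. All
randomness derives from one integer seed via named spawned sub-streams
(allocation, weights, adducts, abundance, spectra), so realizations are
bit-identical per seed.

The ground truth returned with each realization includes the noiseless
frequency profile and the diversity/specialization values it implies;
the planted specialization ranking (co-culture > host > symbiont under
the default blocks) is the ranking computed on that noiseless profile.

What the generator does **not** emulate: isotope envelopes,
chromatographic peak shape, retention-time drift, ionization
suppression, missing-value censoring, or unsaturation variation within
the bilayer glycerolipid classes (saturation structure is planted only
in the menaquinone families). Passing tests therefore demonstrate
correctness of the computations and recoverability under multiplicative
noise — not robustness to every artifact of real LC-MS data.

## Problem sizes and numerical choices

Tests and the acceptance script run the default design (246 species, 45
samples, ≤ 380 spectra) and a 120-spectrum oversized-component fixture;
pairwise scoring of a few hundred Orbitrap-sized spectra takes seconds.
Ranking robustness uses 20 independent seeds of the default noisy
design. Column closure is asserted to 1e-9; oracle agreement for the
information indices to 1e-12; cosine/brute-force agreement to 1e-9; PCA
reconstruction to 1e-9. Degenerate inputs have explicit behavior
(empty samples warn and stay zero, empty spectra are errors,
zero-variance rows/flat designs are flagged), and every ambiguity is
resolved by a documented deterministic tie-break rather than dict or
hash order.
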