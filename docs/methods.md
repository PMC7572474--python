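# Methods

This note documents the models, rules and numerical choices behind
`nichescope`, what the synthetic community generator does and does not
emulate, and the design decisions taken where the procedure was genuinely
open.

## Depth, quality filtering and inputs

Depth-of-coverage of a feature is its summed per-base depth divided by its
length. rMAG-level depth is the contig-length-weighted mean,
Σ contig summed depth / Σ contig length; a simple mean over contigs would
over-weight short contigs, and the weighted form is exactly the coverage a
mapper reports for the concatenated genome. Depth tables are dense after
loading — a missing (feature, sample) pair is an explicit 0, not NA — because
the activity rules downstream branch on zero values.

Genome quality filters: MAGs are retained at completeness ≥ 0.28 and
contamination < 0.20 (strict); rMAG selection additionally requires
completeness − contamination ≥ 0.50 and a kingdom-level taxonomic call.
Completeness and contamination are stored as fractions in [0, 1]; readers
accept percent columns behind a flag.

## Fundamental niche typing

The KO presence matrix sets cell (r, k) = 1 iff at least one gene of rMAG r
carries KO k. Distances are binary Jaccard; a pair of all-zero rows has an
undefined 0/0 ratio and is assigned distance 0 with a warning (the two empty
repertoires are operationally identical).

Classical (Torgerson) MDS double-centers −½D², takes the top positive
eigenvalues and reports per-axis variance explained relative to the sum of
positive eigenvalues. Clustering operates on the 2-D embedding — not on the
raw distance matrix — for fidelity to the visual-ordination workflow this
pipeline reproduces, even though clustering D directly (e.g. PAM) would be
statistically cleaner.

k-means uses k-means++ initialization with 25 restarts, keeping the lowest
within-SS solution; labels are renumbered by descending cluster size so that
output labelling is deterministic. The number of centroids is selected over
k = 1…9 by the kneedle chord rule: both axes of the (k, within-SS) curve are
normalized to [0, 1] and the k with the maximum perpendicular distance to the
chord joining the endpoints wins. The rule is automated because the original
workflow chose k by inspection; a `k_override` passes any manual choice
through while still reporting the curve. A non-decreasing curve falls back to
the smallest k with a warning.

KO enrichment per (KO, FunC) pair uses the one-sided (over-representation)
hypergeometric tail of the 2×2 membership table, with Benjamini–Hochberg
adjustment jointly across **all** (KO, FunC) pairs — the widest family, hence
the most conservative choice where the family scope was unstated. Adjusted
p-values are additionally floored at the raw p. Degenerate tables (KO absent
everywhere) get p = 1.

Procrustes superimposition uses the symmetric convention: both
configurations are centred and trace-normalized before the rotation/scaling
fit, so m² ∈ [0, 1] and correlation = √(1 − m²). Conventions differ between
implementations; the symmetric one makes m² comparable across datasets. The
PROTEST p-value counts row permutations of the second configuration with
m² ≤ observed, using (hits + 1)/(n_perm + 1) so p can never be 0.

## Community dynamics

Abundance profiles are correlation-compared and mapped to distances by
d = 1 − (ρ + 1)/2, which sends ρ = 1, 0, −1 to 0, 0.5, 1. PERMANOVA follows
Anderson's partition (SS_total = Σ_{i<j} d²/n; SS_within summed per group
with its own n_g), with the permutation p on pseudo-F. The dispersion test
embeds the distance matrix on all positive-eigenvalue principal-coordinate
axes, measures distances to group centroids and permutes those distances
among samples (the same scheme betadisper uses).

Temporal stability is mean/sd (sample sd, n−1) of the relative-abundance
series — the standard invariability measure; higher means more constant. The
underlying literature offers several variants and the formula is pluggable;
mean/sd is the default because it is the measure whose qualitative behaviour
(stability rises when a disturbance window is excluded) the pipeline tests.
Constant series are flagged as undefined rather than dropped.

Vector fitting regresses each z-scored abiotic factor on the two ordination
axes; the arrow is the unit coefficient vector scaled by √R², so arrow length
is directly comparable across factors, with a permutation p on R². Missing
abiotic values are handled pairwise-complete; no imputation is performed
except the explicit Stineman path for gappy on-site series (e.g. pH).

Stineman interpolation estimates knot slopes from the circle through each
point and its neighbours (secant slope where collinear; one-sided
extrapolation at the ends, sign-guarded against opposing the adjacent
secant) and evaluates the rational interpolant between knots. Interpolated
values are clamped to the local knot interval: the method's defining property
is the absence of overshoot, and the rational form can exceed the knot range
marginally when both knot slopes dwarf the interval secant. Leading/trailing
gaps take the nearest observed value with a warning.

## Realized niches

The gene activity predicate is
`(MG ≥ 1 and MT/MG > 1) or (MG < 1 and MT > 1) or (MP ≥ 2)`,
with inequalities exactly as stated by the rule it implements. The MG < 1
fallback compares raw MT depth against the same threshold of 1 that the
ratio rule uses — the comparison value is otherwise unstated — to avoid
inflating active calls for lowly abundant populations. The spectral-count
clause is evaluated per gene per sample (the rule's subject is the gene, not
the KO). A KO is active iff any member gene passes.

Per-time-point expression clustering: binary Jaccard over activity vectors →
2-D classical MDS (fixed at two dimensions so each time-point yields one
ordination) → HDBSCAN with min_cluster_size = min_samples = 5. Points in no
cluster keep an explicit noise label (0) in all outputs; cluster labels are
ordered by descending size. scikit-learn's HDBSCAN implementation stands
behind this surface.

MT/MG ratios are computed per (rMAG, sample) at the rMAG depth level,
averaged over the samples of each condition; MG = 0 samples are excluded
with a logged count, and grouped summaries report median and quartiles.

## Functional trends

Per FOAM L1 category and time-point, gene MT depth (resp. MP counts) is
summed and divided by the total over **all** genes — annotated or not — so
category contributions sum to at most 1 and unannotated signal dilutes every
category equally. Each category's relative series is min–max scaled per
series (each panel spans [0, 1] on its own); scaling is affine, so the
Pearson correlation between the MT and MP series is unchanged by it. Genes
listed with multiple FOAM L1 labels count in each. Categories are ordered by
descending mean MP relative count.

## Metabolomics QC

Blank rule: a metabolite is removed when its mean blank intensity exceeds
75 % of its mean sample intensity (strictly), with missing values counted as
0 in both means — the conservative reading that favours removal; a
detected-only variant is available behind a flag. Prevalence rule: detection
(present and > 0) in every pool and in ≥ 25 % of sample measurements (90 %
for correlation workflows). Both filters are per-metabolite predicates and
therefore commute.

Drift normalization divides each measurement by the mean of that
metabolite's intensities in up to two nearest preceding **and** two nearest
following pool injections (≤ 4 pools; "up to two preceding and subsequent"
is read as two per side). Pools missing the metabolite are skipped; a
metabolite absent from all pools is left unnormalized and flagged. The
operation is scale-equivariant. Each fraction is normalized independently,
matching pools that mix extracts of one measurement type only.

Drift QC (`pool_drift_qc`) evaluates pools with a complete two-sided window
(interior pools). Boundary pools necessarily retain a residual trend because
their window is one-sided — an edge property of any local normalization —
so including them would mis-state how well the drift was removed where the
method is actually defined. Pools are replicated identical material and
carry the drift signal without biological variance, which samples do not.

Intra/extracellular ratios divide drift-normalized intensities per
time-point for metabolites detected in both fractions; zero or missing
extracellular values leave the cell missing. No log transform is applied at
this stage (z-scoring happens downstream where factors are fitted).

## Taxonomy consensus

Per (rMAG, rank), marker assignment probabilities are summed per taxon; the
top taxon wins with confidence score/total, and a winner below 1/3 becomes
"low confidence assignment". The result is invariant to rescaling all
probabilities, so raw non-negative weights are acceptable. Ties break
lexicographically with a warning. Ranks are treated independently (an
optional strict mode could force lineage consistency, but none is enforced
by default because the consensus rule itself is rank-local). Genome-level
calls take precedence; consensus fills only unassigned ranks; merged
lineages without a kingdom are flagged for removal.

## Synthetic community generator

The generator emulates the study conditions end-to-end, with one
pseudo-random stream per sub-simulation (derived from the master seed by
fixed offsets, so adding a stage never perturbs earlier draws):

- **Repertoires.** 78 rMAGs in 4 types over a 9000-KO universe: 1857 core
  KOs shared by everyone; unequal type-specific blocks (700/550/850/400 by
  default — one guild has a visibly reduced repertoire); 300-KO blocks
  shared by ring-adjacent type pairs, i.e. overlap along functional
  gradients, which places the four types at unequal pairwise distances and
  makes the configuration genuinely two-dimensional; each member carries a
  uniform-random 60–100 % of its type blocks (guild members rarely encode
  the full guild repertoire — this is the within-cluster spread); 120
  private KOs per rMAG; and independent cell flips at 2 % noise.
- **Time series.** Abundance = positive seasonal sinusoid (type-dependent
  phase) × log-normal noise, emitted as contig- and gene-level depths so the
  aggregation paths are exercised. A transient disturbance multiplies 8
  rMAGs by 20 during a four-time-point window — a dominance takeover of the
  magnitude seen when a substrate pulse restructures a community. Gene MT
  depth = MG depth × a per-(type, KO, condition) activity factor (15 %
  silent, 15 % highly active, the rest log-normal around 1); MP counts are
  Poisson with mean 2 × MT depth. Abiotic factors are linear mixtures of
  latent seasonal signals plus a substrate spike during the window.
- **Gene tables.** Gene complements subsample the KO universe through a
  deterministic per-KO keep rule (~250 KOs per rMAG), so every rMAG retains
  the *same* KO columns and the between-repertoire Jaccard geometry is
  preserved while gene-level tables stay small.
- **Metabolome.** Four fractions sharing metabolite-level signal with
  log-normal intra/extra ratios; instrument sequence with pools after every
  fifth measurement and blanks at both ends; monotone exponential drift
  (slope 0.01 per position, ~40 % over a run) multiplying everything;
  6 planted contaminants present in blanks at 100–150 % of their sample
  mean.
- **Taxonomy.** Marker votes hit the true taxon with probability 0.8,
  decoys otherwise; genome-level calls exist for about half the
  (rMAG, rank) pairs.

What it does **not** emulate: read-level sequencing (no FASTQ, no mapper
biases), assembly/binning artifacts, genome incompleteness as KO dropout
correlated with completeness estimates, compositional coupling between MG
and MT library sizes, realistic mass spectra or retention behaviour, and
phylogenetic autocorrelation of repertoires. Passing recovery tests
therefore demonstrates that the statistical machinery identifies the planted
structure at realistic noise levels — not that the thresholds are optimal
for any particular real dataset.

## Problem sizes and determinism

Recovery checks run the default community (78 rMAGs × 9000 KOs) across 20
seeds; expression-regime recovery uses 12-time-point series across several
seeds with three time-points scored per seed; null calibrations use 200
replicates at 99 permutations each. These sizes give stable pass/fail
behaviour at a few seconds per block. All randomness flows from explicit
integer seeds; pipelines re-run byte-identically under the same seed, and
per-stage sub-seeds are recorded in the run report.

## Known limitations

- Clustering on the 2-D embedding discards higher-axis structure by design;
  more than ~5 well-separated types would not embed faithfully in two
  dimensions.
- The elbow rule needs visible within-cluster variance; on data with
  near-zero within-cluster spread it selects the smallest k whose merge cost
  vanishes.
- PERMANOVA's R² on strongly phase-separated synthetic dynamics is far
  higher than typical field values; it is a property of the planted
  conditions, not a calibration target.
- The dispersion test permutes centroid distances (betadisper's scheme),
  which is known to be slightly liberal for strongly unbalanced groups.
- Consensus taxonomy has no lineage-consistency enforcement across ranks.
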