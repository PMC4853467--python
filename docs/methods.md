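# Methods

This note documents the models, rules and numerical choices behind each
stage of the package, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the method left room.

## Read cascade

### Adapter clipping

A clip site is the leftmost read position at which a prefix of the supplied
adapter, at least `min_overlap = 7` bases long, matches the read exactly
through to its 3′ end. Reads without such a site are counted `no_adapter`
and discarded rather than passed through unclipped: inserts are shorter
than the read, so an adapterless read cannot be a clean insert, and the
audit keeps it accountable. Clipped inserts must be *longer than* 15 nt
(`min_clipped_len = 16`); an insert of exactly 15 nt is `too_short`.
Identical inserts are collapsed to (sequence, multiplicity) pairs and any
sequence containing an N is removed and audited.

### Screening

Contaminant and rRNA screens run before library assignment, in that order.
A read is archived when any screening sequence contains it as a substring
with at most one substitution. Substring containment with ≤1 mismatch is a
deliberate stand-in for an alignment step whose exact parameters are
underdetermined; it is symmetric with the library matcher, so the whole
cascade has a single alignment semantics.

### Hierarchical assignment

Libraries are tried in `class_order` (miRNA, tRNA, piRNA, snoRNA, then an
optional exogenous class last); a read claimed by an earlier library never
reaches a later one. Within a library, a hit at 3′ overhang
`h ∈ [0, max_3p_overhang = 3]` requires the read's first `len − h` bases to
occur in a reference with at most `max_mismatches = 1` substitutions. The
overhang models 3′ non-template additions; trimming never shortens the
query below the `seed_len = 19` nt 5′ seed, so reads shorter than the seed
align full-length only (this also resolves the tension between a 19 nt
seed and a 16 nt minimum insert: the seed constraint binds only when the
read is long enough to have one).

"Equally valid" alignments are those achieving the library's minimal
(mismatches, overhang) cost, compared lexicographically — an exact hit at
overhang 3 beats a one-mismatch hit at overhang 0. A read with *k* equally
valid species receives multiplicity/*k* per species; no random
tie-breaking. Fractions are floats; mass conservation holds to 1e−9 and is
asserted at scale in the tests.

The matcher is a bespoke exact/one-mismatch substring index: exact lookups
hash every reference substring of the query length; one-mismatch lookups
use the pigeonhole split (one half of the query must match exactly),
verifying candidates by bounded Hamming distance. Budgets above one
mismatch fall back to a naive scan. Reference sets here are tens of
sequences, so the index is built lazily per query length. A brute-force
aligner that enumerates every (reference, offset, overhang) placement
serves as the oracle in the tests; the two agree species-for-species on
hundreds of random instances.

A deliberate simplification: genome alignment is collapsed into library
alignment (the toy reference sets play the role the genome plays for
locating precursors), there is no indel handling, no quality trimming and
no secondary-structure verification. All matching is on the given strand;
internal coordinates are 0-based half-open.

### Quantification, detection, replication

RPM is per-sample: `10⁶ · count / total mapped count`; samples with no
mapped reads get a missing row. Detection is mean RPM across samples
≥ 1,000 — the "at least 1,000 RPM" operational definition is used where
wording elsewhere says "above" (the detected set differs only on exact
ties). Replication reports, per class, `|A|`, `|A∩B|` (B's detected set
computed with the same rule) and the overlap percentage, plus Spearman's ρ
of log mean RPM over the overlap. Natural log is used; any strictly
monotone transform gives the same ρ, which the tests assert. The two-sided
p-value is an exact permutation enumeration for `|A∩B| ≤ 8` (at most 8! =
40,320 permutations) and the t-approximation otherwise; ρ is reported as
undefined below 3 overlapping species.

## Cq statistics

Cq values are cycles; lower means more template. Non-detects carry an
explicit marker (NaN in memory, `ND` on disk) until censoring, which is the
single place numeric values are imputed: non-detects and observed values at
or above the detection cutoff (23 cycles) are set to the ceiling (24
cycles) and flagged not-expressed. Censoring observed values in [23, 24) is
a choice — the ceiling and the cutoff are both given, but not the handling
of the gap — and keeps "expressed" consistent with what the normalisation
uses.

ΔCq subtracts, per sample, the mean Cq of that sample's *expressed* assays
(per-sample centering is what makes the normalisation correct for
inter-individual offsets; the shift-invariance test asserts it). Censored
entries still get a ΔCq (relative to the same mean) but stay flagged.
Samples with no expressed assay are flagged and left missing.

Haemolysis QC uses raw, pre-censoring Cq: `Δ = Cq(miR-23a) − Cq(miR-451)`.
miR-23a is stable in plasma while miR-451 is red-cell-derived, so lysis
lowers Cq(miR-451) and raises Δ. Bins: Δ < 5 low, [5, 7) moderate, ≥ 7
high (values above the observed range remain high); non-detects in either
assay produce the three missing categories, and the categories partition
the cohort.

Assay-specificity flagging removes assays that are both flat across
samples (expressed-Cq variance below `variance_floor`, default 0.05
cycles²) and expressed in at least `ntc_detect_rate` (default 50%) of
no-template-control wells — the signature of non-specific amplification.

Association is per-assay OLS of ΔCq on a 0/1 covariate. For a binary
regressor the slope is exactly the group mean difference and its t-test is
the pooled-variance two-sample t with n − 2 degrees of freedom, so the
screen is computed in closed form, vectorised; a statsmodels OLS
cross-check lives in the tests. Fold-change is 2^(−slope): > 1 means more
expressed in the covariate = 1 group. BH-FDR at 5% runs across all assays
tested together (statsmodels' step-up, verified against a brute-force BH
oracle); assays with zero residual variance are excluded from BH with a
warning. The median-age split assigns group 1 to ages strictly below the
median (ties at the median to group 0), making "younger" the positive
group. Continuous-age regression and external risk-score models are out of
scope; any precomputed per-sample binary score can be passed as the
covariate.

## Factor structure

Censoring non-detects at the ceiling would inflate correlations among
unexpressed assays, hence the ordinal score: 0 not expressed, 1 expressed
with ΔCq ≥ 0, 2 expressed with ΔCq < 0. The Spearman matrix is the Pearson
correlation of average ranks (exact under heavy ties); zero-variance assays
are dropped with a logged warning since their rank correlation is
undefined.

Extraction is principal-axis with squared-multiple-correlation (SMC)
communalities, non-iterated: the diagonal of the correlation matrix is
replaced by `1 − 1/diag(R⁻¹)`, the reduced matrix eigendecomposed, and
loadings taken as eigenvector times √eigenvalue (negative eigenvalues
clipped). SMC is the standard default when the extraction method is
otherwise unspecified. Singular matrices fall back to a ridge-regularised
inverse (ridge 1e−8) with a warning. The full eigenvalue spectrum is
returned so the retained dimension can be chosen by scree inspection; k = 4
is the configured default for this cohort and there is no automatic elbow
detection.

Varimax uses the SVD-based update with Kaiser row normalisation
(tolerance 1e−6, max 1,000 iterations, best iterate returned with a flag
on non-convergence); the criterion trajectory is exposed so monotone ascent
can be asserted. Row communalities are rotation-invariant to 1e−6. Each
rotated column is sign-fixed so its largest-|loading| entry is positive,
removing the sign indeterminacy.

Membership is exclusive: an assay qualifying (|loading| > 0.4) on one or
more factors is assigned to the factor of maximum |loading|; otherwise
"None". Counts over {F1..Fk, None} therefore partition the assays — the
tested invariant. Ties in |loading| resolve to the first factor by column
order (the situation has measure zero on real data).

Enrichment is the hypergeometric upper tail (`P(X ≥ overlap)`) per pathway
with BH across pathways at α = 0.05; target maps are filtered upstream at
prediction score ≥ 80 before factor target unions become queries. Venn
region counts enumerate every subset of the factor sets; regions sum to the
union.

## Compartments

Long-format donor panels (≥2, typically 6 donors) with plasma as the
referent. Each (assay, component) pair uses the pooled-variance two-sample
t (identical to OLS on a component indicator; Welch is deliberately not
used). `delta = mean plasma Cq − mean component Cq`; significant negative
delta (plasma more abundant) is `up_in_plasma`, positive `down_in_plasma`,
at raw p < 0.05 with no multiplicity correction — a documented divergence
from the cohort association screen, matching how small-panel component
comparisons are reported. Zero pooled variance yields `not_significant`
with a warning. Non-detects in a panel are censored to 24 cycles before
comparison, consistent with the cohort processing. Direction counts per
(class, component) always sum to the class assay total, and swapping the
plasma/component labels flips the two directions exactly.

## Synthetic data

Every generator takes an explicit seed and draws from a single
`numpy.random.default_rng` stream; identical calls are byte-identical.

**Reference sets** draw unique sequences per class with class-typical
lengths (miRNA 21–24 nt, piRNA 26–31 nt, tRNA/snoRNA fragment ranges,
100–160 nt screening sequences); a requested number of piRNA pairs share an
identical sequence to exercise proportional splitting, and impossible
uniqueness requests fail with the class named.

**Reads** are a fixed 50 nt: insert plus the 3′ adapter run-on, truncated.
With inserts of 15–45 nt the adapter is always partially present, so both
the ≥7-adapter-base rule and the >15 nt rule are exercised (inserts above
43 nt leave fewer than 7 adapter bases and are dropped as designed).
Substitution and N errors are i.i.d. per base; contaminant reads are random
fragments (16–40 nt) of the screening references. The default abundance
profile puts 47% of endogenous weight on a designated miRNA pair — the
observed dominance of miR-223-3p/miR-451a in plasma — over a log-normal
tail; the tail shape is a modelling choice, as no full abundance
distribution is prescribed. Quality scores are constant: quality realism,
amplification bias and ligation chemistry are not modelled, so passing
tests say nothing about quality-dependent artefacts in real data.

**Cq cohorts** follow
`Cq(s,a) = baseline_a + scale · loading · z + effects + noise` with
per-assay Bernoulli detection, an age effect applied as a Cq shift for the
older half of samples (mirroring the median-split analysis), a sex effect
for female samples, and two reserved columns (`miR-23a`, `miR-451`)
realising a designed haemolysis layout exactly. The default layout
reproduces the profiled cohort's published bin counts (2,179 / 439 / 24 /
9 / 24 / 88 over 2,763 samples). Defaults mirror that cohort: 2,763
samples, 331 + 97 + 43 assays, baselines 13–21 cycles.

The canonical planted-factor condition
(`CohortSimSpec.planted_factors`) uses four orthogonal factors, loading
0.8, 20 assays per factor, 40 pure-noise assays and 2,000 samples, with
baselines in 21–23 cycles and factor scale 1.5. Placing baselines just
below the detection cutoff makes factor swings drive detection itself —
the regime in which the cohort's factors were detection-rate-defined. This
matters numerically: per-sample centering removes ~`loading · 20/120` of
each factor score from every assay, which attenuates the factor-sum
direction of a purely continuous planted structure below the 0.4 membership
cutoff, whereas the detection contrast (score 0 vs 1/2) is immune to
centering. Recovery of ≥90% of loaded assays (and ≥90% of noise assays to
"None") is asserted at this scale in the tests.

**Component panels** plant `up_in_plasma`/`down_in_plasma` shifts of a
configurable effect (default 2 cycles, noise 0.2) for six donors across the
eight blood components.

What the generators do not emulate: sequencing-quality structure, PCR
efficiency differences, plate effects, correlated non-detect mechanisms,
and real inter-assay correlation beyond the planted factors. Tests passing
on this synthetic data validate the pipeline's arithmetic and decision
rules, not its robustness to those real-data features.

## Problem sizes

The test and acceptance runs use 10,000-read cascades, 2,763-sample
cohorts for the haemolysis layout, 2,000 × 120 planted-factor cohorts,
500 × 1,000 null-calibration cohorts and 200 random alignment-oracle
instances — sizes chosen so every property is exercised at full fidelity
while the whole suite completes in seconds on one CPU.
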