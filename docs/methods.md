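# Methods

## The problem

Tumor-derived fragments are a small minority of plasma cell-free DNA
(cfDNA). Site-level average methylation (the β-value) dilutes a rare
tumor-methylated fragment among the many background fragments covering the
same CpG. The read-level α-value — the fraction of methylated CpGs among
all CpG sites covered by one sequenced fragment — does not: a single fully
methylated fragment in an otherwise unmethylated region is visible no
matter how deep the background. alphamark builds the whole workflow around
this statistic: marker regions are scored by how cleanly an α threshold
separates a directional subpopulation of reads between sample groups, and
classification features count those directional reads.

## Unit regions

Regions are the intervals between adjacent MspI cut sites (C|CGG) that are
strictly shorter than 350 bp, mirroring the fragment universe of an
RRBS-style assay. Coordinates are 0-based half-open; the cut coordinate is
`motif_start + 1`, so each region begins `CGG…` and ends `…C`. Regions
spanning a run of ≥10 N bases are dropped (assembly gaps; configurable).
Fragments are assigned to the region containing their midpoint — digested
fragments nest inside regions exactly, and the midpoint stays robust for
WGBS-like reads straddling a boundary. CCGG is its own reverse complement,
so a plus-strand scan finds every site.

## Read model and α-values

The canonical input is one TSV row per deduplicated fragment (mate pairs
merged upstream): `sample_id, chrom, start, end, n_cpg_meth, n_cpg_total`.
α = `n_cpg_meth / n_cpg_total`. Reads covering fewer than `min_cpg` CpGs
(default 3) are excluded from α analyses: with 1–2 CpGs, α is quasi-binary
noise and inflates both tails of the distribution. The floor is
configurable; all exclusions are tallied so that included +
excluded-by-floor + outside-region always equals the parsed total.

## Marker discovery

For a region and a candidate threshold t, a *hypermethylated read* has
α ≥ t and a *hypomethylated read* has α ≤ t. For each tumor/normal pair,
the 2×2 table (directional vs non-directional reads in tumor and normal)
is scored with a one-sided Fisher exact test (tumor enriched), computed as
the hypergeometric upper tail. The learned threshold α_hyper (or α_hypo)
is the grid point (default grid 0, 0.05, …, 1) maximizing the number of
significant pairs at p < 0.05, ties broken toward the more extreme
threshold (largest for hyper, smallest for hypo). The number of supporting
pairs measures marker stability; a region qualifies when at least
`support_frac` (default 2/3) of pairs support it.

The exact objective is this package's operationalization of "a
well-separated α-distribution component": it is deliberately
non-parametric (counts, not distribution fits), pair-respecting (each
patient's tumor is compared to their own adjacent normal, removing
age/individual effects), and threshold-adaptive per region.

Unpaired contrasts (tumor type vs tumor type, normal tissue vs normal
tissue) reuse the paired machinery via seeded random pseudo-pairings;
support counts are averaged over R = 5 matchings before threshold
selection. Both ordered directions of a contrast are emitted (A-enriched
and B-enriched are distinct markers).

Cancer-specific candidates must additionally be clean in a reference panel
of noncancer plasma: at the candidate's threshold, at least
`min_pass_frac` (default 0.9) of reference samples must have a directional
read fraction ≤ `max_frac` (default 0.05). A reference sample with no
reads in the region is trivially clean. Because the reference panel is
re-drawn per validation run, panels legitimately differ slightly across
runs and are re-derived inside each run.

Selection is rank-based (support desc, then mean directional-fraction
difference desc) with a `top_m` cap per contrast (default 2000); merging
across contrasts collapses duplicate regions keeping the best-ranked
instance and its threshold. No multiplicity correction is applied by
default — ranking, not error control, drives panel composition — but an
optional Benjamini–Hochberg mode (`fdr_q`) filters candidates by a pooled
per-region Fisher p.

Four panels result: cancer-specific hyper/hypo (tumor vs adjacent normal
for detection; pairwise tumor-type contrasts for tissue of origin) and
tissue-specific hyper/hypo (pairwise normal-tissue contrasts, no reference
filtration).

## Profiles

For each marker, the sample's directional read count at that marker's own
learned threshold is normalized by sequencing depth and log-transformed:

    value = ln(1e9 · count / raw_total + 1)

where `raw_total` is the sample's total mapped deduplicated fragment count
(taken from the metadata, not recomputed). The value is 0 exactly when the
count is 0, strictly increasing in the count, and invariant under joint
rescaling of count and depth. Values over a panel, in panel order, form
one feature profile; each profile records a hash of its panel so that
train/test mismatches fail loudly.

## Stacked ensemble

Level 1: one linear SVM (L2 penalty, C = 1, per-feature standardization
fitted on training data) per marker type — profiles have very different
scales across markers, so standardization is required for a margin
classifier. Level 2: a 2000-tree random forest over the concatenated
level-1 decision scores. For tissue-of-origin both levels are one-vs-rest,
and level 1 contributes one score per class per view.

The level-2 forest is trained on *cross-fitted* level-1 outputs
(stratified k = 5 out-of-fold scores; folds shrink with a warning when a
class is rarer than k): each training sample's level-1 score comes from a
model that never saw it, so the forest calibrates against honest scores
rather than level-1 training optimism.

Detection outputs the forest's cancer probability; thresholding is the
evaluator's job. TOO outputs per-class membership probabilities
(renormalized to sum to 1); the call is the top class only when the fold
change between the top two probabilities reaches 2.5 (a top-2 tie gives
confidence 1, hence no call; a runner-up probability of 0 gives +∞).

All fits are seeded; identical seeds and inputs reproduce identical models
and predictions.

## Validation protocol

Per run: 25% of cancer and 25% of noncancer plasma are held out for
testing (counts round half-up, which reproduces the canonical 48-test-
noncancer arithmetic where one false positive is 97.9% specificity); 30
noncancer samples from the remaining 75% are reserved solely for marker
filtration; the rest train. Ten runs by default; metrics are summarized as
the mean with an empirical 2.5/97.5-percentile 95% interval
(switchable to mean ± 1.96·sd).

Sensitivity at n false positives is the ROC operating point whose
threshold sits just above the (n+1)-th highest negative score; under ties
among negatives at the cut the threshold rises above the tie (fewer false
positives than allowed, reported as achieved). TOO accuracy is computed
over called samples only; per-type precision follows
`correct-as-type / predicted-as-type`; confusion matrices are accumulated
across runs. Per-stage/per-type sensitivities are reported only when the
average number of test patients in the stratum across runs is ≥4.

## Synthetic methylomes

The generator emulates the *structure* the method assumes, not the human
genome. A toy reference is constructed so its MspI digest is exactly a
chosen set of regions with chosen CpG counts. Per-class regional
methylation levels start from a common uniform(0.05, 0.95) baseline;
planted DMRs shift one set of classes by Δ (default 0.6, kept within
[0, 1]): pan-cancer DMRs (all tumor classes; the detection signal),
tumor-type-specific DMRs (the TOO signal), and tissue-specific DMRs (a
tissue's normal *and* tumor classes; the tissue signal).

Reads carry molecule-level heterogeneity: a fragment's methylation
propensity is m* ~ Beta(mκ, (1−m)κ) around the class level m (degenerate
at m ∈ {0, 1}), and its methylated-CpG count is Binomial(n_cpg, m*). The
concentration κ (default 5) keeps α-distributions bimodal/overdispersed —
the regime read-level discovery exploits; κ → ∞ recovers a pure binomial.

Plasma is a read mixture: each fragment is tumor-derived with probability
equal to the tumor fraction f, otherwise drawn from a liver-weighted blend
of the normal-tissue methylomes (the cfDNA background). Tumor *tissue*
samples are themselves impure mixtures at purity 0.7 — the reason
read-level discovery is needed at all. Fragments span their whole region
(digested-fragment behavior), at fixed depth per region (default 30).

Default cohort: 4 cancer types × 20 tumor/adjacent pairs, 8 normal
tissues per type, 15 cancer plasma per type at f = 0.1, 60 noncancer
plasma (enough to reserve 30 per run), 200 regions. These sizes keep the
full 10-run protocol to a few minutes on one core while leaving every
contrast with enough samples to be meaningful.

What passing on this generator does **not** show: robustness to batch
effects, age structure, coverage non-uniformity, bisulfite conversion
failure, fragment-length biology, or realistic genome-scale marker
multiplicity. It shows that the statistics recover exactly the planted
signal, that the null behaves, and that the pipeline's plumbing (per-run
panel re-derivation, panel hashing, seeding) is airtight.

## Numerical choices and degenerate inputs

- Fisher p-values are exact hypergeometric tails (vectorized over the
  threshold grid and pairs); a pair with an empty side contributes the
  uninformative p = 1.
- A sample with no reads in a region contributes an empty distribution
  (count 0, fraction treated as missing in effect-size averaging).
- `profile_value` rejects non-positive depth; counts are validated
  non-negative.
- Threshold grid endpoints are included, so the directional count at the
  extreme threshold equals the total read count.
- Split counts use round-half-up; reserve size and test fraction are
  configurable with protocol defaults of 30 and 0.25.
- All randomness flows from explicit seeds via `numpy.random.default_rng`
  / `SeedSequence`; re-runs are byte-identical.

## Known limitations

- The threshold-selection objective is a stated operationalization; other
  separation scores (e.g. distributional distances) may rank borderline
  regions differently.
- Pseudo-pairing for unpaired contrasts trades a little power for reuse of
  the paired test; with very unequal group sizes only `min(|A|, |B|)`
  samples are used per matching.
- The level-2 forest is platform-bound (absolute branching cutoffs on
  level-1 scores); transferring it across assay platforms is out of scope,
  though a linear level-2 could be swapped in.
- TOO calls on small desk-scale cohorts abstain often at confidence 2.5;
  accuracy is defined over called samples, so the no-call fraction must be
  read alongside it.
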