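# Methods

## Model

`cnaburden` treats a tumor sample as a set of non-overlapping copy-number
segments per chromosome, each carrying a mean log2 ratio of observed to
diploid copy number, and summarizes the sample's alteration landscape with
weighted event counts. Three modelling ingredients drive everything else.

**Purity admixture.** A segment at true tumor copy ratio `2^N` observed in a
sample with tumor-cell fraction `r` is measured at
`2^n = r·2^N + (1 − r)`. The baseline correction inverts this:
`N = log2((2^n + r − 1) / r)`. The inversion is the identity at `r = 1`,
amplifies gains and deepens losses as purity falls, and is undefined when
the admixture argument is non-positive (a loss too deep to be clonal at
that purity); such values, and any value below it, are assigned the cap
`log2(0.2) ≈ −2.3219` — the log2 ratio of a heterozygous deletion observed
at the minimal accepted purity of 40% (purities below 0.4 are raised to
0.4 before correction). The cap is stored at full precision and displayed
rounded to −2.32.

**Amplitude levels.** Calling thresholds are log2 ratios of copy-number
landmarks on a diploid background, compared inclusively at the boundary:

| threshold (log2) | level            | ≈ copies | weight A |
|---|---|---|---|
| ≥ 1      | high-level gain   | ≥ 4      | 3 |
| ≥ 0.58   | medium-level gain | 3–4      | 2 |
| ≥ 0.2    | low-level gain    | ≥ 2.3    | 1 |
| ≤ −0.2   | low-level loss    | ≤ 1.7    | 1 |
| ≤ −1     | medium-level loss | 0.6–1    | 2 |
| ≤ −1.74  | high-level loss   | ≤ 0.6    | 3 |

A near-neutral segment (|log2| < 0.2) with B-allele-frequency deviation
≥ 0.25 is called copy-neutral LOH with weight 2. BAF is interpreted as
deviation from the heterozygous 0.5 band; raw frequencies in (0.5, 1] are
folded via |b − 0.5| when detected. CN-LOH events contribute to BCS or FCS
according to their scope, like any other weighted event.

**Scope.** A segment covering ≥ 90% of its chromosome (centromere-gap base
pairs excluded from both numerator and denominator) is *chromosomal*; one
covering ≥ 50% of its dominant arm is *arm-level*; anything smaller is
*focal*. The dominant arm is the one holding more covered bp (ties go to p).
BCS sums weights over chromosomal + arm-level events; FCS sums `A·L` over
focal events with the coverage score L = 1/2/3/4 for arm fractions
≤ 5% / ≤ 15% / ≤ 30% / > 30%. GCS is the sum of the cohort z-scores of BCS
and FCS using the sample (n−1) standard deviation; it is cohort-relative by
construction and no single-sample GCS is defined. Altered-genome fractions
divide summed lengths (`end − start + 1`) of non-neutral segments by the
genome length (sum of chromosomes 1–22, X, Y of the active build).

## Re-segmentation

Re-segmentation (optional, on by default) iterates three steps to a
fixpoint: (1) segments with |log2| < 0.16 are set to exactly 0 — done first
so runs of near-neutral segments coalesce into single neutral segments,
which are retained because they carry CN-LOH information through BAF;
(2) adjacent same-chromosome segments separated by ≤ 1 Mb whose log2 ratios
differ by ≤ 0.16 (and BAF deviations by ≤ 0.1 when both are known) merge
with length-weighted means, the merged span absorbing the gap; (3) segments
shorter than 100 kb are absorbed into the neighbor (within the merge gap)
with the smaller amplitude difference — ties to the left — or dropped when
no neighbor qualifies. Iterating to a fixpoint, rather than a single
left-to-right pass, makes the operation idempotent and order-insensitive;
the iteration terminates because every step either reduces the segment
count or zeroes a value. All five thresholds are exposed as parameters and
CLI flags.

## Genomic windows and profiles

Windows tile the non-centromeric genome at arm, half-arm (arms split at
their arithmetic midpoint — no biological split point is canonical),
major-cytoband, sub-cytoband, or fixed 40/30/20/10/5/1 Mb resolution (fixed
tiles start at the arm start; the last tile truncates). The window mean is
`W(i) = Σ_t S_t·l_t / L(i)` over segments t overlapping window i; dividing
by the full window length means uncovered base pairs contribute zero, so
sparse-coverage input dilutes toward neutral — a deliberate property of the
formula that users of targeted panels should be aware of. Gain/loss states
use inclusive cutoffs at ±0.2 by default. Group-level profiles are
unweighted means across the samples of a group. Sample/group correlation
uses Pearson, Spearman or Kendall; zero-variance profiles produce undefined
(NaN) correlations rather than errors, imputed to 0 (with a warning) before
clustering. Clustering is agglomerative with complete linkage on distance
1 − correlation; outputs are the linkage, the leaf order for heatmap
reordering, and a Newick serialization. Rendering itself is out of scope.

## Group statistics

Associations between scores and annotations dispatch on variable type:
two-level categorical → t-test + Wilcoxon rank-sum; >2 levels → one-way
ANOVA + Kruskal-Wallis; numeric → Pearson + Spearman. Levels with fewer
than 2 samples are dropped with a warning. Differential-region tests run
per window and, with more than two groups, per group pair, with
Benjamini-Hochberg adjustment across windows within each pair (adjusting
within pair keeps each pairwise family self-contained). The t-test is
Welch by default — the pooled-variance variant is a flag — because group
variances of window means are rarely equal in practice. A window constant
in both groups gets p = 1 when the constants are equal and p = 0 when they
differ (a constant separation is maximal evidence, not a degenerate null).
The default significance level is 0.1.

The Fisher mode tests the groups × {gain, loss, neutral} table. Because no
installed routine offers an exact r×c test, the package enumerates all
tables with the observed margins and sums the conditional multivariate
hypergeometric probabilities not exceeding the observed one (two-sided);
empty rows/columns are collapsed first. Enumeration is used for tables with
total count ≤ 200; larger tables fall back to a seeded Monte Carlo
permutation estimate with the add-one correction (hits+1)/(draws+1).

Survival uses product-limit (Kaplan-Meier) estimates per group and the
multivariate log-rank test; numeric grouping variables are split at the
median by default. When any group has no observed events the test is
skipped with a warning and curves are still returned.

## Classifier protocol

The classifier trains a random forest (500 trees by default, scikit-learn
defaults otherwise, hyperparameters exposed) 50 times. Each iteration draws
P samples per group without replacement — P = floor(N/G), falling back to
floor(0.75·n) when floor(N/G) would exhaust the smallest group of size n —
trains on the union of draws and predicts every held-out sample. The
balanced per-group draw with the 75% fallback reconciles a balanced
training design with an overall ~75/25 split. Cohorts need ≥ 20 samples
and the final P must exceed 1. Categorical classifier features with at
least as many levels as there are groups are rejected (they would encode
the grouping trivially); numeric features are always accepted. Iterations
derive independent sub-seeds from the run seed (`numpy` SeedSequence
spawning), so reports are bit-reproducible. Reported metrics: per-iteration
and mean accuracy, per-group sensitivity/specificity (means over
iterations; with constant per-iteration held-out sizes these equal the
values recomputed from the aggregate confusion matrix), the aggregate
confusion matrix, and each sample's prediction rate over the iterations
that held it out.

## Synthetic cohorts

The generator emulates the statistical structure the scores assume: broad
events occupying whole arms (occasionally whole chromosomes, probability
0.15 per broad event), focal events with log-normal lengths (median ≈ 4 Mb,
log-sd 0.7, clipped to < 45% of the arm), true log2 ratios at the midpoints
of the amplitude bands, level probabilities defaulting to
0.30/0.15/0.05 for low/medium/high gains and the same for losses, uniform
purity in [0.6, 1.0] diluting the observed ratios through the exact inverse
of the purity correction (so round-trip identities are available as test
oracles), Gaussian amplitude noise (sd 0.05 by default), and optional
CN-LOH arms (log2 ≈ 0, BAF deviation 0.35). Event loads are graded: each
sample's expected broad and focal counts are drawn uniformly from
[0, 2 × rate] (defaults 2 broad, 3 focal per sample on average), giving
cohorts that span quiet to highly rearranged genomes. Events keep 1.2 Mb
clearance from one another so re-segmentation never merges distinct true
events; when a sample's genome genuinely cannot hold another focal event
the sample simply keeps the events placed so far. Ground truth records
every event's scope, level, weight and arm fraction, so expected BCS/FCS
are computable without the segment pipeline.

The generator does **not** model platform noise spectra, genomic waviness,
GC bias, subclonality, or overlapping/nested events. Passing tests
therefore demonstrate the correctness of the scoring arithmetic and the
stability of the pipeline under clean admixture + Gaussian noise — not
robustness to real-platform artifacts.

A 3-chromosome toy genome (100/80/60 Mb, centromeres at 40%/50%/50% with
3 Mb gaps) is bundled for fast tests; the real builds work the same way.

## Reference data

Chromosome lengths for hg19/hg38 are the exact public assembly constants.
The bundled cytogenetic band tables are **synthetic**: centromere positions
are approximate and the banding pattern (≈ 10 Mb major bands, sub-bands
above 4 Mb, names counting outward from the centromere) is generated
deterministically by `scripts/make_reference_tables.py`. They give the
windowing machinery a structurally valid scaffold — arms partition each
chromosome minus the centromere gap, bands are sorted and non-overlapping —
but band-window identifiers must not be interpreted as real Giemsa bands.
Users with a real cytoBand.txt can load it via
`cnaburden.genome.from_cytobands`.

## Numerical choices and problem sizes

Coordinates are 1-based inclusive throughout (the convention of
segmentation outputs); interval arithmetic uses `end − start + 1` lengths.
Threshold comparisons are inclusive at every printed boundary. Normalized
scores use the n−1 standard deviation; degenerate cohorts (zero variance)
get zeros plus a warning rather than NaNs. Mitochondrial contigs are
rejected with a warning; X and Y are scored. Test and acceptance runs use
the toy genome with 40–500-sample cohorts, a 1,000-sample scoring-oracle
comparison, 1,000 null windows for t-test calibration, exhaustive 2×2
Fisher enumeration with row margins ≤ 15, and 50-iteration classifier runs
on 60–120 samples — sizes chosen so the full suite completes in a few
minutes on one CPU while keeping every estimate's Monte Carlo error well
inside the asserted tolerances.

## Known limitations

GCS depends on the cohort in which it is computed; scores from different
cohorts are not directly comparable on the GCS scale. The exact Fisher
enumeration grows quickly beyond 2×3 tables (hence the Monte Carlo
fallback). Ploidy is carried as an annotation only — there is no ploidy
re-centering, no subclonal deconvolution and no allele-specific copy
number. Per-gene peak detection (GISTIC-style) is out of scope.
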