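# Methods

This note documents the statistical models behind `sticomics`, the defaults
that matter, and the design decisions taken where more than one reasonable
choice existed. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Statistical primitives (`sticomics.stats`)

**Benjamini–Hochberg.** `bh_adjust` implements the standard step-up
procedure: with sorted p-values p(1) ≤ … ≤ p(m), q(i) = min over j ≥ i of
min(m·p(j)/j, 1). The literature sometimes labels the procedure "step down";
the step-up form is the one with the FDR guarantee and is what is
implemented, verified against a brute-force transcription of the defining
formula and against statsmodels.

**Clopper–Pearson.** Exact two-sided binomial interval from beta quantiles:
lower = B(α/2; s, n−s+1), upper = B(1−α/2; s+1, n−s), with the conventions
lower = 0 at s = 0 and upper = 1 at s = n. Quantiles come from
`scipy.special.betaincinv`; the procedure itself is implemented here and its
conservatism (empirical coverage ≥ nominal) is verified by simulation.

**Fisher's exact test.** r×c tables are tested by full Freeman–Halton
enumeration: every table with the observed margins is generated recursively
and the probabilities of tables no more probable than the observed one
(tolerance 1e−9 relative, to absorb float jitter) are summed. All-zero rows
and columns are dropped first. Tables with total count above an explicit cap
(default 500) raise an error rather than falling back to an asymptotic
approximation — study-scale tables (≈96 samples) are comfortably below the
cap, and exactness is what makes the routine testable against independent
enumeration.

**Spearman correlation.** Pearson correlation of average ranks (mean rank
for ties); constant-after-ranking input is an error rather than a NaN.

**Two-sample t.** Welch (default for data comparisons) and pooled variants.
When the standard-error denominator is zero — a gene constant within both
groups — the convention t = 0, p = 1 applies even if the group means differ
(reachable only with zero within-group variance); this keeps constant genes
in the result table as never-significant rows instead of dropping them and
changing the multiplicity burden.

## Normalization (`sticomics.preprocess`)

Size factors are median-of-ratios: reference genes are those with positive
counts in all samples; factor_j = median_g count_gj / geomean_g(count),
taken in linear space, then rescaled to geometric mean 1. A matrix with no
all-positive gene raises an error suggesting filtering or a pseudocount.
Low-abundance miRNA-like panels use total-count scaling instead
(`total_count_factors`), a deliberate stand-in for panel-specific
normalization, because the median-of-ratios reference set is unstable when
most features contain zeros.

The log transform is log2(count/factor + 1); pseudocount 1 keeps zeros at
exactly zero. Variable-gene selection requires log-scale input (variance
ranking on raw counts is scale-confounded), ranks by sample variance with
ties broken lexicographically by gene id, and defaults to k = 1500 for mRNA
and k = 200 for miRNA in the run configuration — the "most variable" count
is not canonical, so it is always recorded in output metadata.

Ward clustering uses `scipy.cluster.hierarchy` with Euclidean distance, or
1 − Pearson correlation; Ward's variance-minimizing update on a
non-Euclidean dissimilarity is accepted, as in common practice, and flagged
here rather than hidden.

## Class comparison (`sticomics.de`)

`GroupComparison(matrix, groups).fit()` runs a per-gene two-sample t test
and BH adjustment over all genes. Plain (unmoderated) tests are used
deliberately: the power analysis that justifies the design assumes plain
t-tests, so the package's calibration claims are internally consistent. An
empirical-Bayes moderated test would behave differently at this sample size
mostly for low-variance genes; that difference is out of scope and is the
main reason gene-level counts from this package are not comparable
one-for-one with moderated-pipeline counts on real data. Significance
thresholds are strict inequalities (p < 0.01, q < 0.10).

## Subtype classifier (`sticomics.subtype`)

Prototypes are per-gene arithmetic means over each subtype's reference
samples, restricted to the signature genes, on the log-normalized scale. The
assignment rule, exactly: candidates are subtypes with correlation strictly
above the floor (0.2); zero candidates → UNASSIGNED; one → assigned; two or
more → assigned to the maximum only if max ≥ ratio (1.5) × second-max. An
exact tie at the maximum therefore abstains (the ratio test cannot pass for
positive correlations), and ties at the floor are excluded by strictness.
Raising either threshold can only shrink the assigned set — this monotone
abstention property is tested against a brute-force rule oracle.

Correlation is Pearson by default (conventional for centroid classifiers on
log expression), Spearman selectable; the choice is recorded in the model.
The signature gene list is data, not code: it is supplied as a gene-list
file, and the synthetic generator fabricates a stand-in signature (four
disjoint 100-gene blocks).

## Tissue of origin (`sticomics.origin`)

Each tissue is compared one-vs-rest with Welch t tests on log-normalized
pools; genes are ranked by ascending p, then descending |mean difference|,
then gene id (the ranking rule is recorded in the signature metadata since
"most differentially expressed" admits variants). The top 50 per tissue are
combined into a deduplicated union (≤ 150 genes); prototypes are per-tissue
mean profiles over that union. Tumors are Spearman-matched to the
prototypes; the default is correlate-with-the-average-profile, with
correlate-with-each-pool-then-average available as
`match(..., method="average_correlation")` — the two agree on calls in
practice and the averaged-profile reading is the deterministic primary.
Argmax ties break by the fixed priority FT > OSE > PER with a warning; ties
are measure-zero on continuous data but the tie-break must be deterministic.

The summary reports mean correlation per tissue, best-match call counts, and
the proportion of tumors better correlated with FT than with ovarian tissue
together with its exact binomial interval.

## Copy number (`sticomics.scna`)

Region discovery is an input, not a computation: the frequency comparison
operates on a given set of focal regions (from a file or the generator).
Region value = length-weighted mean log2 ratio of overlapping segments;
calls: ≥ +1.0 → +2 ("2+ fold amplification"), ≤ −1.0 → −2 (a purity-naive
proxy for homozygous deletion — real tumors with stromal admixture attenuate
log ratios, so the cut is configurable), |value| ≥ 0.3 → single-copy call,
else 0. Uncovered regions are called 0 with a warning. SEG files are read as
1-based inclusive and held 0-based half-open internally; writers convert
back. Fraction of genome altered = bases in segments meeting a deep cut,
over total covered bases, per sample.

The group comparison tests, per region, altered (call ±2 by default) versus
not in a 2×2 Fisher exact test, BH-corrected across regions. A region
altered in no sample gets p = 1 and a flag. The choice of Fisher + BH is the
package's explicit, documented reading of "no region over-represented in
either group"; no specific test is canonical for this step.

## Power simulation (`sticomics.power`)

Genes are simulated as independent unit-variance Gaussians — the implicit
model of a t-test power study; correlation between genes would inflate the
variance of the realized FDR but not the mean sensitivity, and is out of
scope. Per replicate: n_de of m genes are shifted by the effect size in
group 1, pooled-variance t tests and BH at the configured FDR are applied,
and sensitivity (fraction of true genes with q below the level) plus the
realized false-discovery proportion are recorded. Cells report the mean over
replicates with the standard error taken across replicates (not pooled
counts). The pooled t is the simulation default so that its 2n−2 degrees of
freedom match the oracle.

The analytic oracle solves alpha\* = fdr · R(alpha\*)/m, with R(alpha) =
n_de·power(alpha) + (m−n_de)·alpha and power(alpha) the two-sided rejection
probability of a noncentral t (df = 2n−2, noncentrality effect·√(n/2)).
The fixed-point iteration is Aitken-accelerated because the plain map
contracts at rate ≈ fdr·(1−n_de/m), which is slow for FDR levels near 1;
scipy's noncentral-t CDF can underflow to NaN deep in the lower tail, where
the term is treated as zero. Defaults: m = 20,000 genes, n_de = 50, effects
{0.75, 1.0, 1.25, 1.5} s.d., 40–50 per group, FDR 0.10, 20 replicates for
test-scale runs (200 is documentation grade).

## Synthetic cohorts (`sticomics.simulate`)

**Counts.** All expression counts are negative binomial (gamma–Poisson) with
mean libsize_j · 2^(μ_g + effects) and dispersion 1/size; μ_g ~ N(6, 1.5²)
on the log2 scale for mRNA (median mean count ≈ 64), dispersion 0.05 for
tumor mRNA, 0.02 for normal pools, 0.3 for miRNA. Library sizes are
log-normal with log-sd 0.3, so size-factor normalization is exercised
non-trivially. Effects are additive shifts on the log2 mean in units of the
within-group biological s.d. (`bio_sd`, default 1.0 log2); the realized
shift of log-normalized values equals the nominal shift, while the per-gene
total s.d. also includes counting noise, so effects measured against total
s.d. are somewhat smaller than nominal — the effect-injection test
quantifies the nominal scale.

**Tumor cohort.** 48 STIC + 47 non-STIC samples, 20,000 genes; each sample
draws a latent subtype uniformly from four; subtype prototypes shift four
disjoint 100-gene blocks by `subtype_sep`·bio_sd (default separation 3, the
regime in which the classifier demonstrably recovers the latent structure;
at separation 1 the abstention rule correctly refuses nearly everything,
because the shared baseline keeps second-best correlations high). Group
labels are assigned independently of expression, so `n_de_genes = 0`
(the default) is an exact global null — the study's design point.

**Normal pools.** Three pools per tissue by default (the real pool count is
not canonical; it is a configuration default, not a claim). Marker sets are
disjoint by construction: 4000 FT-specific genes versus 300 each for OSE and
PER, shifted by `marker_shift_sd` × pool s.d. (default 3 × 0.3 = 0.9 log2)
with random sign. OSE and PER share an extra mesothelial profile component
(log2 s.d. 0.5), making the two mesothelial tissues cluster together before
FT. FT and OSE profiles additionally exchange a 10% linear-scale admixture,
reflecting the documented ≲10% cross-contamination of those brushings; this
admixture is what makes peritoneum the systematically poorest match for
FT-derived tumors. With three pools per tissue, one-vs-rest BH-significant
counts are dominated by the FT contrast (the 300-marker tissues have little
small-sample power, and BH's rank dependence amplifies the asymmetry) —
a qualitative, not quantitative, emulation of the real tissue-DE asymmetry.

**What the generator does not emulate.** Sequencing reads, array
intensities, batch effects (none were found worth correcting in the
motivating study, and none are simulated), gene–gene correlation, tumor
purity variation, and panel-specific miRNA normalization artifacts. Passing
tests therefore demonstrate correctness and calibration of the *analysis*
under the stated generative model, not robustness to those real-data
complications.

**Copy-number generator.** Each of 82 focal regions (one per two megabases
of a toy chromosome) is an amplification or deletion region with random
sign; samples carry the deep (±2) event with the baseline frequency
(default 0.2), plus `group_delta` in the STIC group (0 under the null).
Single-copy (±1) events sit behind `shallow_freq`, default 0, so a zero
baseline yields an exactly all-zero call matrix. `segments_from_calls`
renders calls back to segments (±2 → log2 ∓/±1.5, ±1 → ±0.5) for SEG output
and round-trip testing of the caller.

## Numerical and interface conventions

Seeds: every generator and simulation takes an explicit seed (default 17);
CLI entry points require or echo it; identical config + seed is
bit-reproducible. The pipeline summary (`summary.json`) contains the seed
and the fully resolved parameter set and no timestamps, so repeated runs are
byte-identical; the output directory is recorded in the log only. Matrices
are genes × samples TSV; segments SEG (1-based inclusive on disk); regions
BED-like TSV (0-based half-open); configs YAML; summaries JSON. Gene
identifiers are opaque strings throughout — no annotation lookups.

## Known limitations

Unmoderated t statistics differ from the moderated pipelines typically used
on real cohorts; real-data gene counts (e.g. how many genes pass p < 0.01 on
a particular cohort) are therefore not reproduction targets, only their
calibration behavior is. Fisher's exact test is limited to the enumeration
cap by design. The tissue signature depends on the pool replicate count and
ranking rule; both are recorded in metadata. The copy-number caller is
purity-naive. Survival analysis, pathway analysis, segmentation and focal
region discovery are intentionally outside the package.
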