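# sticomics

Comparative molecular analysis of high-grade serous carcinoma (HGSC) with and
without serous tubal intra-epithelial carcinoma (STIC) lesions.

## The scientific problem

Most advanced pelvic HGSCs are thought to arise in the distal fallopian tube,
where STIC lesions are the putative precursor — yet STICs are found in only
about half of cases. If tumors with and without an identifiable STIC arose
from different tissues, their molecular profiles should differ; if they share
an origin, a well-powered comparison should come up empty. This package
implements the computational machinery for that question, for analysts who
want to run, test or re-examine each stage on data with a known ground truth:

* **Class comparison** — per-gene two-sample *t* tests (Welch or pooled)
  between STIC and non-STIC tumors with Benjamini–Hochberg control at
  FDR = 0.10. The scientifically interesting outcome is *negative*: genes
  pass raw p < 0.01 at roughly the chance rate and none survive correction.
* **Expression subtyping** — a nearest-centroid classifier over a signature
  gene set. Sample profile *x* is correlated with each subtype prototype
  (per-gene mean over that subtype's reference samples); the call is made
  only when a single clear best match exists: r(max) > 0.2, and when several
  subtypes pass the floor, r(max) ≥ 1.5 · r(second). Otherwise the sample is
  UNASSIGNED.
* **Tissue of origin** — one-vs-rest differential expression among normal
  fallopian tube (FT), ovarian surface epithelium (OSE) and peritoneal (PER)
  pools; the top 50 genes per tissue are combined into a signature; each
  tumor is Spearman-matched to the per-tissue prototype profiles and called
  for its best correlate. The headline summary is the fraction of tumors
  better correlated with FT than with ovarian tissue, with an exact
  (Clopper–Pearson) binomial confidence interval.
* **Copy-number comparison** — segment log2 ratios are summarized over focal
  regions into calls in {−2, −1, 0, +1, +2} (deep thresholds |log2| ≥ 1);
  per-region alteration frequencies are compared between groups with
  Fisher's exact test (full Freeman–Halton enumeration) and BH correction.
* **Power by simulation** — the design calculation: with 50 of 20,000 genes
  shifted by 0.75–1.5 s.d. and 40–50 samples per group, what fraction of the
  true genes is detected at FDR 0.10? A closed-form fixed-point oracle
  (alpha\* = fdr · R(alpha\*)/m with noncentral-*t* power) cross-checks the
  Monte Carlo.

Because the original cohort is controlled-access, a first-class synthetic
generator (`sticomics.simulate`) produces every input with the study's
statistical structure — negative-binomial counts on a log-normal mean field,
four latent subtypes, a 48+47 two-group design with no true group effect
under the null, marker-asymmetric normal tissues, low-abundance miRNA-like
panels and region-level copy-number calls — so every stage is testable
end-to-end with known ground truth.

## Worked example

```python
import pandas as pd
import sticomics as s
from sticomics.preprocess import log_normalize, size_factors

# a null cohort: 48 STIC + 47 non-STIC tumors, 20,000 genes, no group effect
cohort = s.generate_tumor_expression(s.CohortConfig(seed=17))
logn = log_normalize(cohort.matrix, size_factors(cohort.matrix))
print(s.GroupComparison(logn).fit().summary())

# subtype assignment against in-cohort prototypes
clf = s.SubtypeClassifier.from_reference(logn, cohort.subtypes, cohort.signature_genes)
print(clf.assign_cohort(logn).summary())

# tissue-of-origin matching of tumors drawn 88:12 from FT and ovarian profiles
normals = s.generate_normal_pools(s.NormalPoolConfig(seed=17))
nlog = log_normalize(normals.matrix, size_factors(normals.matrix))
model = s.TissueOriginModel(nlog).fit()
lab = normals.tissues
proto = pd.DataFrame({t: nlog.values.loc[:, (lab == t).to_numpy()].mean(axis=1)
                      for t in ("FT", "OSE", "PER")})
tumors = s.generate_tumors_from_tissue(
    proto, {"FT": 0.88, "OSE": 0.12, "PER": 0.0}, n_tumors=85, noise_sd=0.5, seed=18)
print(model.match(tumors).summary())
```

prints

```
Two-group class comparison
  groups: STIC (n=48) vs NOSTIC (n=47); welch t test
  genes tested: 20000
  genes with raw p < 0.01: 192
  genes significant at BH FDR 10%: 0

Subtype assignment (prototype correlation, floor 0.2, ratio 1.5)
  samples classified: 95
  S1: 25
  S2: 27
  S3: 21
  S4: 22
  UNASSIGNED: 0

Tissue-of-origin matching (Spearman, combined marker signature)
  tumors: 85
  mean correlation: FT 0.91, OSE 0.71, PER 0.63
  best-match calls: FT 75, OSE 10, PER 0
  better correlated with FT than ovarian tissue: 75/85 (88%, 95% CI (79-94%))
```

Reading the output: under the global null, about 1% of genes clear the raw
p < 0.01 bar (192/20,000 here) and *none* survive BH correction — the
negative result the design was powered for. The classifier recovers all four
latent subtypes with no abstentions at this separation. In the origin stage,
75 of 85 tumors correlate best with fallopian tube, and the exact binomial
interval for the FT-better-than-ovary proportion is (79%, 94%).

A command-line interface mirrors the stages (`sticomics simulate`,
`normalize`, `de`, `subtype`, `origin`, `scna`, `power`, `all`); every
subcommand reads and writes plain files and echoes its seed.

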