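# Methods

## Cohort model and stratification

A cohort is a set of patients with paired (baseline, post-supplementation)
measurements of plasma homocysteine (HCY, µmol/L), serum folate (nmol/L)
and cell-free DNA (cfDNA, ng/mL plasma). Stratification is purely the sign
of the HCY change: strictly decreased → *responder*; unchanged or
increased → *non-responder*. Ties are non-responders by definition, since
"unchanged" belongs to the non-response phenotype; no tolerance band is
applied around zero. Patients missing either HCY timepoint are excluded
from group analyses (pairwise deletion per analysis, not listwise).

Paired comparisons are gated on a Shapiro–Wilk test of the paired
*differences* (the quantity whose normality the paired *t*-test actually
assumes): normality p ≥ α → paired *t*; otherwise Wilcoxon matched-pairs
signed-rank. α defaults to 0.05 everywhere. If all differences are zero
the comparison is degenerate and reported with p = 1 and a warning.
Correlations written as plain *r* are Pearson; Spearman is used where rank
correlation is requested (the burden association). Group summaries are
mean ± sample SD (n − 1).

## LINE-1 methylation

Each sample fraction (cfDNA, granulocyte, mononuclear) carries methylation
percentages at three LINE-1 CpG positions per timepoint; the per-sample
summary is their arithmetic mean, kept at full precision internally and
rounded to one decimal only in report tables. Group-level change is the
mean of per-patient relative changes `100·(post − baseline)/baseline`
computed on the averages — not the relative change of group means; with
skewed or noisy baselines the two differ, which is why a cohort can show a
mean-of-ratios change (≈ +1.9 %) that is not the ratio of its printed
means. Per-CpG and average comparisons are both produced; the three CpG
tests are deliberately not multiplicity-adjusted by default; an optional
Holm flag adjusts the per-CpG p-values within each fraction.

## Epigenetic clock

The clock is a penalized linear model of transformed chronological age on
beta values at a fixed whitelist of CpG sites (the "filtered" multi-tissue
design: only CpGs shared across array platforms are eligible; the shipped
default whitelist is synthetic and user-replaceable). The age transform is

    F(a) = log((a+1)/(A+1))   for a ≤ A,    (a − A)/(A+1)  for a > A,

with adult-age constant A = 20 years (configurable); its exact inverse maps
predictions back to years. `F` is continuous and strictly increasing, and
the round-trip is identity to < 1e-9 over [0, 120].

Training uses elastic net (mixing parameter `l1_ratio` = 0.5 by default)
with the penalty strength chosen by seeded k-fold cross-validation (k = 10)
over a descending geometric alpha ladder. If CV selects the smallest alpha
of the ladder, the grid is extended downward and refit (up to five rounds):
near-noiseless data then converge to an essentially unpenalized fit, while
noisy data stop at an interior optimum on the first round. A fixed `alpha`
bypasses CV entirely (and makes the fit exactly invariant to duplicating
the training samples). Numerical settings: coordinate-descent tolerance
1e-5 (1e-7 for fixed-alpha fits), max 10 000–20 000 iterations. With any
nonzero penalty the noiseless round-trip carries O(alpha) shrinkage bias;
in practice the ladder leaves ≈ 2e-4 years of error, and the accuracy
contract used in the tests is MAE < 0.1 years noiseless and < 3 years at
array-scale noise (beta SD 0.02, n = 200).

The clock is trained on an external reference set and then applied to the
cohort's two timepoints — mirroring how multi-tissue clocks are actually
deployed, and avoiding p ≫ n attenuation that training on 43 patients
would cause. Biological-age delta is prediction(post) − prediction(baseline);
"decreasing biological age" means strictly negative delta. Missing
whitelist CpGs raise by default; an explicit mean-imputation flag exists.
Model files serialize intercept, adult age and per-CpG coefficients via
`repr` round-tripping, so write → read is bit-exact. No cell-composition
adjustment is applied.

## Variant pipeline

Inputs are MAF-like TSVs (tumor-centric column names reinterpreted for
germline calls: `Tumor_Sample_Barcode` is the patient id), a 4-column BED
gene panel, and a ClinVar-style `variant_key → clinical_significance`
table. Variant identity is the normalized `chrom:pos:ref:alt` key with
1-based MAF positions; HGVS strings are opaque display labels. BED is
0-based half-open, so a variant at 1-based position p matches region
[start, end) iff start < p ≤ end; this conversion lives in one place and
is unit-tested at both boundaries. SNV classes use the six
pyrimidine-reference categories (C>T, T>C, C>G, C>A, T>A, T>G).

"Classified" means present in the annotation table with *any* non-empty
significance string, including "Uncertain significance" — the split is
annotated-vs-unknown, not benign-vs-pathogenic. Carrier counting ignores
zygosity and multiplicity (one patient = one carrier). The hotspot rule is
applied to two-decimal frequencies: graph node iff non-responder frequency
≥ 50 % (inclusive); highlighted iff ≥ 70 % in non-responders *and* strictly
< 50 % in responders. Mutation summaries count classifications, types and
SNV classes, rank genes by total count (ties broken by gene symbol for
determinism), and build the gene × patient oncomatrix where a cell is
`Multi_Hit` iff the gene carries ≥ 2 variants in that patient. The pathway
graph is bipartite — central pathway hubs, peripheral (gene, mutation)
nodes for every graph-node hotspot, edges flagged highlighted — exported
as GraphML and a minimal hand-written DOT (no graphviz binding required).

## Burden association

Per-gene burden is the raw count of variant records per (patient, gene),
zero-filled over the panel; all panel variants count, classified or not.
Per gene, Spearman rank correlation between burden and age delta plus an
OLS line `delta = intercept + slope · count` (delta regressed on counts,
matching the reported direction). Genes with constant burden are skipped
with a flag. Raw p-values are the default report, matching practice for a
hypothesis-generating screen; a Benjamini–Hochberg column is attached
whenever ≥ 2 genes are tested.

## Synthetic-cohort generator

The generator's defaults *are* the study conditions: 21 responders / 22
non-responders; HCY 15.7 ± 5.5 → 11 ± 2.9 (responders) and 16.7 ± 4.1 →
19.6 ± 3.7 µmol/L (non-responders); folate 46.3 ± 40 → 81.4 ± 29.4 nmol/L;
cfDNA 9.0 ± 4.8 → 8.1 ± 4.9 ng/mL; LINE-1 baselines from the three-CpG
panel means per fraction with planted post shifts of +1.5 (cfDNA), 0
(granulocyte) and +1.45 (mononuclear) percentage points — ≈ +1.9 % relative
change on the cfDNA/mononuclear baselines; age deltas −0.5 ± 4.7
(responders) and −5.3 years (non-responders).

Design choices, and what they buy:

* **Lognormal biomarkers.** Only means ± SD are specified, so a
  distribution had to be chosen. Positive clinical biomarkers are drawn
  from correlated lognormals moment-matched to the configured mean/SD:
  values stay positive without truncation (so sample means converge to the
  configured means exactly) and per-patient relative changes stay finite.
  Before/after pairs share a latent (pair correlation 0.9 for HCY/cfDNA,
  0.5 for folate), and one extra patient latent couples HCY with cfDNA to
  plant their positive cross-correlation (target r ≈ 0.24). A consequence
  worth knowing: the mean of per-patient cfDNA ratios (≈ −10 %) is *not*
  the ratio of the group means — the same mean-of-ratios vs.
  ratio-of-means gap real cohorts show.
* **Planted signs.** Responder pairs are rejection-resampled until
  HCY_after < HCY_before (non-responders conversely), so stratification
  has exact known truth. With pair correlation 0.9 the rejection rate is
  1–8 %, and the induced shift in group means is well under one standard
  error at cohort size.
* **Burden-driven deltas.** Non-responder age deltas are generated *from*
  the planted association: burden x ~ negative binomial (mean 9.93,
  SD 7.2), delta = −5.3 + 0.394·(x − 9.93) + N(0, 5.9). The planted group
  mean, the regression line (intercept −9.214 at slope 0.394) and the
  implied correlation (r ≈ 0.43) are thereby mutually consistent rather
  than three separate knobs. Detection power at n = 22 is ≈ 0.43 — a
  borderline-by-design effect.
* **Methylome.** A generative aging methylome assigns each whitelist CpG a
  baseline in [0.3, 0.7] and (for 272 of 308 CpGs) a slope of ±0.01–0.05
  beta per transformed-age unit, keeping noiseless betas inside [0, 1] up
  to age ~120 with no clipping distortion. Beta noise is Gaussian
  (SD 0.02) clipped to [0, 1] rather than a Beta distribution — the clock
  is linear and indifferent to tail shape at this scale. 42 extra
  pure-noise CpGs exercise whitelist filtering. A reference training set
  (n = 200, ages uniform 20–90) is generated alongside the cohort. True
  biological age scatters around chronological age with SD 2 years.
* **Variants.** Planted shared variants (the four hotspots, the two MTHFR
  polymorphisms, one node-only MTRR variant) assign the first k patients
  of each group as carriers — frequencies are recovered exactly, under any
  seed. Background variants get patient-unique positions, so they can
  never reach a frequency threshold and the planted hotspot calls are
  guaranteed. Chronological ages are N(62, 10) clipped to [35, 90] — a
  mostly postmenopausal cohort — with a 70/30 F/M split.
* **Seeding.** One integer seed drives all sub-generators through a
  spawned `SeedSequence` tree; identical seeds give byte-identical output
  files.

What the generator does **not** emulate: measurement batch effects, array
normalization artifacts, linkage between variants, realistic site-specific
methylation distributions, missingness patterns, or any feedback of
genotype on biomarker trajectories (other than the single planted
burden–delta link). Passing tests therefore demonstrate that the analysis
code recovers known structure under idealized noise — not that the
biological effects would replicate in a real cohort.

## Problem sizes and tolerances

Tests and the acceptance script run the default cohort (n = 43), a
reference clock set of n = 200 × 308 whitelist CpGs (+42 noise rows), and
brute-force recounts on tiny cohorts (≤ 5 patients, ≤ 10 variants).
Continuous recoveries are asserted within 3 × the standard error implied
by the configured SDs (plus a 0.5-unit allowance where rejection
resampling shifts a mean); discrete structure — group sizes, carrier
counts, hotspot calls — must be exact. Null-effect and power-style checks
aggregate over multiple seeded replicates, since a single draw of a
uniform p-value fails its threshold 5 % of the time by construction.

## Known limitations

* The clock whitelist is synthetic; results with the real cross-platform
  CpG list require the user to supply it (`whitelist.txt`).
* No multivariable adjustment (sex, smoking, baseline HCY) anywhere; the
  stratified analyses are univariate by design.
* The oncomatrix/percentage outputs count all panel variants by default;
  restricting to classified-only is a caller-side filter on the split
  variant lists.
* `summarize_group` returns SD = NaN for n = 1 (sample SD undefined).
* Whole-exome preprocessing (alignment, calling, annotation, MAF
  conversion) is upstream and out of scope; the pipeline starts at the
  MAF-like table.
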