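# Methods

`teasig` re-implements, as a tested library, the population-signature
analysis used for diverse tea (*Camellia sinensis*) accession panels: five
phylogenetic groups (group 1 = the large-leaved CSA lineage, groups 2–5 =
CSS subpopulations), transcriptome-derived SNPs, and replicated untargeted
LC-MS metabolite profiles.  This note records the models, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data can and cannot show.

## SNP filtering and site classification

Genotypes are biallelic calls coded 0/1/2 with −1 for missing.  Quality
filtering keeps sites with minor allele frequency **strictly greater than
0.05** (over non-missing alleles, two per called diploid), missing rate
**strictly less than 0.20**, and thins clustered sites so retained SNPs are
more than 5 bp apart.  The spacing rule is a greedy left-to-right scan per
scaffold over the sites that already passed the other two filters: a site
survives only if it is more than 5 bp from the previously *retained* site.
Greedy first-wins retention is one of several defensible readings of a
"more than 5 bp apart" rule (alternatives: keep the higher-quality or a
random member of each cluster); it is deterministic, order-preserving and
idempotent, which the tests rely on.

Codon degeneracy is classified under the standard genetic code: a site is
4-fold degenerate iff all four nucleotides at that codon position encode
the same amino acid (stop codons count as their own "amino acid", so the
third position of TGG is not 4-fold).  Sites with a single synonymous state
are labeled 0-fold, following the field's convention.  Distance-grade
marker selection keeps only 4-fold sites with zero missing calls across all
samples.

## Major alleles and signature SNPs

The major allele of a SNP within one group is the allele with frequency
**≥ 0.75** among the group's non-missing alleles; if neither allele reaches
the threshold (or the group has no calls at the site) the major allele is
undefined.  Because sites are biallelic, an exact 0.5/0.5 tie can never
reach a threshold in (0.5, 1], so no tie-breaking rule is needed.

A pairwise *signature site* requires **both** groups to have defined major
alleles that differ — an undefined side never matches.  A *group-specific
site* for focal group g requires g and **every** other group to be defined,
with every other group differing from g.  This all-groups-defined rule is
the stricter of the two possible readings (the alternative only requires
definedness in g and the compared group); it is the one implemented because
a signature marker that cannot be typed in some group is not usable as a
diagnostic for that group.

## Windowed diversity and Fst

Window presets: Fst on 100-kb windows stepped by 10 kb; π on 10-kb windows
stepped by 1 kb; score tracks on non-overlapping 10-kb windows.  Windows
start at 0, step, 2·step, … while start < scaffold length, with the last
window truncated; all internal coordinates are 0-based half-open (VCF
positions are converted once at the I/O boundary).

Per-site diversity is the unbiased average pairwise difference
2p(1−p)·n/(n−1) over n called alleles; window π sums the per-site values
over SNPs in the window and divides by window length in bp.  Invariant
sites are assumed monomorphic, so SNP-free windows carry π = 0 (not
missing) — also in region-scale means used by the sweep filter.

Fst uses the Weir & Cockerham (1984) estimator: per-site variance
components a (among populations), b (among individuals within populations)
and c (within individuals), combined per window as Σa / Σ(a+b+c)
(ratio of averages).  No estimator is canonical for this kind of scan, but
W-C is the community default; Hudson's estimator is available behind
`estimator="hudson"`.  Sites where either group has no called genotypes are
excluded; windows with no usable SNPs are missing.  The test suite checks
the implementation against an independently coded hierarchical-ANOVA
formulation (mean squares over allele indicators) rather than the same
frequency formulas.

## Sweep-region calling

XP-CLR (or any per-window score) is consumed, never computed.  The chain:

1. windows with score ≥ the empirical 95% quantile are selected;
2. adjacent/book-ended selected windows merge into regions; a region's
   score is its best member window;
3. regions are kept if they reach the 99% quantile of *window* scores —
   thresholding region scores on the window-score scale keeps both cuts on
   one common distribution (the alternative, a quantile of region scores,
   would make the 1% cut depend on how merging happened to go);
4. each region's π ratio = mean reference-group π over mean focal-group π
   across overlapping windows; regions in the top half of ratios are kept.
   The ratio is oriented reference-over-focal so that genuine sweeps
   (reduced diversity in the swept, focal group) give *large* ratios.

Score quantiles use the nearest-rank (inverse-ECDF) definition with ≥
comparisons, so exact ties are kept.  The π-ratio cut uses the standard
interpolated median of the surviving candidates: with a small candidate set
the lower nearest-rank median would keep *every* candidate (ratio ≥ min is
vacuous for two candidates), defeating the filter, whereas the interpolated
median always keeps the top half.  Zero focal diversity yields an infinite
ratio, kept and logged.  Output regions are disjoint and sorted.

## Metabolomics

The pipeline order is fixed: internal-standard normalization → MAD
replicate-outlier removal → aggregation to accession means → low-abundance
filter → pairwise one-tailed tests with BH correction → signature calling.

* **Normalization** multiplies each sample column by median(IS)/IS so the
  internal-standard signal is equalized; zero/missing IS is an error.
* **MAD filter**: within each (feature, accession) replicate vector
  (R = 5), x is discarded when |x − median| > k·1.4826·MAD with k = 3
  (Hampel convention; the 1.4826 factor makes MAD consistent for normal
  noise).  When MAD = 0 (a majority of identical replicates) any deviating
  value is discarded.  With only five replicates this rule is intentionally
  aggressive: the small-sample MAD is noisy, and a few percent of perfectly
  clean replicates are trimmed along with essentially all gross (≈10×)
  outliers.  Because the test statistic operates on accession means of the
  survivors, this trimming costs little power.
* **Statistical unit**: the accession — replicates are technical-scale
  repeats of one plant pool, while group claims are about accessions
  (group sizes 29/11/32/26/36).  Features with fewer than two accession
  values in a group are skipped for that group's pairs and reported.
* **Testing**: pooled-variance Student t (Welch behind a flag) on accession
  means, one-tailed per ordered pair (A, B) for H1: mean_A > mean_B.  BH
  correction is applied across features *within each ordered pair* — with
  the correction family unstated, the per-pair family is the symmetric,
  conservative choice and is configurable.  A DAM requires adjusted
  p < 0.05 **and** raw fold change > 2; fold changes are computed on raw
  (pre-log) means, consistent with the reference table's fold claims.
* **Signature metabolites**: up-DAM versus every other group.  Mutual
  exclusivity of A>B and B>A makes the per-group sets disjoint.
* Fragment-ion identification is manual curation upstream of this package;
  an exclusion-list input reproduces its effect.

The headline per-feature statistic `min_fold_ratio` is the focal group's
mean divided by the *largest* other group's mean (infinite when all other
means are zero).  A 40-row reference table of per-group signature-
metabolite means ships with the package for worked examples.

## Synthetic data

The generators define the study conditions; their defaults are fixed, not
tuning knobs.

* **Genotypes**: 134 samples in groups of 29/11/32/26/36; 1000 sites;
  ancestral frequencies Uniform(0.05, 0.95); per-group frequencies from the
  Balding–Nichols Beta with divergence F = 0.1 (the standard minimal
  F-model for population structure; 0.1 is a moderate level consistent with
  closely related crop populations); genotypes Binomial(2, freq); 2%
  missingness.  100 planted group-1-divergent sites use alternate-allele
  frequency 0.95 in group 1 and 0.05 elsewhere.
* **Metabolites**: 400 features; baselines 10^N(3.5, 0.75) spanning roughly
  1e2–1e5 like real relative-abundance tables; 10 planted signature
  features per group at 4-fold effect; log-normal accession noise (log-sd
  0.3) and replicate noise (log-sd 0.3); R = 5 replicates; optional 10×
  single-replicate outliers; an internal-standard row with 5% variation.
* **Tracks**: 2000 non-overlapping 10-kb windows; background scores
  Gamma(shape 4, scale 1) — right-skewed like composite-likelihood scores
  but with a light enough tail that a 10× planted run separates cleanly
  from the background's 95% quantile; diversity tracks log-normal around
  0.003 (log-sd 0.2).  A planted run multiplies scores by 10 and focal π by
  0.3 over a 5-window span.

Everything is a pure function of (config, seed) via independent PCG64
substreams, so outputs are byte-identical across runs and platforms.

What the generators do **not** emulate: linkage disequilibrium and
recombination (sites are independent), realistic allele-frequency spectra,
isotope/adduct structure or correlated features in MS data, batch effects,
and retention-time drift.  Recovery results on synthetic data therefore
show that the *decision rules* behave as specified under the intended
noise model, not that real-data performance will match.

## Problem sizes and known limitations

Tests and recovery experiments run at desk scale: 1000-site genotype
matrices, 400-feature tables, 2000-window tracks, 10–20 seeds — sizes at
which every stage's behavior is already identifiable.  Dataset-scale
figures from real panels (hundreds of thousands of SNPs, hundreds of
annotated metabolites, hundreds of sweep regions) depend on deposited raw
data and manual curation and are out of scope.

Known limitations: the 5-bp thinning keeps the *first* SNP of a cluster;
the sweep caller's top-1% window threshold necessarily admits ~1% of
background windows as candidate regions, so isolated high-score noise
windows can appear alongside a genuine sweep (the π-ratio filter halves
them); with five replicates the MAD rule trims several percent of clean
replicate values by construction; and multi-allelic variants are excluded
throughout.
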