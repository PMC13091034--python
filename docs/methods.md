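# Methods

This note documents the models, estimators, parameter choices and
numerical conventions behind `feralscan`, and what the synthetic
validation does and does not establish about real data.

## Coordinates and containers

Variant positions are 1-based (VCF); all intervals, windows and BED
outputs are 0-based half-open. The single conversion lives at the
window/interval boundary: a variant at position `pos` occupies base
`pos − 1` and falls in window `[start, end)` iff `start < pos ≤ end`.
Genotypes are stored as an int8 array of shape (samples × variants ×
2) with −1 for missing alleles; only bi-allelic SNPs are loaded, and
multi-allelic or non-SNP records are counted and skipped at read time.
All frequencies are computed over called alleles only; a site missing
in an entire population drops out of any pairwise statistic involving
that population.

## The synthetic cohort model

The generator emulates the study design the scans are built for: a
focal feral population, several domestic reference populations, two
wild donor species and one distant outgroup.

**Shared-polymorphism backbone (Balding–Nichols).** Each site draws an
ancestral derived-allele frequency p ~ Uniform(0.05, 0.95); each
population draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with
its own drift parameter F, and haplotypes are independent Bernoulli
draws from that frequency. Defaults: focal HKF (n = 20, F = 0.15),
references EAI (15, 0.15), SAI (10, 0.20), EUT (15, 0.25), NEAT (10,
0.25) — drift values in the range of moderately diverged cattle
populations; donors banteng and gaur (4 each, F = 0.8, species-level
divergence with strongly U-shaped frequencies); outgroup buffalo (2,
F = 0.01), i.e. near-ancestral, so outgroup polarization is realistic
but occasionally wrong or impossible (a 2-diploid outgroup is split
50/50 at a noticeable fraction of sites; those are flagged
unpolarizable and excluded from derived-allele statistics). The ALT
allele is the derived allele at every simulated site.

**Donor-private fixed differences.** Shared ancestral polymorphism
alone cannot produce the site class that donor-diagnostic scans live
on: sites fixed derived in the donor but (near-)absent in all other
populations. Under the Beta model, donor fixation favours high p while
reference rarity favours low p, so the joint class is vanishingly
rare — whereas real species pairs separated by 1–3 My carry fixed
differences of the same order of magnitude as segregating sites. The
generator therefore converts a fraction (default 0.08 per donor) of
sites into donor-lineage fixed differences: fixed derived in that
donor, with a small incomplete-lineage-sorting "leakage" frequency
~ Uniform(0, 0.05) in every other population and in the outgroup.
These sites are recorded in the ground-truth manifest so model-level
tests can exclude them when checking Balding–Nichols moments.

**Planted features.** All planting operations record themselves in a
ground-truth manifest (JSON + BED) and keep their intervals disjoint
where distinguishability matters (a sweep may not overlap an
introgression tract):

* *Introgression*: exactly round(α·n) focal haplotypes are chosen once
  per tract (not per site) and their alleles inside the tract replaced
  by Bernoulli draws from the donor's empirical frequencies. Choosing
  the exact count rather than a Bernoulli(α) subset keeps the realized
  admixture fraction at α instead of fluctuating around it, which
  matters when a downstream threshold sits exactly at α.
* *Sweeps*: focal frequencies in the region are redrawn from
  Uniform(intensity, 1]; intensity 1.0 fixes the focal population.
* *Autozygosity*: the sample's second haplotype is overwritten by its
  first inside the segment.
* *CNV calls*: planted copy-number regions (background: one shared
  copy-number distribution; differentiated: group means 2 vs 4, sd
  0.3) emit per-sample calls with boundary jitter ≤ 1 kb plus a few
  junk calls (short, high p, high q0) so the quality filters are
  exercised. A group at mean 2 emits no call — its samples are
  diploid non-carriers.

There is no background LD and no recombination map: planted tracts are
the only spatial structure. Positions are evenly spaced; default
spacing 2 kb on a 10 Mb contig. Count-based window scans (U50) are run
on denser cohorts (250 bp–1 kb spacing, 50 Mb) because real WGS data
has ~1 SNP per 50 bp and a 50 kb window needs tens of informative
sites for a stable count; even the densest simulated spacing is ~5×
sparser than the data the thresholds were designed for. The mutation
rate (1.26 × 10⁻⁸/generation) and generation time (6 years) are
carried as config constants for demographic work but are unused by the
frequency-model simulator.

**What passing recovery tests shows — and does not.** Recovery of
planted features demonstrates that each estimator computes what it
claims and that the detection thresholds behave as designed under
drift, sampling noise and missing polarization. It does not
demonstrate robustness to background LD, recombination-rate and
mutation-rate heterogeneity, ascertainment from variant calling, or
demographic histories outside the Balding–Nichols family; on real
data those affect window-to-window variance and hence empirical-tail
thresholds.

## Estimators and numerical choices

**π.** Per site, the unbiased form 2j(n−j)/(n(n−1)) for derived count
j among n called alleles; window value = Σ π_site / window length in
bp (matching the windowed-π convention of common VCF tooling; a flag
switches the divisor to callable sites). Windows with < 10 SNPs are
flagged low-support and excluded from scan quantiles.

**Ho / F.** Per sample over its called sites: Ho = het/n;
F = (O_hom − E_hom)/(n − E_hom) with E_hom(site) = 1 − 2p(1−p)·n/(n−1)
from cohort frequencies (the PLINK `--het` convention).

**Hudson FST.** Bhatia-style ratio of averages with finite-sample
correction (see README for the formula); per-site values may be
negative; windows whose summed denominator is zero are NaN and
flagged. The suite asserts ratio-of-averages explicitly — the
average-of-ratios variant is biased and genuinely differs on mixed
fixtures.

**Di.** Per-site pairwise FST is the Hudson N/D ratio (sites with
D ≤ 0 skipped for that pair); each (focal, other) pair is standardized
by its genome-wide mean and SD over all usable sites, and Di sums the
standardized deviations over pairs. Pairs with zero genome-wide SD are
excluded with a warning. The top fraction (default 0.1%) is selected
by rank.

**FST/θπ-ratio scan.** pi_ratio = log₂(π_ref / max(π_focal, floor))
with floor = (smallest positive focal window π)/10, keeping fully
swept windows finite and maximal; floored windows are flagged.
Candidates must lie strictly above the (1 − tail) quantile on *both*
axes — strict inequality makes a degenerate axis (all windows tied,
e.g. ratio identically zero) produce no candidates instead of passing
everything through. The joint tail defaults to 1% per axis,
configurable.

**Patterson's D.** Frequency-based (donor panels are small):
ABBA = (1−p_W)p_X p_Y(1−p_Z), BABA = p_W(1−p_X)p_Y(1−p_Z) on
outgroup-polarized derived frequencies; D = Σ(ABBA−BABA)/Σ(ABBA+BABA).
SE by delete-one jackknife over contiguous blocks (default 5 Mb,
chosen to exceed any simulated tract-scale correlation); Z = D/SE.
Unpolarizable sites and sites with no calls in any of the four
populations are excluded. Degenerate cases (Σ(ABBA+BABA) = 0, < 2
blocks, SE = 0) raise or flag rather than returning silent numbers.

**U50.** Donor "fixed" is judged on integer counts — derived count
equals called count with ≥ 2 called donor alleles — never on floating
equality; reference rarity (< 1%) and focal commonness (> 50%) use
strict inequalities as printed. Window counts are small integers
massively tied at zero, so the "top 5%" threshold is the smallest
integer t whose exceedance fraction is ≤ 5%; a plain quantile would
either flag every nonzero window or none beyond ties.

**ROH.** Detection parameters default to the cited tool's documented
defaults (50-SNP windows, ≤ 1 het, ≤ 5 missing, hit fraction 0.05,
≥ 100 SNPs, ≥ 1 Mb, density ≥ 1 SNP/50 kb, gap ≤ 1 Mb); all are
exposed in `ROHParams`. The caller is genotype-only and therefore
phase-invariant. Size classes come from a k = 3 univariate Gaussian
mixture on log₁₀ length fitted by EM with quantile initialization
(deterministic given the data; unequal variances allowed; sd floored
at 10⁻³); class boundaries are the equal-posterior crossings between
adjacent components, found by root-bisection between the sorted means
with a midpoint fallback. Boundaries are derived per dataset, not
fixed in bp. Common ROH uses base-resolution coverage counting with a
strict "more than" fraction (a region covered in exactly half the
individuals is excluded); specific ROH is interval subtraction of all
other populations' common sets. Burden comparisons use the two-sided
Wilcoxon rank-sum test (exact when sample sizes and ties permit;
all-tied inputs report p = 1) and Pearson correlation of per-sample
segment count vs cumulative length per class.

**LoF load.** "Homozygous" is homozygous-*derived*: the screen targets
putatively deleterious derived alleles, so homozygous-ancestral
genotypes carry no load. Sites the outgroup cannot polarize are
excluded (logged). Both the per-individual mean ± sd and the pooled
ratio from summed counts are reported, since the two aggregations can
differ.

**CNVR/VST.** Quality filters are strict inequalities (length
> 1 kb, p < 0.001, q0 < 0.5 — boundary values are removed). Merging is
single-linkage over the "≥ 50% reciprocal overlap of both calls"
relation, per contig and per type (deletions and duplications never
merge); single-linkage is order-independent and idempotent, which the
suite asserts. Non-carrier samples receive copy number 2 (diploid
reference) so every CNVR has a full-cohort vector. VST uses population
(ddof = 0) variances, V_S = (V_A n_A + V_B n_B)/(n_A + n_B), which
bounds VST in [0, 1]; regions with zero total variance are flagged
uninformative and excluded from the empirical top-1% quantile, which
is computed jointly over both CNV types (a per-type option exists).

**Pipeline.** All stage randomness derives from the single top-level
seed through fixed per-stage offsets; floats are written with a fixed
format, so a config + seed reproduces every output byte-identically.
The coat-color phenotype is a deterministic half split of the focal
population. Gene–region annotation reports any ≥ 1 bp overlap on
half-open intervals (an abutting gene is not a hit). A
Benjamini–Hochberg helper is provided for scan p-values; gene-set
enrichment against external databases is deliberately out of scope.

## Validation scales

The test and acceptance workloads were sized for a single CPU: D
calibration uses 100k-site cohorts (200 Mb at 2 kb spacing, 40
jackknife blocks), 20 null and up to 20 planted replicates; U50 uses
50 Mb at 250 bp with a 1 Mb α = 0.5 tract; the sweep scan uses 50 Mb
at 1 kb with a grid-aligned 390 kb fixed sweep; ROH uses the default
10 Mb / 2 kb cohort with 1.5–2 Mb planted segments; the mixture check
fits 3000 lengths at means 2.8/3.3/4.0 log₁₀ bp, sd 0.05. Under the
null the jackknife Z is approximately standard normal (empirical SD
~1.1 across replicates — mildly anti-conservative with 40 blocks,
which the calibration bound accommodates).

## Known limitations

* No background LD or recombination: LD-pruning is exercised on
  synthetic correlation only, and block-jackknife block size cannot be
  stress-tested against realistic LD decay.
* The outgroup has 4 alleles; ~20% of sites are unpolarizable and
  excluded from D/U50/load, mirroring — but not calibrated to — real
  outgroup panels.
* ROH detection assumes dense, evenly spaced sites; array-like sparse
  panels would need the window vote and density parameters retuned.
* The CNV simulator emits calls, not read depth; read-depth calling
  artifacts (GC bias, mappability) are outside the model.
* Phasing is trusted as given ("|" separators are written but nothing
  downstream uses phase except haplotype-level planting).
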