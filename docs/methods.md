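# Methods

## Setting

The pipeline analyses absolute DNA-methylation scores estimated from
MeDIP-chip experiments (BATMAN-style Bayesian deconvolution) on a fixed
grid of 100-bp windows, together with tag-SNP genotypes, over regions of
strong linkage disequilibrium around disease-association SNPs.  Its goal is
to detect and localise *haplotype-specific methylation* (HSM): a
kilobase-scale methylation difference that tracks the haplotype, typically
driven by CpG-creating SNPs in phase on one haplotype.  Array processing
and the methylation estimation itself are upstream of this package; its
inputs are per-sample window scores in [0, 1], a repeat-exclusion mask,
genotypes coded as rare-allele dosage 0/1/2, case/control status and age.

All coordinates are 1-based inclusive internally and in TSV I/O (matching
hg18-style printed coordinates); BED/BEDGRAPH inputs are converted from
0-based half-open at ingestion.  Window indices reported to users count
only unmasked windows — the only convention under which "60 windows" can
span 7.7 kb of genome once repeats are excluded — and genomic coordinates
are always reported alongside so masked gaps are visible.

## Stage 1 — block-level methylation load

A sample's *methylation load* over a region is the arithmetic mean of its
unmasked, non-missing window scores fully inside the region (samples
missing more than half of a region's windows are flagged).  Loads are
compared across tag-SNP genotype groups three ways:

- **Kruskal–Wallis** over the 0/1/2 dosage groups (midranks, tie
  correction, chi-square df = k−1), sensitive to non-additive patterns.
  The degenerate all-equal case returns H = 0, p = 1 by convention.
- **Linear regression** of load on additive dosage, optionally with age in
  years as a covariate; the reported p is the two-sided t-test on the
  dosage coefficient.  Dosage is the count of the *rare* allele; because
  the risk allele need not be rare, allele labels accompany every result.
- **Permutation**: genotype assignment is shuffled over the fixed loads
  (default 10,000 shuffles) and the empirical p is (b+1)/(n_perm+1), where
  b counts shuffles whose statistic is at least the observed (H for KW,
  |t| for regression).  The estimator never returns 0; the attainable
  floor 1/(n_perm+1) is reported explicitly.  With age as a covariate the
  shuffled dosage and the response are both residualised on age, since age
  stays attached to its sample while genotype is reassigned.

Across multiple blocks, uncorrected p-values are reported with a
Bonferroni-adjusted column; no FDR is applied at this stage.

## Stage 2 — multi-scale sliding-window scan

Every window size w from 1 to the block's unmasked window count slides one
window at a time over unmasked indices; each placement's per-sample load
is the mean of its w scores, computed by cumulative sums (O(1) per
placement), and each placement is tested exactly as at block scale.  The
full scan is O(W²) placements; the statistics are vectorised row-wise
(all placements of one size in single array operations), cross-checked in
the tests against scipy and statsmodels single fits.  Placements are
plotted at the midpoint of their genomic span.

Peak calling takes the global minimum of the regression p over all
(w, placement) pairs; exact ties break toward smaller w, then the leftmost
placement.  Per-size minima are retained so the nesting of a narrow peak
inside a broader one can be examined.  Slope profiles expose the direction
of the effect (per copy of the rare allele).

Scan permutation shuffles the genotype labels once per permutation and
applies the same shuffle to every placement and size, preserving the
spatial correlation of the methylation tracks.  `pointwise` mode gives
per-placement empirical p (the primary analysis); `max_statistic` mode
compares each observed |t| with the permutation distribution of the
family-wide maximum |t| — a family-wise-adjusted extension, clearly
flagged as such, since the pointwise scan alone does not control the
family-wise error over the W²/2 placements.

## Stage 3 — empirical-Bayes DMR calling

Case/control status y_s is modelled by logistic regression on the
methylation values m_ps of the individual 100-bp proxies p inside a region
of interest (ROI, 500–4000 bp).  With roughly as many proxies as samples,
the per-proxy coefficients β_p are treated as draws from a distribution
with mean zero and variance σ²; no differential methylation is H₀: σ² = 0.
The score test for this null (the Goeman global-test statistic) is

    Q = (y − ȳ)ᵀ X Xᵀ (y − ȳ) / nprox ,

with X the sample × proxy matrix after per-proxy centering (which removes
the intercept).  Q = 0 exactly when every proxy is uncorrelated with the
labels in-sample.  Proxies are not variance-scaled by default — the test
is meant to use the proxies' methylation values as they stand — with a
`standardize` switch available.  Missing proxy values are mean-imputed per
proxy and flagged.

Inference is by permutation of the labels, (b+1)/(n_perm+1), with one
shuffle stream shared across all ROIs.  An *advisory* asymptotic p
moment-matches Q to a scaled chi-square a·χ²_ν using the exact permutation
mean and variance of Q, derived in closed form: because X's columns are
centered, B = XXᵀ/nprox has zero row sums, and the first two moments of
zᵀBz under random rearrangement of the centered label vector reduce to
expressions in tr B, tr B², Σᵢ Bᵢᵢ² and the label moments Σc², Σc⁴.  The
derivation is validated in the tests against exhaustive enumeration of all
n! rearrangements at n = 6.  The permutation p is primary at n ≈ 60.

FDR over many ROIs is estimated two ways: Storey q-values with π₀
estimated at the single fixed λ = 0.5 (fewer degrees of freedom than a
λ-smoother, fully reproducible), q monotonised right-to-left; and a direct
permutation FDR, FDR(t) = E_perm[#{null p ≤ t}] / max(1, #{observed
p ≤ t}), from the same joint shuffles.

## Stage 4 — CpG-creating SNPs and pyrosequencing re-analysis

A SNP is CpG-creating/abrogating when it is **YpG** (alleles {C, T}
immediately 5' of a G; the C allele forms the CpG) or **CpR** (alleles
{A, G} immediately 3' of a C; the G allele forms the CpG).  CpG is
palindromic, so checking both motifs on the given strand makes the call
strand-invariant (property-tested on random contexts).  An N at the
deciding flank base yields "unknown".  Against a supplied ancestral base —
or the unanimous base of several outgroup species, else unknown — the
CpG allele being derived is a *gain* of methylatability and the ancestral
base being the CpG allele is a *loss*.  In-phase SNPs are clustered by
single linkage at a distance threshold read as ≤ 75 bp (the worked pair in
the narrow peak is exactly 75 bp apart; the threshold is a parameter).  A
haplotype's CpG capability is the reference CpG count plus phased gains
minus phased losses.  D' and r² between phased loci use the standard
D/Dmax and D²/(p_A q_A p_B q_B) forms, clamped to [0, 1] against float
round-off.

Pyrosequencing-style tables (sample, site, percent methylation) are
re-analysed by genotype stratification.  A SNP-dependent site's percent is
interpreted as the bisulphite-read C fraction, so a non-CpG allele reads
as unmethylated and the expected gradient across local CpG-allele dosage
0/1/2 is ≈ 0/50/100%.  Non-polymorphic sites are screened for
allele-specific methylation by per-site Kruskal–Wallis at α = 0.01 without
multiplicity correction by default (validation tables are small; a
Bonferroni switch exists).  Re-stratification by the locally read CpG-SNP
genotype lists samples out of phase with the tag SNP (imperfect LD) and
recomputes group means over concordant samples only.

## Synthetic cohorts

The generator draws cohorts with the statistical structure the analysis
assumes, so every stage is testable without any external data:

| parameter | default | rationale |
|---|---|---|
| n_samples / n_cases | 60 / 30 | study design (all-female 30 T2D / 30 control) |
| maf | 0.425 | CEU frequency of the FTO risk haplotype |
| n_windows | 334 | usable 100-bp windows in the 46-kb block |
| mask_fraction | 0.272 | interleaved repeat mask; grid spans ~46 kb |
| hsm_window_range | 161–169 | the 9-window narrow peak, unmasked indices |
| effect_peak | 0.048/allele | Table-2-calibrated: risk-homozygote − non-carrier = 0.096 |
| effect_block | 0.016/allele | reproduces the block-scale difference ≈ 0.034 |
| baseline_mean | 0.50 | mid-scale absolute methylation |
| noise_sd | 0.14 | the data set's reported per-window SD |
| age_mean / sd | 37 / 6.6 | study demographics |

Scores are baseline + dosage × effect + Gaussian noise, clipped to [0, 1].
Only an empirical SD is reported for the real data, so Gaussian noise
clipped at the boundaries is the simplest model matching that moment; at
baseline 0.5 the clipping bias is negligible.  Effects enter additively
per risk-allele dosage (the observed three-genotype means are
near-additive).  Genotypes are Hardy–Weinberg at the configured MAF; ages
are independent of genotype and methylation (age was a non-significant
covariate in the source analysis), with an `age_effect` switch for
covariate testing; case/control labels are independent of methylation by
default, with a `dmr_effect` option that shifts designated windows by
status for power testing of the DMR caller.  The pyrosequencing simulator
reads SNP-dependent sites at 100 × local dosage / 2 plus noise and can
inject a chosen number of tag/local discordant samples, returned as truth.

**What the generator does not emulate:** windows are independent by
default, whereas real MeDIP tracks are strongly autocorrelated along the
block (fragment size, probe overlap, biological co-methylation).
Consequently block-level loads average noise away faster than in real
data, and simulated block-scale p-values are far smaller than published
ones at the same effect sizes; calibration (type-I error) is unaffected.
An `ar1_rho` knob adds AR(1) noise correlation as a clearly-labelled
extension.  No MeDIP enrichment, fragment, probe-intensity or estimation
noise is simulated — scores are generated at the estimated-methylation
level.

## Numerical and design choices

- Empirical p-values use (b+1)/(n_perm+1) everywhere; identical seeds give
  bit-identical results (generator-based shuffles; one `argsort` of a
  random matrix per permutation batch).
- Row-wise Kruskal–Wallis and OLS implementations exist because the scan
  and permutation layers evaluate 10⁴–10⁵ statistics; they are
  cross-checked against scipy/statsmodels and brute-force enumeration.
- The q-value π₀ can reach 0 on tiny, all-significant p sets; it is used
  as computed (no clamping), with λ fixed at 0.5.
- Degenerate inputs: constant dosage and single-class labels are errors;
  all-identical values return (H, p) = (0, 1); empty result tables refuse
  to serialise; a region with no unmasked windows is an error, and a
  sliding window larger than the block is trimmed with a warning.
- Tie-breaks in peak calling (smaller w, then leftmost) are documented and
  tested.

## Problem sizes used by the tests and the acceptance script

Null calibration uses 1,000 replicate cohorts (500 in the script) with
200-shuffle permutation tests; recovery uses 100 replicate full
multi-scale scans; the null DMR screen uses 200 one-kb ROIs with
1,000–2,000 shuffles.  These sizes give binomial standard errors of
~0.7–2% on the reported rates while keeping a full run in tens of seconds.

## Known limitations

- The scan's pointwise permutation p does not control the family-wise
  error over the W²/2 placements; the max-statistic mode does, and is an
  extension beyond the primary pointwise analysis.
- The asymptotic global-test p is moment-matched to two moments only;
  at strong signals it can deviate from the permutation p in the extreme
  tail.
- Published block-level p-values for the source data set are not
  desk-reproducible: they require the deposited MeDIP tracks and the
  original estimation run.  Two printed values for the broad-peak
  regression p (1.33×10⁻⁷ in the running text versus 1.13(3)×10⁻⁷ in the
  abstract and the genotype-means table) disagree in the source itself;
  this package does not adjudicate between them.
- The repeat mask and ROI definitions are inputs, not computations: how
  masked windows and ROI boundaries were chosen upstream is not specified
  by the method.
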