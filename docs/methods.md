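# Methods

## The transmission model

The unit of analysis is a complete trio (father, mother, affected child)
genotyped at a biallelic autosomal marker, with genotypes coded as
risk-allele dosages 0/1/2. We model the child genotype conditionally on
the *ordered* parental mating type (F, M):

P(child = c | F, M) ∝ Σ_{a_p + a_m = c} T(a_p | F) · T(a_m | M) · r_p^{a_p} · r_m^{a_m},

where a_p and a_m are the paternally and maternally transmitted
risk-allele counts, T(· | g) is the Mendelian gamete distribution
(certain for homozygotes, ½/½ for heterozygotes), and r_p, r_m are
multiplicative per-allele relative risks of a paternally or maternally
transmitted risk allele. Normalisation is within each (F, M) stratum, so
all mating-type (and hence population-stratification) nuisance parameters
cancel. This conditional multinomial is equivalent to a log-linear model
with ordered mating-type strata. For the triple-heterozygote cell, where
parental origin cannot be resolved, the two origin configurations are
summed, giving relative weight (r_p + r_m)/4.

Three nested models are fitted by maximum likelihood: **null**
(r_m = r_p = 1), **association** (r_m = r_p = r, 1 parameter), and
**POE** (r_m, r_p free, 2 parameters). The POE test is the 1-df
likelihood-ratio contrast POE vs association — the POE-specific contrast,
chosen over the 2-df POE-vs-null alternative so that the test is not
driven by plain allelic association; the association test is association
vs null (1 df). p-values are asymptotic upper-tail χ²(1); no
exact/permutation option is provided in this version. The POE odds ratio
is reported as r_p/r_m, i.e. paternal relative to maternal transmission.

### Numerical details

Optimisation is in log relative risks, started at (0, 0) and boxed to
|log r| ≤ log 20; the box also defines the reported boundary flag. The
2-parameter fit uses L-BFGS-B with an analytic gradient (likelihood
tolerance 10⁻¹³); the 1-parameter fit uses bounded scalar minimisation.
When the ambiguous (het, het, het) cell is empty the likelihood
factorises into two independent Bernoulli series — paternal transmissions
from het-father matings plus the origin-resolvable het×het cells with a
homozygous child, and the maternal mirror — and the MLE is taken in
closed form as the transmitted:untransmitted ratio, clipped to the box.
Tallies with no heterozygous parent are uninformative: all three models
share one likelihood and parameters are reported as 1 with a flag.
Mendelian-impossible cells (which QC removes upstream) are excluded from
the likelihood with a flag rather than propagating −∞. The LRT statistic
is clipped at 0.

The diagnostic counts (b_m, c_m, b_p, c_p) are taken from
single-heterozygous-parent matings only; note that het×het matings with a
homozygous child, while origin-resolvable and used by the fit, are not in
these counts, so the identity POE OR = (b_p/c_p)/(b_m/c_m) is exact only
when no het×het matings are present at all.

## QC cascade

Order of operations: (1) families whose Mendelian-error rate over all
tested markers exceeds 3% are discarded (the denominator is trio-marker
cells with all three genotypes called); (2) marker statistics are
recomputed on the retained families; (3) markers are dropped for a
Mendelian rate > 1%, founder MAF < 1%, or founder exact-HWE p < 10⁻⁶ —
each exclusion carries exactly one primary reason, in that precedence;
(4) residual Mendelian-inconsistent trio-marker cells at retained markers
are set missing so downstream tallies never contain impossible
configurations. MAF and HWE use parents only: founders avoid counting
transmitted alleles twice. The HWE test is the exact conditional test
(sum of probabilities of heterozygote counts no more probable than the
observed one given the allele counts), valid at low MAF where the χ²
approximation is not. The marker-level filter runs after family
exclusion; the reverse order is defensible but fixed here for
determinism. Positions are 1-based throughout.

## LD

Unphased r² comes from the standard two-locus haplotype-frequency EM:
the only phase-ambiguous genotype class is the double heterozygote, split
between cis and trans in proportion to the current haplotype-frequency
products; initialisation is linkage equilibrium, convergence is a maximum
haplotype-frequency change below 10⁻⁸ (cap 1000 iterations), and the
per-iteration log-likelihood trace is retained so monotonicity is
assertable. LD is computed in founders only. A monomorphic marker makes
r² undefined and raises — it is not reported as 0.

Proxy search returns a genotyped index as its own perfect proxy;
otherwise the highest-r² cohort marker within ±500 kb wins, ties broken
by distance then marker id. r² to an index absent from the cohort must be
supplied by an external LD table, since the reference panel behind such
proxies is an input, not something the cohort can provide. Pruning is
greedy: sort by p (ties by position then id), keep the best, drop
everything with r² > 0.5 to a retained marker, repeat; unknown pairs
count as r² = 0 with a warning.

## Gene annotation and enrichment

A SNP belongs to a gene iff it lies on the same chromosome within the
closed interval from first-exon start to last-exon end; a SNP inside two
overlapping genes counts once per gene for per-gene tallies but once for
set-level significant-SNP counts. The default MHC exclusion interval is
chr6:25,000,000–34,000,000 (configurable; the extended-LD region has no
canonical edges). Gene-set overlap uses the two-sided Fisher exact test
(sidedness is a choice; two-sided is the convention for overlap tests)
with an explicit universe size — no default universe is assumed.

The matched bootstrap redraws, for each gene with n SNPs, a uniformly
random window of n consecutive genome-ordered SNPs that does not cross a
chromosome boundary; windows are drawn independently and may overlap each
other and the original gene set (an exclusion flag exists, off by
default). The empirical over-representation p is the proportion of
replicates whose significant-SNP count is ≥ the observed count (r/B,
which can return 0; an (r+1)/(B+1) mode is available). The
experiment-wide threshold records, per replicate, the k-th smallest of
the M pooled window p-values with k = ⌈αM⌉ and returns the mean; ⌈·⌉ is
fixed because it reproduces the natural rank at non-integral αM and is
documented for the integral case. The empirical p of the best single
marker uses the per-replicate minimum over **all** windows (a per-gene
minimum variant would be stricter; the global minimum is implemented and
flagged).

## Synthetic data

The trio generator draws parents under Hardy–Weinberg at the configured
founder frequency and transmits each parental allele with probability
r/(1+r) for heterozygotes (r = r_p for fathers, r_m for mothers) — the
exact conditional model the likelihood fits, so parameter-recovery
semantics are exact by construction (fitting 10⁵-trio cohorts recovers
(r_m, r_p) within 2%). A liability-threshold population generator would
be the realistic alternative and is a documented extension point.
Defaults mirror the study design: 695 trios. Mendelian errors are
injected by drawing the corrupted-cell count as Binomial(cells, rate) and
then sampling cells among *corruptible* strata (every stratum except
het×het, where all child genotypes are consistent and no detectable error
exists), replacing the child with a uniformly chosen impossible genotype;
this makes the detected error rate an unbiased estimate of the nominal
rate. Missingness blanks one uniformly chosen member per selected cell.
A ledger records every transmitted-origin pair, corrupted cell and
blanked cell.

The GWAS-pool generator lays SNPs across 22 synthetic autosomes and
carves genes as contiguous SNP runs with per-gene counts from a
log-normal with median 73 and mean ≈ 303 — the strong right skew
(median ≪ mean) of real per-gene marker counts; at desk scales the tail
is clipped to half a chromosome so the layout stays feasible. Null
p-values are Uniform(0,1); non-null ones default to 10^(−U(4,12)), and
can be confined outside the candidate gene set to emulate a well-powered
GWAS whose signals lie elsewhere. The planted-signal scenario adds one
gene with ultra-significant SNPs plus a trio cohort genotyped at exactly
those SNPs with a true paternal distortion; trio markers are simulated
independently (no LD between cohort markers), so pruning at the planted
gene retains every SNP rather than one — a deliberate simplification.

What the generators do **not** emulate: LD between pool SNPs (real
windows are internally correlated, which widens the bootstrap replicate
distribution), realistic recombination or allele-frequency spectra,
population structure, genotyping batch effects, and case-control
sampling. Passing tests therefore demonstrate internal statistical
correctness (calibration, recovery, convention fidelity) — not
robustness to those real-data features.

## Problem sizes

The test suite and acceptance script use: 5,000 null markers × 695 trios
(two settings) for type-I error; 500 replicate cohorts for POE-OR
recovery; 50 random tallies against a zooming grid-search oracle; 200
regenerated pools × 1,000 bootstrap replicates for calibration;
M = 10,000 for the threshold check; 2,000 founders for EM r²; and a
30,000-SNP / 30-gene pool with a 695-trio cohort for the end-to-end scan.
These sizes give each stochastic check a ≥3-SE margin under its stated
tolerance.

## Known limitations

Asymptotic χ²(1) p-values can be conservative for sparse tallies
(b + c ≲ 10); incomplete trios are dropped rather than handled by EM;
haplotype-level (multi-marker) POE tests, maternal-genotype (prenatal)
effect models, covariates, X-chromosome analysis and imputed dosages are
out of scope. The double-het weighting ((r_p + r_m)/4) is one defensible
resolution of the origin ambiguity; alternatives (e.g. dropping the cell)
change power but not validity.
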