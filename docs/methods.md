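# Methods

`awmnet` implements a gene-network-enriched genomic prediction chain for
multi-breed dairy-cattle populations: de-regressed sire evaluations feed a
Bayes-B marker association per trait; per-marker variance shares select
SNPs into an association weight matrix (AWM); PCIT infers a gene network
from AWM row correlations; and the network informs genomic relationship
matrices used in cross-validated GBLUP.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## De-regression

Published PTAs (predicted transmitting abilities; half the breeding value)
blend a bull's progeny information with the parent average (PA) and shrink
it toward the PA.  Used directly as pseudo-phenotypes they double-count
family information, so the PA contribution and the shrinkage are removed
with the two-equation mixed-model algebra of Garrick, Taylor & Fernando
(2009).  With `lam = (1-h2)/h2`, `alpha = 1/(0.5-rel_pa)` and
`delta = (0.5-rel_pa)/(1-rel)` the records equivalents of the PA and of the
bull's own data are

    u       = 0.5*lam*(alpha + sqrt(alpha^2 + 16/delta))
    zpz_pa  = u - 4*lam
    zpz_own = delta*u - 2*lam

and dPTA = (-2*lam*pa + (zpz_own + 2*lam)*pta) / zpz_own, with reliability
`zpz_own/(zpz_own+lam)` and association weight
`w = (1-h2)/((c + (1-r)/r)*h2)`, c = 0.5.  The derivation was checked by a
round-trip property: rebuilding the 2x2 coefficient matrix from the derived
records equivalents reproduces the input reliabilities to 1e-10, and an
independent numerical inversion of the same equations gives identical
output.  Records with non-positive own information are excluded.

When an explicit PA is absent it is estimated by the first applicable of
0.5*sire + 0.25*MGS + 0.25*AYB, 0.5*sire + 0.5*AYB, or
0.25*MGS + 0.75*AYB, where AYB is the birth-year cohort mean PTA.

Parameters and defaults:

- `c = 0.5` — emphasis on low-reliability records in the weights.
- `h2` proxies per trait: 0.1 for the categorical calving traits (DCD,
  MCD), 0.5 for gestation length, 0.4 for the type traits.  These enter the
  weights only; they are configuration, not estimates.
- `rel_pa` defaults to 0.2 when the evaluation table does not carry one.
- Records are kept when the dPTA reliability exceeds 0.2 (strictly), and
  only bulls with pseudo-phenotypes in all six traits survive, avoiding an
  animal-trait confounding in the multi-trait selection step.

A caveat recorded here deliberately: for a PTA that is itself an optimal
blend of own and parent information, de-regression necessarily loses some
correlation with the true transmitting ability — that is the price of
removing double-counted information.  The "signal is preserved" property is
therefore only asserted where it genuinely holds: when own information
dominates the PA (high reliability, low PA reliability).

## Bayes-B marker association

Model: `y = 1*mu + sum_i Z_i g_i + e`, y = dPTA, residuals
`N(0, R*sigma_e^2)` with `R_ii = 1/w_i`.  Each marker effect is zero with
prior probability pi = 0.9, otherwise normal with its own
scaled-inverse-chi-square variance.  Prior scales follow
`S = sigma^2*(nu-2)/nu`, with (nu = 4, sigma^2 = 5) for marker variances
and (nu = 10, sigma^2 = 3) for the residual — both priors then have mean
sigma^2.  Assigning nu = 10 to the residual and nu = 4 to the markers is a
documented package choice; both assignments are exposed in configuration.

The sampler is single-site Gibbs with a joint Metropolis-Hastings update of
each marker's (indicator, variance) pair, proposing from the prior so the
acceptance ratio is the marginal likelihood ratio with the effect
integrated out.  Default chain 40,000 with 5,000 burn-in; the tested
instances use shorter chains (stated per test) after verifying that
summaries from different chain lengths correlate above 0.99.  Posterior
mean effects average over all post-burn-in samples including zeros, which
keeps PV_g comparable across markers:

    PV_g = 2*p*(1-p)*abar^2 / sum_j 2*p_j*(1-p_j)*abar_j^2

Marker QC removes MAF < 0.05 and call rate < 0.90 (both strict) and imputes
surviving missing codes to the marker mean.  Per trait, markers at or above
the 75th PV_g percentile are retained; the threshold is the ascending order
statistic at index floor(0.75*m) and ties at the threshold are kept, so
45,188 distinct values retain exactly 11,297.

Calibration evidence computed by the suite: with data simulated from the
prior at pi = 0.9 the mean per-iteration inclusion fraction is 0.10 ± 0.01;
on 300 bulls x 1,000 markers with 20 QTL at h2 = 0.5 the posterior-mean
effects correlate with truth at 0.83–0.89 across ten seeds; pure-noise data
never concentrate PV_g (max < 0.5).

## SNP-to-gene mapping and QTL overlap

Coordinates are 1-based inclusive.  A SNP maps to every gene whose interval
extended by 2,500 bp on each side contains it (boundary distance, not TSS;
strand is ignored); all qualifying genes are retained, with a flag-gated
nearest-only mode.  A gene lies "within" a QTL only under full containment;
partial overlap is flag-gated.  Both operations are verified against naive
double loops.

## Association weight matrix

Per breed, the six per-trait significant sets feed three selection
criteria: (a) significant in all six traits, (b) in all functional traits
(DCD, MCD, GL), (c) in all type traits (STAT, STR, RW).  One row per gene
(largest mean PV_g across traits among its mapped selected SNPs; exact ties
break by genomic order for reproducibility); unmapped SNPs enter as their
own rows only under criterion (a).  Cells are posterior-mean effects
z-scored within trait columns over the AWM rows (population SD); the
standardization set is a documented choice — the matrix itself is the
analysis object — and signs are preserved because the network lives on
signed co-association.

## PCIT network inference

For every trio of AWM rows the three first-order partial correlations are
computed and the local tolerance is the mean of the partial-to-direct
ratios; the edge x–y is removed when some z gives
`|r_xy| <= eps*|r_xz|` and `|r_xy| <= eps*|r_yz|`.  Surviving edges carry
the direct correlation as weight.  Trios with a unit or zero direct
correlation are skipped (partial or ratio undefined).  The implementation
(O(n^3), numba-accelerated) is tested for exact edge-set equality against a
plain-Python exhaustive enumeration on random instances.

With only six trait columns, row correlations are noisy; no additional
significance test is layered on — the analysis relies on PCIT plus
trimming to |r| >= 0.98.  Trimming uses the absolute value by default (a signed mode
exists): with 6-point rows a strong negative co-association is as
informative as a positive one.

## Across-breed statistics

The intersection of breed networks (genes with at least one retained
connection) is tested exactly: each network's gene set is modelled as an
independent uniform draw without replacement from a common universe
(default: the number of SNP-mapped genes).  The intersection of the first
two sets is hypergeometric, and each further set applies another
hypergeometric kernel to the current intersection size; chaining the
kernels gives the exact distribution, accumulated in log space so tails far
below 1e-300 survive.  The two-set case collapses to the hypergeometric
survival function (checked to 1e-12) and the three-set case matches Monte
Carlo.  For the published configuration (sets 1,272/1,454/1,455, universe
8,599, k = 80) the tail probability is 4.1e-11.

Degree sequences are tested against a discrete power law by the
Clauset-Shalizi-Newman procedure: x_min by KS minimization, exponent by
maximum likelihood on the tail, p-value by semi-parametric bootstrap (100
replicates by default, seeded).  Hub reports list the top fraction of nodes
by degree that carry a QTL assignment.

## Relationship matrices and GBLUP

BASE/TOP25/BOT75/NET/FREE are VanRaden method-1 matrices
`G = MM'/(2*sum p(1-p))` on their marker sets; allele frequencies come from
the analysed bulls (base-generation frequencies are unobservable).  TOP25
holds markers in the per-trait top PV_g quartile for at least three of six
traits; NET holds the AWM source markers.  CONN is `G = ZDZ'` with Z
centered and scaled per marker and D the gene-gene correlation structure:
unit diagonal, trimmed-network edge weights off-diagonal (a flag switches
to untrimmed PCIT correlations).  D is the network-derived correlation
structure rather than the m x 6 AWM itself, which cannot play that role
dimensionally.  An indefinite D is replaced by its nearest PSD projection
(eigenvalue clipping, diagonal restored, distance logged) because an
indefinite kernel breaks the sampler.  CONN is then rescaled by an affine
map matching mean diagonal and mean off-diagonal to BASE — the
allele-frequency-free normalization.

GBLUP fits `y = 1*mu + sum_k g_k + e`, `g_k ~ N(0, G_k*sigma_k^2)`,
weighted residuals as in the GWAS.  Each kernel is eigendecomposed once and
the genetic vector reparameterized into iid coordinates, so the Gibbs
sampler is single-site with O(n) updates and singular kernels need no
repair.  Variance priors are scaled-inverse-chi-square (df 5) with scales
from an even split of half the phenotypic variance across kernels;
residual weights are used in fitting by default (`use_weights=False`
reverts to unweighted).  Default chain 20,000/5,000; the fixed-variance
posterior mean matches the direct GLS-BLUP solution within 0.01 RMSE at
n = 50.

Cross-validation masks one pedigree family at a time: k-means (seeded,
10 restarts) on the rows of the numerator relationship matrix A builds
k = 4 families, a documented reading of "k-means medoids" with the A-row
profile as the representation.  Within each fold the GWAS, AWM, network and
marker partitions are rebuilt from training records only; kernels span all
bulls (genotypes carry no phenotype information).  Accuracy is the plain
Pearson correlation between predictions (intercept plus genetic effects)
and the masked dPTAs; folds with fewer than three usable validation records
are skipped.  A canary test asserts the leakage guarantee bit-for-bit.

Model grid (one or two kernels): 1 BASE; 2 TOP25; 3 TOP25+BOT75; 4 NET;
5 NET+FREE; 6 CONN; 7 CONN+FREE.

## Synthetic populations

The generator emulates the data structure the chain assumes, per breed:

- one generation of paternal half-sib families (default 25 sires, 40
  progeny each); dams are unobserved Hardy-Weinberg founders, so each
  bull's maternal allele is drawn at the founder frequency; the maternal
  grandsire is recorded for PA fallbacks but contributes no gametes;
- biallelic markers with founder MAF uniform in [0.05, 0.5], Mendelian
  gene-drop, no linkage by default (an optional block-LD mode copies
  ancestral haplotypes in windows);
- gene intervals placed so a configurable fraction of markers lies within
  2,500 bp of a gene (exact at 0 and 1), QTL intervals covering a
  configurable fraction of each chromosome;
- six traits with sparse marker effects (zero with probability
  pi_qtl = 0.9, matching the GWAS prior), multivariate-normal across traits
  under a configurable genetic correlation matrix.  Because only ~0.1*m
  markers carry effects, the realized genetic covariance is noisy at the
  QTL-sampling level (~1/sqrt(n_qtl)) no matter how many bulls are
  simulated, so the generator moment-matches: the realized TBV covariance
  is linearly transformed to the target exactly — variances to the
  configured heritabilities (phenotypic variance 1; defaults
  0.1/0.1/0.5/0.4/0.4/0.4 for DCD/MCD/GL/STAT/STR/RW) and correlations to
  the configured matrix — falling back to variance-only scaling when fewer
  QTL than traits make the covariance singular;
- PTAs equal to TBV/2 plus noise sized so corr(PTA, TBV/2)^2 equals a
  per-record reliability drawn uniformly in a configurable range.  The real
  traits' genetic correlations are not published, so the default matrix
  (0.3 within the calving block, 0.5 within type, 0.2 across) is a
  generator choice, not a calibration to any real population.

What passing tests do not show about real data: the generator has no
linkage disequilibrium beyond family structure by default, no breed
divergence, no selection, and its PTAs are not PA-blended evaluations, so
absolute prediction accuracies and network sizes on synthetic data do not
transfer to real populations.  What the tests do establish is the internal
correctness of every stage (oracle equivalence, exact distributions,
calibrated recovery) and the integrity of the cross-validation.

## Problem sizes used by the test suite

Simulation sizes are chosen per test to exercise each property at the
smallest scale where it is informative: generator calibration at 2,000
bulls; Bayes-B recovery at 300 bulls x 1,000 markers with 10,000-sample
chains; the end-to-end demo at 500 bulls x 2,000 markers with six traits,
models 1–7 and 4 folds, using shortened chains after the chain-length
robustness check.  Default chain lengths for production use remain
40,000/5,000 (GWAS) and 20,000/5,000 (GBLUP).

## Known limitations

- The sampler-level reproducibility contract is per-process and
  per-library-version (numba and NumPy RNG streams).
- The exact intersection test assumes uniform, independent network
  membership across breeds; biological non-uniformity makes the reported
  p-values conservative statements about chance overlap only.
- GO/pathway enrichment, human-homolog mapping and real-genome annotation
  retrieval are out of scope.
- The power-law bootstrap uses a continuous approximation for discrete
  tail sampling, adequate for the descriptive use made of it here.
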