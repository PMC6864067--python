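# Methods

This note documents the generative model behind the couple simulator, the
estimators, the numerical conventions, and the design choices made where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The couple simulator

### Individuals

Each cohort draws `n_individuals`, split evenly into males and females.
Geography is a planar km grid (default 1000 km northing × 600 km easting,
UK-like): `n_centres` recruitment centres are placed uniformly, each person is
attached to a centre and born at the centre plus isotropic Gaussian scatter
(`migration_sd_km`, default 60).

The focal variant emulates a low-frequency, large-effect alcohol variant
(rs1229984-like). Its minor-allele frequency follows a logistic cline,
`logit p(x) = logit(maf_focal) + g_n·(north − mid) + g_e·(east − mid)`, with
default gradients (−3×10⁻⁴, +1.6×10⁻⁴) logit/km so that the major (effect)
allele is more common in the north/west and the implied km-per-allele
association is of the order of tens of km — matching the published geographic
associations in sign and scale. Genotypes are binomial at the *local* p, so
every neighbourhood is in Hardy-Weinberg equilibrium while pooled samples show
a Wahlund heterozygote deficit. Note the deficit is a weak-signal property:
at MAF 2.8% and a frequency split of ±0.01, the HWE chi-square noncentrality
at n = 200,000 is ≈ 2.7, i.e. nominal-α detection in roughly a third of
replicates; the diagnostic becomes decisive only with stronger structure or
much larger samples. `n_pgs_snps` background SNPs (frequencies U(0.05, 0.5),
no cline, no LD except an optional correlated block for pruning tests) carry
Gaussian weights rescaled in-sample so the polygenic score explains exactly
`h2_pgs` of phenotypic variance.

The latent phenotype (weekly alcohol units) is

`P = μ + β_focal·(G − E[G]) + PGS + U + ε`,

with total variance `sd_weekly_units²` (default 10²), confounder share
`var_confounder` (default 0.15), and the residual absorbing the remainder
after the focal variant's empirical contribution; an infeasible budget raises
a configuration error. Defaults μ = 11 units/week, β_focal = 3.99 units per
major allele, h²_pgs = 0.10 reflect the published phenotype scale, stage-one
effect size, and the ~13% common-variant heritability of self-reported
consumption.

Observed weekly units are left-censored at zero (configurable) and then
decomposed into integer beverage counts (measures of spirits = 1 unit,
glasses of any wine = 2, pints of beer/cider = 2.5); the recomposed total *is*
the analysed `weekly_units`, so the unit-derivation contract holds exactly and
the decomposition's ±0.5-unit rounding is part of the measurement noise.
Censoring plus rounding attenuates the spousal correlation of observed units
by a few percent relative to the calibrated latent correlation; estimator
tests that target the exact closed forms disable censoring.

Questionnaire plumbing: intake-frequency categories are assigned consistently
with units (zero units ⇔ sub-weekly frequency, for whom intake questions are
"not asked"); drinker status, sex-specific height, education leaving-age with
degree flag, country of birth, and parental ages at death (30% missing) are
drawn independently — they exist to exercise covariate handling and the
derivation filters, not to model real covariance with drinking.

### Couple formation (the four mechanisms)

- **assortative** — matching score = standardised latent phenotype plus
  Gaussian noise; both sexes are sorted by score and paired by rank. The
  noise SD is calibrated by bisection, reusing the same noise draws across
  bisection steps and the final pairing, so the realised spousal correlation
  of the pairing basis lands on `assort_C` to ~10⁻⁴. An unreachable target
  (e.g. C ≈ 1 at small n) falls back to exact rank pairing with a log
  warning.
- **homogamy** — identical machinery applied to a basis that is *not* the
  phenotype: the genotype-independent confounder U (default), giving spousal
  phenotype correlation ≈ C·var_confounder with zero genetic signal; or, with
  `homogamy_basis="geography"`, the birth-location projection along the cline
  axis, which induces genotypic concordance through shared local gene pools.
- **interaction** — random pairing, then convergence of observed phenotypes:
  `A_obs = (1−w)·latent + w·couple_mean` with `w = min(1, κ·duration)`
  (κ default 0.03/year; duration U(0, 40) years). Genotypes are untouched.
- **dissolution** — random pairing, then couples dissolve with probability
  `logistic(α + λ·|ΔA_obs|)` (α = −3, λ = 0.15 per unit): ~10–25% dissolve
  and surviving couples are more concordant than the pre-dissolution
  population. Dissolved members stay in the cohort as non-cohabiting
  singles.

Mixtures act sequentially: formation on a weighted blend of the assortment
and homogamy bases, then interaction scaled by its weight, then dissolution.
Mean couple age is `44 + 0.5·duration + noise`, so mean age proxies duration
as the relationship-length analysis assumes; the spousal age-correlation and
duration distribution are package choices (no published values exist for
them).

Randomness: one master seed spawns named child streams in a frozen order
(geography, focal genotypes, PGS genotypes, weights, confounder, residual,
pairing, duration, interaction, dissolution, household, beverages,
covariates); identical configs reproduce byte-identical cohorts.

### Decoys

`inject_decoys` *appends* freshly simulated non-spouse records — same-sex
cohabiting pairs, opposite-sex full-sibling pairs with Mendelian-transmitted
genotypes (expected GRM 0.5), and trios sharing one household key — rather
than re-using cohort members, because every simulated individual already
belongs to a true couple. Sibling decoys carry missing parental-death ages
(non-response), so they pass the parental-death filter and are caught by the
GRM step; siblings who reported shared parental death ages would be caught
earlier, which is precisely that filter's purpose.

## Spouse-pair derivation

Candidates must cohabit with a spouse, be genotyped, and agree exactly on
eight household fields (years at address, occupants, vehicles, accommodation
type, rental status, home north/east rounded to integer km, recruitment
centre). Keys shared by >2 people are discarded outright. Filters then run
in order — same-sex, parental-death (both parents' ages of death equal and
non-missing across the pair), and relatedness — each logging per-individual
reasons and per-step counts in a ledger. The same-sex and parental-death
filters commute; relatedness runs last, matching the published order.

Relatedness uses the GRM estimator
`(1/M)·Σ_i (g_ij − 2p_i)(g_ik − 2p_i)/(2p_i(1−p_i))` over an LD-pruned marker
pool (greedy 50 kb windows, 5 kb steps, r² < 0.1; earlier variant kept), with
allele frequencies from the candidate-pair sample itself and missing dosages
mean-imputed (zero contribution). Pairs with estimate strictly > 0.1 are
excluded — the threshold is taken verbatim as strict. Sampling SD is ≈ 1/√M,
so a ≥1,000-marker pool keeps false exclusions of true couples below ~0.2%;
a warning fires below 100 markers.

## Estimators

Concordance analyses use one row per couple with the reference member chosen
by a seeded coin flip (estimates are invariant to the flip up to sampling
symmetry, which is asserted in tests); MR stages use two rows per couple
(both orientations), as in the source design. Standard errors are
conventional OLS/Logit (an HC-robust switch exists but is off by default, to
mirror the published analyses); confidence intervals are beta ± 1.96·SE and
p-values come from the normal approximation for consistency with them.

MR estimator conventions:

- **Wald ratio**: β_GY/β_GX with first-order SE `se_GY/|β_GX|` (the published
  CI scaling); a second-order option adds the exposure-stage term.
- **IVW (fixed effects)**: weights β_GX²/se_GY² on the ratio scale; Cochran's
  Q on k−1 df; I² = max(0, (Q−(k−1))/Q).
- **MR-Egger**: weighted regression of β_GY on β_GX with intercept, exposure
  betas oriented positive, multiplicative-dispersion floor at 1, t(k−2)
  p-values — the conventional implementation choices; requires k ≥ 3.
- **Weighted median**: inverse-variance-weighted cumulative distribution of
  the ordered ratios interpolated at 0.5.
- **Weighted mode**: argmax of the weighted normal-kernel density over
  ratios; bandwidth = `bandwidth_factor` × 0.9·min(SD, IQR/1.34)·k^(−1/5)
  (modified Silverman, factor default 1). The maximiser is located by a
  dense grid scan plus derivative root-finding at every local maximum, so
  near-tied modes resolve deterministically at machine precision.
- Median/mode SEs: seeded parametric bootstrap (default 5,000 draws) from
  N(ratio_i, se_i), weights held fixed.
- Additive-vs-dominant: both codings plus the saturated 2-df genotype factor
  are fitted; the recommendation is the better-AIC coding, or "neither" if
  the saturated model shows no association at 5%.

Principal components, when requested as covariates, come from a truncated SVD
of the centred/scaled dosage matrix (top 10), standing in for cohort-supplied
PCs.

Stratification: the HWE test is the textbook 1-df chi-square from genotype
counts (monomorphic samples return chi² = 0, flagged); allele-frequency
contrasts use the 2×2 allele-count chi-square without continuity correction;
the within-centre meta-analysis excludes strata under `min_pairs` (default
50, the operational reading of small-centre convergence failure) or with
failed regressions, then combines by inverse variance with Q across strata.
Externally supplied stratum tables use SE = (CI width)/(2×1.96); this
symmetric convention also absorbs the one published centre row whose printed
CI is asymmetric about its beta. Birth-distance stratification uses
Euclidean km on the planar grid, assigns exactly-100 km pairs to "within",
reports pairs with missing coordinates separately, and compares strata by
z-test.

One property worth flagging: under *cline-only geographic homogamy*,
restricting to couples born within 100 km does **not** attenuate genotypic
concordance — close-born spouses share a local gene pool, so the
stratification-driven concordance is strongest there, while far-born pairs
are the attenuated stratum. What removes the stratification signal is the
within-centre meta-analysis, which absorbs between-region frequency
variation; the tests assert that contrast (pooled strong, beyond-100 km
attenuated, within-centre combined near zero). That is also why the real
design stratifies by centre after the distance restriction.

## Theory oracles

`expected_correlations(C, h2)` returns C·√h² and C·h² for corr(G_I, P_partner)
and corr(G_I, G_partner) under joint normality with single-round assortment on
the phenotype — the standard linear-projection result, validated empirically
against the simulator over a (C, h²) grid at 50,000 couples (3 Monte-Carlo-SE
agreement, censoring disabled) rather than asserted axiomatically.
`mr_rescaling_check` exhibits the cancellation that makes the Wald ratio
estimate C regardless of h². A corollary the worked example demonstrates:
for an instrument explaining <1% of variance, the per-variant spousal
concordance expected from assortment alone (C·ρ² ≈ 0.003) is far below what
biobank-scale analyses report for rs1229984, so observed single-SNP
concordance of that size implies contributions beyond phenotypic assortment,
e.g. fine-scale structure.

## Problem sizes and numerical conventions

Test and acceptance runs use 20,000 couples for mechanism discrimination,
50,000 couples per cell of the theory grid, 1,000-marker GRM panels, 2,000
replicates for Q calibration, and 100 replicates of 200,000 individuals for
the Wahlund property — sizes at which Monte-Carlo error is comfortably inside
the asserted tolerances while the whole suite runs in well under a minute per
module. Floating-point outputs in pipeline tables are written at 6
significant digits; ties in LD pruning keep the earlier variant; degenerate
regressions (constant exposure) return an exact zero slope where the estimand
is zero by construction and raise a data error where it is undefined
(monomorphic variant, zero-variance score).

## Known limitations

The simulator's covariates are independent of the phenotype, so covariate
adjustment is exercised but not stress-tested against real confounding
structure; LD is absent except the optional test block, so the pruning step
sees an easy problem; single-round assortment only (no multi-generation
equilibrium); the dissolution model is memoryless in duration; and passing
tests on simulated cohorts demonstrates estimator correctness under the
stated generative model, not the behaviour of the derivation on real
household data, where field-agreement noise and non-spouse cohabitation
patterns are richer than anything generated here.
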