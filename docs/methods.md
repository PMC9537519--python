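# Methods

`cnvmod` estimates whether germline deletions and duplications modify
breast cancer risk in *BRCA1*/*BRCA2* pathogenic-variant carriers, using
cohorts that were recruited through genetics clinics and are therefore
non-randomly sampled with respect to disease status. This note records
the statistical model, the corrections for that ascertainment, what the
synthetic-data generator does and does not emulate, and the numerical
and design choices that were genuinely open.

## Disease model

Each carrier is followed from birth to the age at first breast cancer
diagnosis, or to censoring at ovarian cancer diagnosis, bilateral
prophylactic mastectomy, or last observation — whichever comes first.
Only breast cancer counts as an event; ovarian cancer and mastectomy are
censoring. The age-specific hazard for subject *i* is proportional:

    lambda_i(t) = lambda0(t) * exp(beta * g_i),

where `g_i` is a 0/1 gene-region CNV indicator (or, in the
mutation-type model, indicators for a deletion/duplication pathogenic
variant class), and `lambda0` is a piecewise-constant carrier incidence
supplied as configuration (an `IncidenceTable`, per-year hazards over
age bands; the shipped default is a BRCA1-carrier-style curve whose
cumulative risk to age 80 is ≈71%). Its integral Λ0(t) is piecewise
linear and is evaluated exactly; no extrapolation beyond the table is
ever performed.

## Retrospective-likelihood score test

Clinic recruitment oversamples affected carriers, so the prospective
likelihood of (δ, t) is biased. Conditioning the genotype on the
observed phenotype removes the bias: with stratum-specific carrier
frequency p_s as nuisance,

    P(g | delta, t) ∝ p_s^g (1-p_s)^(1-g) * exp(delta*beta*g) * exp(-Λ0(t) e^{beta g}),

(the λ0(t)^δ factor cancels). The score for β at β = 0 is
(g_i − p_s)(δ_i − Λ0(t_i)). Profiling p_s out (its MLE at the null is
the stratum carrier fraction p̂_s) projects the score orthogonal to the
nuisance direction and yields the *efficient* per-subject score

    u_i = (g_i − p̂_s) * (r_i − r̄_s),      r_i = delta_i − Λ0(t_i),

with r̄_s the stratum mean of the martingale residuals. The centring
leaves the total U = Σ u_i unchanged (the extra term cancels against
Σ(g − p̂) within stratum) but it is essential for the variance: under
clinic ascertainment the residuals r_i have a large positive mean, and
an uncentred cluster-robust variance estimate overstates Var(U) several
fold, making the test severely conservative (empirical size ≈0.014 at
nominal 0.05 in our null simulations; ≈0.05 with centring).

Relatives share CNV genotypes, so the variance is family-clustered:

    V = Σ_families ( Σ_{i in family} u_i )²,

and U²/V is referred to chi-square(1). The hazard ratio is approximated
by a one-step estimator from the null, β̂ = U/I with model information
I = Σ p̂_s(1−p̂_s)(r_i − r̄_s)², se(β̂) = √V / I, and Wald 95% limits.
The one-step is a quadratic approximation around β = 0; on 20-subject
fixtures with moderate effects it stays within 0.15 of the grid-search
maximiser of the full retrospective log-likelihood (`retro_mle_grid`,
which profiles p on an inner grid over β ∈ [−2, 2]); for extreme
estimates on tiny samples it can overshoot, which is why the package
reports it as an approximation and the score-test p-value as primary.

Strata are the cross of country and Ashkenazi-Jewish ancestry. Strata
with fewer than two carriers of the tested CNV are pooled into one
residual stratum before centring, to avoid degenerate genotype means.
Regions with fewer than two carriers overall are not tested. A genotype
monomorphic within every stratum gives U = 0, p = 1 and an undefined
(NaN) hazard ratio. Conflict-excluded subjects (below) enter as NaN
genotypes and are dropped from that region's test only.

## Weighted-cohort hazard model

The second engine estimates deletion and duplication effects (of the
clinically diagnosed pathogenic-variant class) in one Cox model with age
as the time scale, baseline stratified by country × Ashkenazi ancestry,
fixed effects for birth cohort and genotyping array, and a sandwich
variance clustered on families. Exposure codings: `del_vs_other`
(duplications retained as a third level), `dup_vs_other_excl_del`
(deletion carriers removed), `three_level`. Reference level is always
"other". The fit is delegated to `lifelines.CoxPHFitter` (weighted
partial likelihood, Efron tie handling; event ages in this package are
continuous so ties do not arise).

Ascertainment is corrected by weighting: within 5-year age-at-exit bands
(18, 25, 30, …, 80), affected subjects receive weight `expected/f` and
unaffected `(1-expected)/(1-f)`, where `f` is the observed affected
fraction in the band, so the weighted affected fraction equals the
expected one exactly. The expected fraction is *not* simply the
penetrance F at the band's ages: among subjects whose follow-up *ends*
in a band, the affected/unaffected mix also depends on the censoring-age
distribution. Because unaffected carriers are recruited with a
probability that does not depend on their own event timing, that
distribution is recoverable from the unaffected band counts u_a:
censoring mass g_a ∝ u_a / (1 − F(mid_a)), censoring survival S_c by
partial sums, and

    expected_a = dF_a * S_c(mid_a) / ( dF_a * S_c(mid_a) + g_a * (1 − F(mid_a)) ).

Under random sampling this reproduces the observed composition and all
weights are ≈1 (we verified the naive penetrance-only target attenuates
the fitted log-HR by ≈17% even without ascertainment). Bands with an
observed affected fraction of exactly 0 or 1 get unit weights with a
warning; empty bands are skipped; strata without events are dropped with
a warning.

**Known limitation.** Affected/unaffected band weights can only undo
selection that acts through individual disease status. When whole
families are ascertained through an affected proband and the exposure is
shared within families (as a pathogenic-variant class is), the implied
inverse-sampling ratio depends on the exposure itself and the estimator
retains a conservative bias; in simulations with *pure* proband-affected
sampling of sibships and a true HR of 1.5 the mean log-HR is attenuated
by ≈0.09–0.13. Under the default clinic-style ascertainment (below),
which matches the ~50% affected fraction of real carrier cohorts, the
residual attenuation is ≈0.03–0.04.

## CNV pipeline conventions

* Coordinates are 1-based closed internally (PennCNV convention); BED
  I/O shifts at the boundary. Chromosomes 1–22 and X only; Y rejected.
* Sample QC excludes a sample when any criterion is breached, with the
  comparison strictness applied literally: LRR sd > 0.28, BAF drift
  > 0.01, |waviness| > 0.05, LRR outliers > 0.1, BAF sd ≥ 0.2, LRR sd
  ≥ 0.4, or more than 100 CNVs. Both LRR-sd cutoffs are applied; the
  stricter dominates. cn=2 records are errors, not silently dropped.
* Calls need ≥5 probes. Neighbouring same-(sample, chromosome, type)
  calls merge when gap/span < 0.2, where gap counts the bases strictly
  between them and span is the merged extent end−start+1 (the "total
  length of the combined CNVs" is read as the merged span, matching
  PennCNV `clean_cnv` semantics); probe counts add; passes repeat to a
  fixed point so merges can cascade. The operation is idempotent and
  order-insensitive.
* A gene region scores a genotype when a call overlaps it by ≥1 bp
  (interval-tree index; verified against quadratic brute force). A
  (subject, region) pair is excluded when a deletion and a duplication
  both hit the region without overlapping each other; a mutually
  overlapping pair is not treated as a conflict. Hypervariable gene
  families (HLA, immunoglobulin superfamily, olfactory receptors) are
  dropped via a user-supplied symbol list, since they are named by
  family, not coordinates.
* The effective-test threshold is alpha divided by the number of regions
  with at least one overlapping CNV of the tested type, displayed to one
  significant figure (printed-table style).
* Concordance: a call is supported by a truth interval under ≥1 bp
  same-type (optionally same-individual) overlap; "sensitivity" is
  detected/truth and the "support rate" is supported/called — the latter
  is a precision, although validation studies of array CNV calling
  often print it as "specificity". Percentages round half-up to one
  decimal. A population-CNV-map support proportion below 95% per region
  is the screen used to prioritise candidate loci.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
with everything downstream of configuration:

* **Families** are sibships of size 1–4 (default probabilities 0.35,
  0.35, 0.20, 0.10). Two unobserved parents draw CNV alleles at the
  frequency implied by the configured carrier frequency (dominant
  coding, p = 1−(1−q)²) and transmit Mendelianly — giving the positive
  within-family genotype correlation the cluster-robust variances must
  absorb. Multi-generation pedigrees and kinship matrices are not
  modelled; clusters are what the estimators use.
* **Phenotypes**: onset age by exact inversion of Λ0(t)e^{βg} = −log U;
  independent uniform censoring (default ages 25–80) plus an independent
  exponential competing-event clock (default 0.005/year) for ovarian
  cancer/mastectomy; subjects whose follow-up would end before age 18
  fail recruitment eligibility and are dropped. The default carrier
  frequency is 0.05 per region and regions alternate deletion/
  duplication types.
* **Ascertainment** modes: `random`; `proband_affected` (a family is
  retained only if its first-listed eligible member is affected); and
  the default-for-examples `clinic`, a 75/25 mixture of proband-affected
  and cascade-tested families. The mixture weight was set so the
  retained cohort is ≈50% affected, the composition of real carrier
  cohorts; pure proband sampling yields ≈65–70% affected.
* **Calling errors**: each true CNV (gene-region CNVs, extended by a
  random flank up to 20 kb, plus the diagnostic BRCA1/2 CNVs carried by
  deletion/duplication mutation-type families) is detected with
  type-specific sensitivity (defaults 0.90 deletions, 0.75
  duplications); probe support is Poisson(0.17 probes/kb × length,
  minimum 1), an OncoArray-like density so that short CNVs realistically
  fail the five-probe filter; false calls arrive per genome at
  type-specific rates (defaults 0.3, 0.6) at random positions; a
  configurable fraction of samples (default 2%) draws QC-failing LRR
  dispersion. Breakpoints are exact by default (array breakpoints are
  probe-quantised; a jitter knob exists).

What the generator does **not** emulate: linkage disequilibrium and
locus-specific CNV frequency spectra, recurrent rearrangement hotspots,
batch/plate effects correlated across samples, informative censoring
(competing events are independent by assumption), residual familial
frailty beyond the shared genotype, and real pedigree depth. Passing
tests therefore demonstrate the statistical machinery — calibration
under phenotype-driven ascertainment with family clustering — not
robustness to those data pathologies.

## Problem sizes and numerical choices

* Null calibration runs 5,000 replicates of 2,000 subjects (sibships of
  two, proband-affected, carrier frequency 0.2) in the test suite and
  2,000 replicates in the acceptance script; the weighted-model recovery
  uses 100 (script: 40) ascertained cohorts of 20,000 subjects with a
  true deletion HR of 1.5. These sizes give Monte-Carlo standard errors
  of ≈0.003 on the size and ≈0.003 on the mean log-HR while keeping a
  full run to a few minutes on one core.
* The likelihood-grid oracle uses 801 β points on [−2, 2] × 197 p points
  on [0.01, 0.99].
* Random draws all flow from one `numpy` Generator seeded from the
  `SimConfig`; identical configurations are byte-identical, and derived
  seeds stay below 2³¹.
* Merged calls with differing copy-number states record an unknown copy
  number; the type never mixes.
* Weight computation clips ages into the band range and treats the last
  band as right-inclusive.
* `AssocResult` enforces ci_low ≤ HR ≤ ci_high at construction; p-values
  are upper chi-square tails, so p and U²/V are monotonically related by
  construction.

## Limitations

The score test's hazard-ratio is a one-step approximation — accurate for
moderate effects, primary inference should use the p-value. The weighted
cohort model inherits the family-level ascertainment limitation above.
Mutation-type effects are a three-level classification; variant-specific
risks are out of scope, as are raw-array processing, CNV calling itself,
ancestry inference and any wet-lab validation modelling.
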