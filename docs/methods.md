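# Methods

## The matched-set likelihood

For each family and SNP, the four Mendelian transmissions of the parents'
alleles form a 1-case : 3-pseudo-control matched set. Conditioning on the
set, the case's contribution to the log-likelihood under the additive model
with design row x(G, E) = (G, G·E_1, …, G·E_k) is

    l_s(β) = x_case′β − log Σ_{j=0..3} exp(x_j′β).

Sets whose four member genotypes coincide (both parents homozygous) carry no
information at any β and are excluded from both the fitted and the null
likelihood; the null (empty) model assigns each member probability 1/4, so
ll_null = n_informative · log(1/4). Exposures are maternal attributes shared
by all four members, so an exposure main-effect column is constant within
every set: it is structurally inestimable, and the model refuses it
explicitly (`InestimableError`) rather than silently absorbing it. The same
check catches interaction columns that are identically zero (e.g. an
exposure nobody reports).

Interpretation of coefficients: exp(β_g) is the one-copy odds ratio for
carriers vs non-carriers among trios unexposed to every modelled factor;
exp(β_g + Σ β_{g×e_i} E_i) the analogue within exposure stratum E; two-copy
ORs are the squares. Risk for exposed carriers is only identified relative
to exposed non-carriers — contrasts across exposure strata are not
estimable in this design, which is why no exposure main effect appears.

## Fitting and inference

* Newton–Raphson from β = 0 with step-halving (the conditional
  log-likelihood is concave, so halving guarantees monotone ascent);
  convergence when max|score| < 1e-8, at most 100 iterations.
* Covariance = inverse observed information at the MLE; 1-df Wald test of a
  contrast c is (c′β̂)² / (c′Σc); the LRT against the empty model has
  df = 1 + k.
* Separation: when any |β| exceeds 15 before convergence (e.g. every
  informative case carries the extreme genotype) the fit is flagged, SEs are
  reported infinite and the SNP is treated as non-estimable downstream.
* A singular information matrix (within-set collinear columns) is reported
  as inestimable, not regularised.

The tests cross-check the fitter against a 1-D optimisation of the
likelihood written independently (closed form exp(β̂) = T/U on
single-heterozygous-parent matings) and against statsmodels'
`ConditionalLogit` on a shared fixture (coefficients, SEs, Wald p to 1e-6;
note statsmodels keeps uninformative groups, each contributing log(1/4) to
its log-likelihood, so totals differ by exactly that constant).

## Marker QC

All QC statistics use the parents (founders); thresholds default to
MAF < 0.01, call rate < 0.95 (over all 3n members), Mendelian error rate
> 0.05, and an exact Hardy–Weinberg test at α = 0.05/m for an m-marker
panel. Choices worth stating:

* **HWE exact test**: conditional on the allele counts, summing the
  probabilities of all heterozygote counts whose configuration is no more
  probable than the observed one (two-sided "at most as probable" rule, no
  mid-p). A marker *fails* when p < α. Verified against full enumeration
  for all totals ≤ 20.
* **Minor-allele fixing**: dosages are read against the lexicographically
  smaller allele and flipped (d → 2 − d, labels swapped) when its parental
  frequency exceeds 0.5; an exact tie keeps the lexicographically smaller
  label as minor, for determinism.
* **Mendelian errors**: a trio-SNP genotype inconsistent with transmission
  is counted in the error rate and then blanked (all three members set
  missing) before analysis — standard trio hygiene.
* **LD de-duplication**: r² is computed from EM-estimated haplotype
  frequencies on pairwise-complete parents (phase resolved only for double
  heterozygotes); within each r² = 1 group the first marker in map order is
  kept. Monomorphic input yields r² = 0 by convention.
* Complete-case handling is per SNP and per model: a trio missing one
  exposure still enters models that do not use it, so the analyzed trio
  count varies across SNPs and exposure subsets.

## The synthetic-data generator

Parents are drawn Binomial(2, MAF) independently (HWE, no inbreeding or
stratification); each parent transmits one uniformly chosen allele;
maternal exposure combinations follow a configurable joint distribution
(default: independent exposures at rates typical of Asian trio consortia —
ETS 38.2%, VIT 15.0%, SMK 2.9%, ALCOHOL 2.2% — with MAF defaulting to
0.20). Ascertainment of affected children uses rejection sampling with
acceptance probability exp(η − η_max), η = β_g G + Σ β_{g×e_i} G·E_i: the
rare-disease multiplicative model, under which the conditional-logistic ORs
equal the simulated relative risks without specifying a baseline
penetrance. Per-stratum OR input is converted to coefficients as
β_g = log OR_ref and β_{g×e_i} = log(OR_i / OR_ref).

What the generator does *not* emulate: linkage between markers (extra panel
SNPs are independent), parental assortment, parent-of-origin effects,
genotyping-error structure beyond uniform child-dosage replacement, and
informative missingness (missingness is uniform). Passing simulation-based
tests therefore validates the estimators under the design's own
assumptions, not robustness to those real-data complications.

Determinism: every simulation and power run is reproducible from a single
integer seed; injected missingness and Mendelian errors consume the same
generator stream.

## Power estimation

`estimate_power` simulates replicates of the configured design, runs the
requested test (gTDT Wald, joint LRT, or a stratum Wald contrast) and
reports the rejection fraction with its binomial Monte-Carlo SE;
non-estimable replicates count as non-rejections and are reported
separately. For stratum tests both a *full-design* mode (all strata
simulated, contrast tested inside the joint model) and a *subgroup-only*
mode (only that stratum's trios simulated, G-only test) are available,
since an analytic power tool fed per-stratum inputs could be read either
way.

Problem sizes used by the test suite and acceptance script — 2,000 null
replicates of 500 trios for type-I error, 300 replicates of 2,000 trios for
coverage, 10,000 replicates of 89 trios for the small-cohort power — were
chosen to keep Monte-Carlo SEs a few times smaller than the tolerances
being checked.

**Finite-sample behaviour of the Wald test.** At small n and very small α
the Wald and LRT rejection rates separate. For 89 trios at MAF 0.188 and
per-allele OR 0.72 tested at α = 0.05/117, the replicate Wald z-statistics
have mean ≈ −1.15 — implying an *asymptotic* two-sided power of ≈0.9% —
but the realised Wald rejection rate is ≈0.3%, with the LRT at ≈0.8%.
The gap is the well-known far-tail conservatism of the Wald statistic in
logistic-type models (Hauck–Donner: SE(β̂) inflates superlinearly with
|β̂|, so extreme estimates do not yield proportionally extreme z). Analytic
power calculators work on the asymptotic scale and thus sit near the LRT
value. The package reports the simulated rejection rate of the test it
actually runs.

## Known limitations

* Autosomal biallelic SNPs only; no dominant/recessive codings, no
  haplotype or parent-of-origin tests, no robust variances.
* The empty-model LRT convention means "2-df" and "3-df" tests include the
  genotype term; nested comparisons between non-empty models are supported
  but must share the same matched sets.
* Bonferroni correction is the only multiplicity adjustment provided; m
  defaults to the number of SNPs tested in the run and should be set
  explicitly when reproducing a published panel count.
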