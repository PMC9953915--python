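# Methods

## The ME pooled-screening model

Group testing for a rare variant treats each individual as a carrier with
probability `p` (carrier = at least one copy of the mutant allele; under
Hardy–Weinberg with mutant-allele frequency `q`, `p = 1 − (1 − q)²`, and for
the low frequencies this package targets `p ≈ 2q`). Screening pools of `n`
and retesting members of positive pools costs, in expectation,

    E[RT](n) = N/n + N · (1 − (1 − p)^n),   n ≥ 2;   E[RT](1) = N.

Two conventions matter and are fixed as follows:

* **`p` is a per-individual carrier probability**, not a per-allele
  frequency. The per-allele reading (replacing `(1−p)^n` with `(1−p)^(2n)`)
  gives different optima and reaction counts and is not what the design
  tables of this workflow imply.
* **Continuous pool count for the objective, integer layout for the
  screen.** The optimizer treats `N/n` as continuous; the predicted reaction
  count `pRT` is the ceiling of the optimum. The simulator, by contrast,
  builds `⌈N/n⌉` pools with a short final pool, whose positivity probability
  uses its actual size. `expected_realized_rt` gives the exact expectation
  of that integer layout; it coincides with `E[RT]` whenever `n | N` and
  differs by well under 1.5 reactions at the design points of interest.

The integer minimizer is found by exhaustive scan over `n ∈ [2, n_max]`
(default `n_max = 64`); ties within float tolerance resolve to the larger
pool (fewer pools to pipette). For `p ∈ [0.001, 0.1]` the minimizer sits
within 1 of `round(1/√p)`. At `p ≥ 0.5` the design warns: no pool size beats
individual testing.

Pool-level screening errors are modelled as independent flips of the pool's
true status (false-positive rate for variant-free pools, false-negative rate
for pools containing a carrier). Individual retests are error-free — no
retest error data exist for this workflow — so a false-positive pool only
wastes reactions, while a false-negative pool silently miscalls its carriers
as homozygous reference. That leakage is deliberate and measurable: the
recovery tests quantify it at zero error, and the simulator exposes it at
nonzero error.

## The synthetic herd

The generator emulates the study cohort the pipeline is meant for: 640
animals (172 male, 466 female, 2 of unknown sex), two biallelic InDel loci
with rare-mutant frequencies 0.052 and 0.009, and complete coupling
(D′ = 1) between the two mutant alleles.

* **Genotypes.** Each individual receives two haplotypes drawn iid from the
  four-haplotype distribution built from the marginal mutant frequencies and
  a target D′: `D = D′ · Dmax`, `Dmax = min(p_A(1−p_B), (1−p_A)p_B)` for
  positive coupling (sign configurable via `coupling="repulsion"`; which
  phase the real population carries is not identifiable from summary
  statistics, so it is a knob, not a constant). Scaling by the tightest
  admissible bound makes every (frequencies, D′) combination feasible by
  construction. Collapsing haplotype pairs to unordered genotypes yields
  Hardy–Weinberg proportions at each locus automatically.
* **Traits.** A trait spec maps genotype → (mean, SE, n) as association
  tables report them; values are drawn `Normal(mean, SE·√n)` — the group SD
  recovered from the standard error — truncated at 0 kg by resampling
  (carcass weights are non-negative; at the configured means the truncation
  is inactive in practice). Sex restriction and a missingness rate reproduce
  the varying per-trait `n` of real report tables. The two unknown-sex
  animals are generated but never enter sex-stratified analysis.
* **What it does not emulate:** family/pedigree structure, farm or batch
  effects, genotype×sex interactions, trait–trait correlations, genotyping
  error, and non-normal trait distributions. Passing recovery tests on these
  herds therefore demonstrates correctness of the estimators under the
  stated model, not robustness to confounding in real herds.

## Population-genetic statistics

Allele frequencies by gene counting, `He = 1 − p² − q²`, `Ho = 1 − He`,
`Ne = 1/(p² + q²)`, and Botstein's PIC specialized to two alleles,
`PIC = He − 2p²q²` (strictly below He whenever both alleles segregate). The
HWE test is a Pearson chi-square against `(p², 2pq, q²)` on 1 df without
continuity correction — the convention of the population-genetics tools this
mirrors — with the Levene–Haldane exact test available (`hwe_exact_p`) for
the very small heterozygote counts where the chi-square approximation
thins out. A monomorphic locus reports `chi² = 0, p = 1`.

Two-locus LD uses the standard EM over the double-heterozygote phase
ambiguity: initialized at linkage equilibrium, E-step splits double
heterozygotes between cis and trans in proportion to current haplotype
frequency products, M-step re-normalizes, iterating until the log-likelihood
moves < 1e-10 (cap 1000 iterations; the log-likelihood is non-decreasing by
construction and asserted in tests). `D` is measured between the `I` alleles;
`D′ = |D|/Dmax` with the sign-appropriate bound; `r² = D²/(p_A q_A p_B q_B)`.
With either locus monomorphic the function raises rather than returning
silent NaNs.

## Association testing

* **t-test:** pooled-variance Student t by default — the classical
  "independent samples t-test" with equal variances assumed, matching the
  convention of the statistical packages this workflow mirrors — with Welch
  by flag. Two zero-variance groups with equal means give `t = 0, p = 1`.
* **ANOVA:** one-way F across groups with `n ≥ 2`; degenerate groups are
  reported (n, mean) but excluded from the omnibus test; groups with
  `n < 3` are flagged low-n but still tested, since report tables in this
  field do test n = 4 and even n = 2 groups. With two groups, `F = t²`
  exactly (asserted to 1e-9 relative).
* **Letters:** compact letter display built from all pairwise pooled
  t-tests by insert-and-absorb. Uppercase letters are used when the pattern
  separates at 0.01, lowercase when only at 0.05, none otherwise — one case
  per row, the way lettered association tables are printed.
* **Fixed-effect model:** OLS of trait on reference-coded genotype and sex.
  Per-effect F-tests come from nested-model comparisons (equivalent to
  type-III with no interaction term present). Effects that are constant
  after subsetting (sex within one stratum) are dropped and logged; the
  genotype F then reduces exactly to the one-way ANOVA F, and with two
  groups to the pooled t-test — both asserted in tests. Whether a published
  within-sex p-value came from the raw t-test or the sex-adjusted model is
  generally ambiguous; both routes are exposed.
* **Multiple testing:** none by default (matching the field's reporting
  convention for candidate-gene scans); `rows_to_frame(..., fdr=True)` adds
  a Benjamini–Hochberg column.

## Expression statistics

2^−ΔΔCt with arithmetic-mean aggregation of technical-replicate Ct values
before differencing (the method's standard convention); the calibrator
sample has RQ = 1 identically. No amplification-efficiency correction is
applied. The Pearson p-value is the exact two-tailed tail mass of
`t = r√(n−2)/√(1−r²)` on `n − 2` df; `pearson_p_from_r` exposes the same
transform for checking printed (r, n, p) triples, which is how the
published four correlation p-values (0.042, 0.018, 0.012, 0.004) are
verified to 3 decimals from their r and time-course lengths (6 adipocyte,
7 myoblast stages).

## Numerical and design choices

* Ceilings for predicted reaction counts are taken with a 1e-9 guard so an
  exactly-integer expectation is not bumped up by float noise.
* Per-stage seeds derive from the pipeline's global seed by fixed offsets,
  so one seed reproduces the whole bundle byte for byte while stages stay
  independently re-runnable.
* Genotypes are the strings II/ID/DD throughout (the vocabulary of gel
  reads); `dosage_table` exports 0/1/2 mutant-allele dosages for
  interoperability. No VCF is emitted: these are two bespoke loci without a
  carried reference assembly.
* Simulation sizes in the test suite are chosen to keep Monte-Carlo error
  a small fraction of each tolerance while the full suite runs in well
  under a minute of simulation time: e.g. 1e5 replicates per grid point for
  the reaction-count check (SE ≈ 0.08 reactions), 60 herds of 4,000 for D′
  recovery (SE of the mean ≈ 0.0025 against a 0.02 tolerance), 100 herds
  of 400 for effect-size recovery, and 1000 replicates for test
  calibration. All stochastic tests run under fixed seeds.

## Known limitations

* Single pooling round plus retests only; no multi-stage group testing.
* Two-locus EM only; no multi-allelic loci or longer haplotypes.
* The realized reaction count of a physical screen depends on lab events
  (repeat reactions, ad-hoc pool sizes, contamination) the model does not
  represent; the simulator brackets such outcomes but does not reproduce
  any specific one.
* Association machinery is deliberately small-scale: fixed effects for
  genotype and sex only — no covariates, mixed models or GWAS machinery.
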