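# Methods

## The problem

Skim whole-genome resequencing (skim WGR) genotypes many individuals at low
sequencing coverage (well under 10x) and accepts missing data and occasional
wrong calls in exchange for cost. Two mechanisms dominate data quality:

* **absent evidence** — at mean coverage λ, a site in a sample is covered by
  `K ~ Poisson(λ·mᵢ)` reads (mᵢ the sample's coverage multiplier), so the
  chance a cell survives a minimum-depth filter d is the Poisson tail
  `P(K ≥ d)`;
* **insufficient allele sampling** — at a heterozygous cell covered by k
  reads, all reads carry the same allele with probability `2^(1−k)`, and an
  error-free caller then reports a homozygote.

This package simulates the data-generating process, reproduces the
down-sampling / calling / filtering / concordance procedure used to audit
skim genotyping, and provides the closed forms that predict the outcome, so
coverage × depth-filter × missing-data trade-offs can be explored without
any sequencing.

## Generative model (`skimeval.simulate`)

**Truth genotypes.** Three genetic backgrounds:

* *Diverse panel* — per site, alt-allele frequency `p` is drawn from a
  configurable law (default Uniform(0.05, 0.5], i.e. sites that would
  survive a MAF screen); genotypes follow inbreeding-adjusted
  Hardy–Weinberg frequencies `{(1−p)² + Fp(1−p), 2p(1−p)(1−F),
  p² + Fp(1−p)}` with inbreeding coefficient `F`.
* *Four-parent cross* — families of ~19 offspring; per family eight founder
  haplotypes carry iid Bernoulli(p) alleles and each offspring unites one
  gamete from each of two distinct founders. Highly heterozygous.
* *Doubled haploid (DH)* — `HOM_ALT` with probability p, else `HOM_REF`;
  never heterozygous, so downstream heterozygous calls measure error.

**Coverage.** Per-sample multipliers are Gamma(shape 1/cv², scale cv²)
(mean 1, coefficient of variation `cv`), emulating the pooling variability
of multiplexed sequencing. Defaults used by the study driver: cv 0.27 for
the simulated panel (0.34 four-parent, 0.17 DH in the corresponding
presets). The dispersion *law* is a modelling choice — only realized CVs
are constrained — and Gamma is the standard mean-1 overdispersion mixing
law.

**Reads.** Depth is Poisson(λ·mᵢ) per cell. Each read reports ref or alt:
a fair coin at heterozygous cells; the true allele flipped with probability
`per_read_error` at homozygous cells (flips go to the paired allele — a
two-allele world; third-allele reads are generated separately at
`other_read_rate`, default 0, solely to exercise triallelic handling).
A fraction of sites may be flagged as collapsed-paralog artifacts, chosen
once per run and shared by all samples ("consistent misalignment"): at
these sites every sample's read pool behaves as heterozygous regardless of
genotype, which is the mechanism that puts heterozygous calls into DH data.
The artifact fraction is a free parameter (default 0) because observed DH
heterozygosity mixes artifacts with sampling noise and the split is not
identifiable from summary rates.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: genome-wide depth heterogeneity
(mappability, GC bias, reference collapse), linkage between sites,
alignment losses (realized coverage below nominal), base-quality structure,
and indels. One visible consequence: with homogeneous per-site coverage,
an ultra-low (≤ 1x) set filtered at depth 2 with max-missing 0.5 retains
essentially zero sites, whereas real data retain a small percentage thanks
to depth heterogeneity. The package reports this regime honestly rather
than modelling it.

## Down-sampling (`skimeval.downsample`)

FASTQ subsetting keeps each read (pair) independently with probability
`target/nominal` coverage; pairs are kept or dropped together. Output
counts are Binomial(N, fraction) rather than an exact quota — matching the
coverage variability of pooled runs and allowing O(1)-memory streaming.
The matrix analogue thins every allele count by Binomial(c, fraction);
by the Poisson thinning theorem this maps Poisson(λ) depth fields to
Poisson(fraction·λ), so matrix thinning and read subsetting agree in
distribution. Per-file random streams are derived from the master seed
plus a CRC32 of the file name, so extending a batch never perturbs
existing outputs.

## Calling (`skimeval.caller`)

A deliberately transparent two-allele maximum-likelihood caller stands in
for a full pileup genotyper: with per-read error ε, likelihoods are
`(1−ε)^r ε^a`, `0.5^(r+a)`, `ε^r (1−ε)^a` for HOM_REF / HET / HOM_ALT;
zero depth is MISSING; exact ties break toward the homozygote of the
majority allele, then HOM_REF. Consequences used throughout: at ε = 0 a
heterozygote with k reads is mis-called with probability exactly `2^(1−k)`,
and the call is monotone in the read counts. De-novo discovery emits a
site when one sample shows ≥ 2 alt reads or two samples show ≥ 1 — the
threshold is this module's own choice (set so a single read error cannot
create a site); no attempt is made to match any particular caller's priors.

## Filtering (`skimeval.filters`)

Fixed order: triallelic policy → depth mask → missing → MAF → het. The
order is a design decision (the procedure lists the rules without ordering
them): masking first means the site filters judge the evidence a
depth-filtered set actually presents. All thresholds are inclusive on the
retain side (missing ≤ 0.5, MAF ≥ 0.05, het ≤ 0.1); whether a site at
exactly the boundary survives is under-determined by the source procedure
and inclusive was chosen once. MAF is computed per subpopulation group
(HET contributes one allele to each count, MISSING cells excluded) and a
site is retained when **any** group passes; a strict all-groups rule is
available (`MafRule.ALL_GROUPS`) because the grouping phrase is ambiguous.
Presets: `diversity_panel` (missing 0.5, MAF 0.05, het 0.1, drop
triallelic), `four_parent` (MAF 0.01, no het filter), `doubled_haploid`
(no site filters, triallelic sites set to missing).

The study driver's diverse panel uses inbreeding F = 0.9: the canola
panels this workflow audits are predominantly homozygous (DH-derived
breeding lines), and a ≤ 0.1 heterozygosity cap is only a sensible QC rule
when true heterozygosity sits well below 10%. With a generic outbred F the
het filter would discard most genuinely polymorphic sites — a different
regime from the one being emulated.

## Evaluation (`skimeval.evaluate`)

Concordance uses a matched-depth rule: a skim set filtered at depth d is
compared against the deep reference masked at `max(d, 2)` — the floor of 2
keeps the reference from resting on a single read. Cells partition into
match / mismatch / missing-in-skim / not-evaluable (reference too
shallow); `called_accuracy = match / (match + mismatch)` excludes the last
two categories from both numerator and denominator. The cumulative
accuracy table restricts to sites with per-site missing fraction strictly
below each ceiling in {0.1, …, 0.5} (the `<10% … <50%` reporting
convention; the *retention* filter at ≤ 0.5 is separate and inclusive).
Chromosome density is per-Mbp (length-corrected) with the densest
chromosome set to 1 and half-open 1-Mbp bins; raw counts are available via
`length_normalised=False` since the convention is not fixed by the
procedure being reproduced. The de-novo audit reports fold and absolute
increases over the list-based set, the share of list-based sites
re-identified, and classifies novel-site genotypes against the deep matrix.
A log-linear least-squares helper (`exponential_fit_r2`) quantifies
exponential growth of marker counts with coverage; no particular R² is
asserted.

## Design arithmetic (`skimeval.design`)

`p_called(λ, d)` is the Poisson upper tail; `p_het_undercall(k) = 2^(1−k)`;
`expected_called_accuracy(λ, d, het_rate, ε)` mixes exact per-depth caller
correctness (binomial sums over read splits, the same decision rule as the
caller) over Poisson depth truncated at `max(d, 1)` — depth-0 cells are
missing, not wrong. Homozygous ref and alt are symmetric under the caller,
so only the het rate matters at ε = 0, where the closed form reduces to
`1 − het_rate · E[2^(1−K) | K ≥ max(d,1)]`. This is the analytic oracle
the full simulate → call → evaluate pipeline is required to reproduce
within Monte-Carlo error.

Cost: `n · (lib + coverage · gb_per_1x · cost_per_gb)` with defaults
$12 / $30 / 1.0 Gb per 1x (a ~1-Gb genome); `affordable_samples` rounds
the budget quotient to the nearest whole sample — the rounding rule is
fixed by requiring internal consistency of the calculator's own headline
examples. `gb_per_1x` is configurable for other genomes (pea ≈ 4.3).

## Numerical and testing choices

* Poisson-family distributional checks use an exact chi-square
  goodness-of-fit against the pmf (cells pooled below expected count 5);
  a KS test is misspecified for integer counts.
* Statistical assertions use 3·SE bands from the relevant binomial/Poisson
  standard errors at fixed seeds; nothing is asserted tighter than the
  sampling noise of the simulated sizes.
* Problem sizes: distributional tests use 10⁵ cells; the
  analytic-vs-pipeline closure uses a 3×3 grid of (coverage, het rate) at
  10⁶ cells per point; the simulated study driver defaults to 50 samples ×
  2,000 sites over the 7-coverage × 4-depth grid. These sizes put
  Monte-Carlo error well inside the assertion bands while keeping a full
  run in seconds.
* Reproducibility: every stochastic stage takes a seed; identical
  configuration and seed reproduce outputs byte-for-byte, and study
  bundles embed the seed plus a config hash.

## Known limitations

Sites are simulated independently (no LD), the caller ignores base
qualities, alignment and its losses are out of scope (nominal vs realized
coverage is accepted as an input distinction, not modelled), and the
de-novo discovery rule is a simple count threshold. Real-data yields at
ultra-low coverage are therefore underestimated (see the generative-model
section), while the accuracy arithmetic — which conditions on observed
depth — transfers directly.
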