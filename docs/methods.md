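# Methods

This note records the models implemented in `ratesfs`, their assumptions,
the numerical choices behind them, and what the bundled synthetic data can
and cannot establish.

## Spectra and their summaries

The SFS of a sample of `n` chromosomes is stored as raw (possibly
real-valued) class counts, unfolded (derived counts `1..n-1`, requiring
polarized data) or folded (minor counts `1..n/2`). "Rare" means minor-allele
count ≤ 2 (singletons and doubletons) throughout; the threshold is an
argument everywhere it appears. Sample sizes are always chromosomes; the
CLI accepts diploid individuals via `--diploids` and doubles them, logging
the conversion.

**Projection.** The expected SFS of a subsample of `m` chromosomes is the
hypergeometric reweighting of the full spectrum. Classes `j=0` and `j=m`
are dropped, so the projected spectrum covers expected *segregating* sites;
their mass is reported separately by `projection_masses`. Because
`fraction_rare` normalizes by the spectrum total, the raw and
segregating-renormalized projections give identical rare fractions, so the
question of which normalization a subsampling curve should use is moot for
that statistic; both count forms are available.
`projected_rare_fraction` evaluates the same quantity in O(n) per subsample
size for cohort-scale spectra.

**Bootstrap.** Stratified rare fractions use a percentile bootstrap
(default 1000 replicates, seeded) resampling sites with replacement.
Continuous covariates are standardized by their mean over all input sites
and binned on a log scale. Strata with fewer than two sites are flagged as
CI-undefined.

## Demographic models

A model is an ordered list of epochs from the present backwards; each epoch
has a duration in generations (the terminal epoch is unbounded), a diploid
size at its recent end, and a per-generation growth rate. A quoted growth
rate `r` is read as compound per generation, `N(t) = N0 (1+r)^-t`
backwards; an exact-exponential convention is a switch on the model. Pair
coalescence occurs at rate `1/(2N)` per generation; when simulating with
ploidy-1 samples in msprime (whose ploidy-1 convention is rate `1/N`),
`to_msprime()` doubles all sizes — this is deliberate and tested against
the constant-size `1/i` law.

Shipped presets: `constant` (10,000 diploids); `tennessen_european`, the
two-bottleneck two-phase-growth European model transcribed from its
publication (ancestral 7,310; African expansion 14,474 at 5,920
generations; out-of-Africa bottleneck 1,861 at 2,040; second bottleneck
1,032 at 920 with 0.307%/generation growth; accelerated 1.95%/generation
growth from ~205 generations to a present size of 512,000), used as a
single population without migration; and `modified_nelson_recent`, the
re-fit recent-growth epoch (current size 4,009,877 diploids, 5.38% per
generation, onset 119.47 generations ago) on top of a constant
pre-out-of-Africa size of 10,000 diploids. The older intermediate epochs of
the original Nelson et al. parameterization are not shipped — they must be
supplied by the user (`modified_nelson(older_epochs=...)`); the simple
preset is continuous to within ~25% at the join (the growth epoch reaches
≈7,700 at its ancient end).

**Expected SFS.** Two routes:

* *Analytic.* `E[ξ_b] = Σ_k p(b|k) · k · E[T_k]` with `p(b|k)` the standard
  branch-subtree probability and `E[T_k]` obtained from the spectral
  (alternating-sum) representation of the ancestral lineage-count process
  after the deterministic coalescent-intensity time change. The alternating
  sums cancel catastrophically in floats, so they are evaluated in mpmath
  with precision scaled to `n` (~0.8 digits per sample). Growth epochs are
  discretized into 64 piecewise-constant slices (geometric midpoint rule;
  the discretization error is far below simulation noise at the tested
  scales, and a resolution knob is exposed). The path is capped at
  `n = 512`; beyond that it raises rather than degrade, per the module
  contract. A single-epoch constant model short-circuits to the exact
  `1/i` law; multi-epoch equal-size models exercise the full machinery and
  are tested to reproduce `1/i` to 1e-8.
* *Simulation.* Branch-mode allele-frequency spectra averaged over
  independent msprime genealogies — unbiased at any `n`; the rare fraction
  is a ratio of branch-length expectations. Used at cohort scale (e.g.
  67,500 chromosomes, where 48 replicates give a Monte-Carlo SE of ~0.15
  percentage points on the rare fraction in ~30 s).

**Ancestral polymorphism.** The probability that a polymorphism predates a
species split is bounded by the probability that ≥2 sample lineages survive
to the split time. Conditioning on polymorphism favours genealogies with
more mutational opportunity, so simulated genealogies are weighted by total
branch length and the weighted fraction with ≥2 surviving lineages is
reported. This weighting is one concrete reading of "conditional on the
site being polymorphic" (exact conditioning would weight by
`1 - exp(-M L_tree)`; at small `M` the two agree to first order). The
worst-case variant freezes all coalescence until the terminal epoch: all
`n` lineages enter the ancient constant-size epoch intact, which can only
raise the bound. The estimator is validated against a direct
holding-time-representation oracle at `n = 4`.

## Finite-sites simulation

Genealogies are Kingman coalescent trees (multiple mergers are ignored —
appropriate while the sample is much smaller than the current effective
size); each tree carries a block of `L = 1000` non-recombining sites by
default. Mutations are dropped with the Jukes–Cantor 4×4 model at per-site
per-generation rate `M` (uniform root base, Poisson events along branches,
uniform choice among the three other bases), so recurrent and back
mutations arise naturally. Sites are classified mono-/bi-/tri-/quad-allelic
from the leaf bases; tri- and quad-allelic sites are excluded from spectra
(mirroring the upstream data filter) but counted. For biallelic sites the
derived allele is the non-root allele; in the rare event that recurrent
mutation removes the root allele from the sample the site is polarized by
the minor allele — mispolarization is part of the phenomenon being
modelled, not an error to correct.

`estimate_grid` tabulates `P(S=1|M)` and `E[Y|S=1,M]` over a log-uniform
grid (default 40 points, 1e-9 to 5.3e-5 per bp per generation per haploid)
until at least `min_biallelic` biallelic sites accumulate per rate
(default 10,000 at test scale). At low rates the block length is enlarged
instead of multiplying genealogies — sites are conditionally independent
given the tree, so this only moves variance between levels, and all
standard errors are computed treating each genealogy as a cluster (ratio
estimator with per-tree residuals). Rates whose biallelic yield collapses
(saturation into multiallelism) are flagged rather than silently dropped.
The `n = 2` biallelic probability has the closed form
`(3/4)·θ'/(1+θ')` with `θ' = (16/3) N M`, used as an independent oracle.

## The lognormal rate mixture

Within a mutation type, per-site rates follow
`log10 M ~ Normal(log10 μ − σ² ln10/2, σ²)`; the location term makes
`E[M] = μ` exactly. σ is in log10-rate units; the working default is 0.57,
and the chimp/human co-occurrence estimates (0.83 non-CpG, 0.80 CpG
transitions) ship as named constants. A convenient closed form:
`P(M > kμ) = 1 − Φ((log10 k + σ² ln10/2)/σ)`, independent of μ — about 3%
of sites exceed five times their type mean at σ = 0.57.

The expected rare fraction at mean rate μ marginalizes the grid quantities
over the polymorphism-conditioned rate law `f(M|S=1;μ) ∝ P(S=1|M) g(M;μ)`
(Bayes), by trapezoid quadrature in log10 M over `μ·10^±4σ` (≥ 0.9999 of
g's mass; truncation and resolution are arguments, and doubling the
resolution moves the default result by < 1e-3). Grid quantities are
interpolated linearly in log10 M, matching the log-uniform grid. A support
that exceeds the grid raises an error naming the gap; `clip_to_grid=True`
instead assigns the out-of-range tail mass the grid's edge values — the
same convention as clipped interpolation — which is appropriate when the
edges are already in the flat low-rate limit or the saturated high-rate
regime. Monte-Carlo grid errors are propagated through the (linear)
interpolation and quadrature weights to give a standard error on the
mixture value.

Fitting σ by 1-D least squares over a rare-fraction curve is provided as an
extension (the core analyses fix σ); recovery to ±0.1 is verified on
noise-free synthetic curves at σ* ∈ {0.3, 0.57, 0.8}.

## The conditioned SFS

Divergence categories follow the exactly-one-substituted-species rule:
`substituted_s` requires species `s` to carry the human minor allele and
all other primates — baboon included, since it anchors the ascertainment —
to be observed carrying the major. The strict mode (default) requires all
six primate alleles nonmissing; a lenient mode ignoring missing species
exists and is labelled non-faithful. An alternative conditioning labels
each site by the nearest minor-carrying primate. Mutation types are
computed on the major→minor change, collapsed with the reverse complement
(central allele ∈ {A, C}); the CpG>TpG type overrides C>T when the human
reference flank supplies the CpG context (polymorphic context is ignored —
a deliberate simplification). Sites whose needed flank base is ambiguous
are flagged, not guessed. The strand partition maps each change onto the
host gene's coding strand without collapsing, distinguishing e.g. A>G on
the coding vs template strand; CpG sites and strandless records are
excluded with counts reported.

Folded conditioned spectra require one common chromosome total; tables with
ragged totals must be projected or subsampled first (the generator emits
constant totals; for real cohort tables this is where the ≥100,000
chromosome filter and a projection step would be applied).

## The two-category phylogenetic rate model

Sites carry a rate multiplier `M ~ g` (mean-1 lognormal) and belong to a
uniform-clock category U (yearly rate `r_U·M` on every lineage) or a
generation-scaled category G (per-generation rate `r_G·M`, yearly rate
`r_G·M/g_years`). Substitution on a branch is Poisson:
`1 − exp(−rate·t_years)`. Human polymorphism probability defaults to the
linear-in-rate approximation (a finite-sites grid can replace it).
Conditioning a site on being polymorphic in humans and substituted in
species `s` size-biases `M` and re-weights the categories: long-generation
lineages accumulate fewer G substitutions per year, so their substituted
sites are enriched for U (CpG-like) mutations —
`uniform_clock_enrichment` is strictly increasing in the branch's
generation time, and in the low-rate limit depends only on rate ratios.
The posterior distribution of the site's human-side per-generation rate
mixes the two categories' shifted copies of the multiplier posterior; its
mean is higher for substituted species with longer generation times. This
construction is this package's own formalization of the two-category
idea — the Poisson-thinning form was chosen for its transparency; its
exact quantitative outputs depend on the default branch lengths and
generation times, which ship as an editable YAML of literature-typical
values and are choices, not fits. Orangutan has the longest generation
time among the shipped lineages, which is why enrichment orderings follow
generation time rather than relatedness exactly.

## Rare-variant logistic model

For coding variants, `logit P(Y=1) = β0 + β_μ·μ + (1−Z)β_s^syn·s +
Z β_s^ns·s` with mutually exclusive mutation-type indicators μ (resolution
none / mononucleotide / trimer), divergence-category indicators s with
`human_private` as the baseline (a convention this package makes explicit), and Z the nonsynonymous flag. CpG>TpG sites are
excluded by default; when included, the mono-level type block distinguishes
CpG>TpG as its own type (otherwise the block could not absorb CpG
composition), and the trimer context identifies CpG sites by itself. Fits
aggregate identical covariate patterns into a binomial GLM (IRLS,
likelihood tolerance 1e-10) — identical estimates to a site-level fit,
orders of magnitude faster; the stored log-likelihood is the site-level
Bernoulli one, so nested type resolutions are comparable. Complete
separation raises an error naming the cell; empty categories are dropped
with a record.

The species-coefficient trend is Spearman rank correlation against split
times with an exact two-sided permutation p-value (all `n!` orderings
enumerated, feasible for the 2–8 species this analysis concerns; midranks
on ties, flagged). Exact enumeration is this package's choice of p-value
convention; for five species a perfect ordering gives 2/120 ≈ 0.017 and a
single adjacent transposition 10/120 ≈ 0.083.

## Synthetic data generator

Each site draws, in order: divergence category → mutation type (CpG
fraction per category, shared mono composition otherwise) → per-site rate →
rare indicator and minor-allele count → primate alleles, flanks, strand,
functional class and covariates. Everything latent lands in a manifest.
Default conditions: 50,000 sites, 2,000 chromosomes (a desk scale chosen so
the whole suite runs in minutes; paper-scale values like 121,412
chromosomes are plain config changes), human-private-dominated category
proportions with a substituted-species gradient from chimpanzee (fewest) to
gibbon (most), a CpG-fraction gradient declining with divergence
(0.30 → 0.10 across chimpanzee→macaque, 0.08 for human-private), de-novo
study-motivated mean rates (CpG transitions 1.2e-7; transitions ~1e-8;
transversions ~3e-9), and σ = 0.57.

Two regimes for allele counts:

* Without a rate grid, every site's rare probability is the infinite-sites
  rare fraction of the configured demography at the table's sample size
  (analytic when feasible, otherwise branch-simulation), and minor counts
  are drawn from the corresponding folded expected spectrum conditioned on
  rare/common. Rarity is then independent of mutation type by construction
  — the correct infinite-sites null.
* With a rate grid, per-site rates are drawn from the
  polymorphism-conditioned law `f(M|S=1;μ_type)` (every generated row *is*
  a polymorphic site, and polymorphic sites are rate-enriched), and the
  rare probability is the grid's `E[Y|S=1,M]` at the drawn rate. Count
  classes still come from the infinite-sites expected spectrum within the
  rare/common split — a simplification: the full finite-sites spectrum
  shape at each rate is not reproduced class by class, only the
  rare-versus-common structure that the analyses in this package measure.

Injectable effects, all off by default: per-category log-odds shifts of
rarity on nonsynonymous (or synonymous) sites — a selection-like residual
trend; additive rare-probability gaps on template-strand sites of chosen
types — transcription-coupled asymmetry. The two-population split
allocates minor copies hypergeometrically between panels; optionally
flagged sites model two independent mutational origins (one copy planted on
each side), the sharing signature of recurrent mutation.

**Desk-scale rate maps in tests.** At a grid sample size of 50–200
chromosomes the recurrent-mutation regime begins at far higher per-site
rates than in a 100,000-chromosome cohort. Tests that need the CpG/non-CpG
contrast to be *visible* therefore use a scaled-up rate map (CpG in the
recurrence zone of the grid, transversions near the infinite-sites limit)
and, where per-category resolution matters, a steeper CpG gradient with
balanced category sizes — power-driven scaled-down conditions, documented
in the fixtures. With the cohort-realistic defaults the same machinery
produces the same orderings, but with effect sizes below desk-scale
sampling noise.

**What the synthetic data does not emulate:** linkage disequilibrium
(sites are independent, as in all site-wise analyses here), sequencing or
ascertainment error, variable per-site chromosome totals, true ancestral
polymorphism leaking across the species split, and context-dependent
mutation beyond the CpG flag. Passing tests establish that the pipeline
recovers the structures it is designed to detect, under the stated
generative model, at the stated scales — not that real exome data satisfy
that model.

## Scaled-down study sizes

The default test/acceptance conditions are: 40-point rate grid at 200
chromosomes with ≥10,000 biallelic sites per rate; mixture cross-checks at
μ = 2e-7 (the largest mean rate whose ±4σ support fits inside the standard
grid); demographic rare-fraction checks at the full 67,500 chromosomes via
branch simulation (48 replicates); the sample-size rank-flip demonstration
from a 20,000-chromosome "population" spectrum at the CpG-like rate 1.2e-7
projected down to 50–1,000 chromosomes; synthetic tables of 50–60,000
sites for recovery checks and 400,000 sites for the composition-driven
trend check, whose per-category effect (at most ~3 percentage points at
this grid scale) needs that many sites to clear binomial noise. The
trend's presence and attenuation are summarized by a weighted
least-squares slope of the species coefficients on split times with known
coefficient variances — the natural line-fit summary of a coefficient
trend — alongside the exact rank statistic. These sizes
were chosen so the complete suite runs in well under the practical budget
of a laptop-class single core while keeping each statistical assertion at
≥3σ resolution.

## Known limitations

* The analytic SFS path is capped at n = 512 and raises beyond; cohort-scale
  expectations rely on (unbiased) simulation.
* The ancestral-polymorphism conditioning is branch-length weighting, an
  interpretation; exact polymorphism conditioning would require a mutation
  rate.
* `RateGrid` stores rare-fraction and biallelic-probability curves, not full
  per-rate spectra; generator count classes use the infinite-sites shape
  within rare/common.
* The Tennessen preset omits African↔European migration (single-population
  use); the modified-Nelson preset's intermediate epochs are user-supplied.
* No selection models, no linkage, no multi-nucleotide or context-dependent
  mutation beyond CpG.
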