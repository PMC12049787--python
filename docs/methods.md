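# Methods

## Allele-specific open chromatin calling

**Model.** At a biallelic heterozygous SNP the two alleles of each donor are
exposed to the same ATAC reaction, so under the null of equal accessibility
the reference read count pooled over heterozygous donors is
`X ~ Binomial(n, 0.5)` with `n` the pooled total.  The test is the exact
two-sided binomial test in the minimum-likelihood convention (the total
probability of all outcomes no more likely than the observed one), which at
`p0 = 0.5` reduces to `min(1, 2·P(X <= min(x, n-x)))`; the vectorised caller
uses that closed form, the scalar entry point delegates to
`scipy.stats.binomtest`, and the two are pinned against each other and
against exhaustive pmf enumeration for all `n <= 200`.

**Filters (defaults, applied per record before pooling).** Heterozygous
genotype (`0/1`, `1/0` or phased equivalents), total depth `>= 20`, each
allele observed `>= 2` times, variant-quality tranche `> 99.5` when the
field is present.  The per-allele clause is read as a heterozygosity
confirmation — `min(ref, alt) >= 2` — since requiring only one allele at
`>= 2` would be vacuous at depth 20.  A consequence worth knowing: SNPs with
near-monoallelic signal (allelic fraction ~1) lose their records to this
filter and are rarely tested at all; the power tests pin this behaviour.

**Multiplicity.** Benjamini–Hochberg step-up over all qualified SNPs
(delegated to `statsmodels`), calls at `q < 0.05`, strict inequality.  Ties
in the sort are broken by stable input order.  Under the global null the
pipeline's realised any-rejection rate is ~0.03 (measured over 1000
simulated replicates), below the nominal 0.05 because the exact test is
discrete.

**Power.** `estimate_power` is Monte-Carlo: each replicate plants one
imbalanced SNP among a configurable number of balanced SNPs (all donors
heterozygous, per-donor depth Poisson), runs the identical
filter → pool → test → BH math in vectorised form, and reports the fraction
of replicates in which the planted SNP is called, with
`mc_se = sqrt(p(1-p)/n_reps)`.

## Motif disruption scoring

PFMs are normalised with a pseudocount proportional to each position's
column total (`0.01` by default) so zero counts stay finite while rank order
is preserved.  Scores are `sum_i log2((p_i(b_i)+1e-9)/q(b_i))` against a
background `q` (uniform by default, configurable); `N` bases contribute the
zero log-odds background term.  Only placements covering the SNP are scored,
on both strands (the reverse strand scores the reverse complement; reported
offsets are in forward-window coordinates).  Ties prefer the forward strand
and the leftmost offset.  `delta = score_alt - score_ref > 0` means the
alternative allele is the stronger predicted binder.  Note that N-padding
invariance of the best score is guaranteed only when the best placement has
non-negative column scores (e.g. a planted consensus); with strongly
negative columns a truncated placement over `N`s can legitimately score
higher.

## Dual-species co-culture differential expression

**Composition correction.** Each sample's human:mouse read-total ratio
summarises its cellular composition.  The correction is realised as
species-specific effective library sizes: human transcripts are offset by
`log(human total)` of each sample, mouse transcripts by `log(mouse total)`.
This makes the group-effect estimate exactly invariant to a per-sample
composition rescaling, which is the stated purpose of the factor.  A
whole-library offset mode is retained for comparison; the mechanism of the
correction is demonstrated by a regression test in which tripling one
sample's human counts changes no call under species offsets but floods the
whole-library mode with spurious calls.  That comparison is run at the
generating dispersion: with per-transcript *estimated* dispersion a
single-sample outlier inflates the dispersion estimate (the outlier
t-statistic is bounded near 1) and masks the mis-normalisation instead of
fixing it — an observation worth remembering when interpreting
"robustness" of DE pipelines to normalisation errors.

**Expression filter.** A transcript must have a nonzero count in at least
75% of samples, evaluated on the exact rational (7 of 9 passes, 6 of 9 does
not).  "Expressed" = nonzero raw count; a CPM-threshold variant can be had
by pre-transforming.

**NB model.** Per transcript `y ~ NB(mu, alpha)`, `log mu = beta_group +
offset`, NB2 variance `mu + alpha mu^2`.  Group coefficients solve the score
equation by damped Newton started at the closed-form Poisson solution
(monotone score, vectorised across all transcripts).  Dispersion: raw
per-transcript value from the Pearson estimating equation at the two-group
Poisson fit; trend by lowess over log mean abundance; moderation
`(d0·trend + df·raw)/(d0 + df)` with prior df `d0 = 10` and residual
`df = S - 2`.  The group effect is a likelihood-ratio statistic referred to
`F(1, df + d0)` when the dispersion was estimated (acknowledging its
estimation uncertainty, in the quasi-likelihood spirit) and to chi-square(1)
when a dispersion is supplied.  At the study design size (9 samples per
group) this calibrates the null p-value distribution to uniformity (KS-test
pinned) and keeps the fraction of null p-values below 0.05 at 0.05 ± 0.02.
`log2fc = (beta_A - beta_B)/ln 2`; BH FDR across all tested transcripts;
all-zero transcripts are dropped with a warning.  Exact numerical parity
with any published DE package is explicitly not a goal; the pinned claims
are operating characteristics (type-I error, FDR <= 0.10 empirically on
planted fixtures, fold-change recovery within ±0.15 at planted log2FC = 1).

**Gene representation.** Per gene the transcript with the smallest p-value
is flagged representative; ties prefer higher mean expression, then the
lexicographically smaller id; unmapped transcripts represent themselves.

**PCA.** Samples are embedded by PCA of `log2(CPM + 1)` (pseudo-count 1),
transcripts centred, CPM computed against the species-specific effective
sizes.

## Synthetic data

The generators define the study conditions the tests run under.

- **Allelic counts:** donors are heterozygous with probability 0.5; depth per
  heterozygous donor is negative binomial (Gamma–Poisson) with mean 60 and
  size 10 (`inf` recovers Poisson) — the depth law at het SNPs is an
  assumption, chosen as the simplest over-dispersed count model; 10 donors
  and 10,000 SNPs by default.  Reference-mapping bias is a generator-only
  knob (`p_eff = a/(a + bias(1-a))`), default 1 (none): the caller applies no
  bias correction, so the knob exists to probe robustness, not to be undone.
- **Co-culture counts:** 9 samples per group (the study's replicate count),
  two genotype groups, per-sample human:mouse ratio log-normal around 1 with
  log-sd 0.3, library size log-normal around 2e6, per-transcript log-normal
  base abundance, NB dispersion 0.1, 10% DE transcripts at |log2FC| = 1 with
  random sign, 5% independent dropout.  Desk-scale transcript counts (4,000
  human / 3,200 mouse by default) keep runtimes in seconds; the analysis code
  is size-independent.
- **Motif windows** plant the PWM consensus at a random SNP-covering offset;
  disruption substitutes the column's lowest-probability base at the SNP.
- **Peaks** cover an exact fraction of SNPs with disjoint half-open
  intervals, shrunk at midpoints so uncovered SNPs stay outside.

What the generators do *not* emulate: read-level artefacts (mapping,
duplicates, Tn5 insertion bias), cross-species read misassignment,
correlated dropout, donor effects, or library-preparation batch structure.
Passing tests therefore certify the statistical machinery under the stated
models, not robustness to those real-data artefacts.

## Numerical choices and edge cases

- Newton solvers: steps clipped to ±2 (means) / ±10 (dispersions), 100/60
  iteration caps, convergence at 1e-12/1e-10; groups with all-zero counts
  get an effectively -inf mean and contribute zero likelihood.
- `binomial_two_sided` tie tolerance follows the 1 + 1e-7 relative rule of
  the underlying exact test.
- Zero explained variance (identical samples) reports 0, not NaN.
- BED intervals are validated (`end > start`) with line numbers; VCF
  multiallelic and non-SNP sites are skipped with a counted warning; DP is
  recomputed as `ref + alt` from AD.
- Provenance headers echo the package version and full parameter set but no
  timestamp, so identical command + seed gives byte-identical outputs.

## Known limitations

- No beta-binomial over-dispersion in the allelic test: donor-level biology
  that over-disperses allelic fractions would inflate ASoC calls; the caller
  matches the pooled-binomial procedure it implements.
- The dispersion moderation uses a fixed prior df (10) rather than an
  empirical-Bayes estimate of it.
- `estimate_power` treats every donor as heterozygous and depth as Poisson;
  it answers "power at a typical testable SNP", not genome-wide average
  power over the het-probability distribution.
- Technical replicates are pooled like distinct samples (a donor-collapse
  step, if wanted, belongs upstream of the caller).
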