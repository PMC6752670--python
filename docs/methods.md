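# Methods

## The screening posterior

A pileup site is summarised by `(k, n, e)`: alternative-supporting
reads, total depth, and a scalar per-base miscall probability. Reads are
modelled as conditionally independent Bernoulli draws given the sample's
mutant allelic fraction (MAF) `f`, with symmetric miscalls, so the
probability that a read reports the alternative allele is

    p(f) = f (1 − e) + (1 − f) e .

The posterior over `f` is `Bin(k | n, p(f))` times a flat prior,
evaluated on a uniform grid of step 1e-4 (a factor >10 below the 0.5%
decision boundary) and normalised; the MAP is the grid argmax and the
interval is equal-tailed at 95% (first grid points at which the
cumulative mass reaches 2.5% / 97.5%). Equal-tailed rather than HPD was
chosen because it is order-statistic testable and matches the interval
convention of the screening tooling this stage emulates; an HPD interval
would be slightly narrower for the very asymmetric posteriors near 0.

Classification applies the screening thresholds in fixed order:
hom-ref when `ci_low < 0.005`; het when the MAP lies in 45.0–55.0%
(a MAP rule, since the heterozygous criterion is phrased as a MAF
threshold, not an interval rule); hom-alt by the mirror of the hom-ref
rule (`ci_high > 0.995` with MAP ≥ 0.995); otherwise mosaic candidate.
The hom-alt convention was an open choice; the mirrored rule keeps the
decision a pure function of the posterior and thresholds.

All sites are classified identically regardless of sex; hemizygous male
X sites simply travel the same MAF continuum (a true hemizygote appears
near 1.0), and sex is carried as metadata only.

## The amplicon (validation) estimator

At ~12,000× depth the binomial read noise shrinks to ~0.5 percentage
points and site-to-site variation in the platform error rate becomes
the dominant nuisance. The hierarchy is beta-binomial: per-site error
rates `e_i ~ Beta(α, β)`, observed control alt counts
`k_i ~ Bin(n_i, e_i)`. The Beta is fitted by method of moments from
variant-free control sites, with the within-site binomial component
subtracted from the observed variance of the control fractions
(`v_between = v_obs − mean(m(1−m)/n_i)`); when the excess is
non-positive the controls are consistent with one shared error rate and
the model collapses to a point mass at the mean (floored at 1e-6).
Without the subtraction the error spread is overstated by the sampling
noise of the controls themselves and the resulting intervals visibly
over-cover at low MAF.

The site likelihood marginalises the error rate by quadrature over 32
equal-probability Beta quantile midpoints. Quantile nodes (rather than
Gauss–Jacobi) were chosen because they reduce *exactly* to the
fixed-error likelihood when the Beta degenerates, so the marginalised
posterior provably agrees with the screening posterior in that limit.
The validation decision uses the stage's own thresholds: confirmation
requires `ci_low ≥ 0.005` and MAP outside 40.0–60.0% (wider het band
than screening, as the stage convention specifies).

## Droplet digital PCR

Droplets are gated with fixed rectangular thresholds (closed lower
bounds; a droplet at threshold is positive): MU when the mutant-channel
(FAM) intensity clears its gate regardless of VIC, else WT when the
VIC gate is cleared, else NA. Fixed gates rather than clustering keep
the classification deterministic and mirror two-threshold quadrant
gating.

The primary estimate is the raw ratio `MAF = MU/(MU+WT)` with an exact
Clopper–Pearson 95% interval (beta quantiles) — exact and conservative
by construction. The optional Poisson-occupancy correction converts
positive-droplet counts to concentrations `λ_c = −ln(1 − positives/N)`
per channel and forms `λ_mu/(λ_mu + λ_wt)`; to first order the raw
ratio exceeds the corrected one by `f(1−f)(1−2f)·λ/2` at mean occupancy
λ, which stays below one percentage point (absolute) for λ < 0.1 and
vanishes at `f = 0.5`. The corrected interval maps the raw-ratio
endpoints through the same transform with channel totals held at their
observed values — an approximation, acceptable because the correction
itself is an optional extra and the raw ratio is the reported quantity.
Which exact interval construction the original instrument software used
is not documented; Clopper–Pearson is the unambiguous, reproducible
choice.

Limit-of-detection power is estimated by simulation: a run "detects"
when at least 3 MU droplets appear (a configurable default; the assay's
published floor of 1e-4 mutant per genomic copy states the limit but
not the rule). With 1e5 template copies, 1e-4 means ~10 mutant
molecules, comfortably above the 3-droplet rule, and measured power is
1.0 there and at every larger MAF.

## Exact 2×2 inference

Conditioning on both margins of the 2×2 table leaves the (noncentral)
hypergeometric family with odds ratio ψ as the only parameter,
`P(X = x | ψ) ∝ C(r1, x) C(r2, c1 − x) ψ^x`.

* **p-value** — two-sided by the point-probability (minimum-likelihood)
  rule at ψ = 1: sum the probabilities of all margin-consistent tables
  whose point probability does not exceed the observed table's. The
  weights are exact Python integers (`math.comb`), so the "no more
  probable" comparison involves no floating-point tie tolerance and
  cannot overflow; only the final ratio is floated.
* **Odds ratio** — the conditional MLE solves the score equation
  `E[X | ψ] = x_obs` by Brent root-finding in log ψ to relative
  tolerance better than 1e-8. Boundary tables (observed cell at the
  support edge) return 0 or ∞ with a flag. Note that widely used exact-test
  software solves the same equation with a loose default solver
  tolerance and can print values a few hundredths off the exact root;
  this package reports the converged root.
* **Confidence bounds** — exact test inversion: the lower bound is the
  ψ at which `P(X ≥ x_obs | ψ)` equals the tail level, the upper bound
  the mirror. Both the two-sided interval (α/2 per tail) and the
  one-sided 95% bound (interval open above) are reported, because
  published tables sometimes pair a two-sided p-value with a one-sided
  interval.

Rate summaries attach exact Clopper–Pearson intervals and display
percentages rounded to one decimal.

## Synthetic-data generators

The generators reproduce the statistical structure the estimators
assume, and their defaults are the study conditions of the motivating
cohort analysis:

* **Read counts** — two-stage sampling: the mutant template count is
  drawn once per site, `Bin(input_copies, f)` (3000 copies for 10 ng
  panel libraries, 6000 for 20 ng amplicon libraries), reads resample
  the template pool, and each read is miscalled symmetrically with
  probability `e` (default 1e-3, Phred 30). When depth outruns the
  template pool — 12,000× over 6000 copies — replicate variance exceeds
  binomial read variance by the factor `1 + depth/copies`, the
  PCR-bottleneck overdispersion. No PCR-cycle-explicit amplification or
  read-level FASTQ/BAM structure is modelled.
* **Droplets** — mutant and wild-type molecules load droplets as
  independent Poissons with channel means `λ_c = copies_c/N`. The
  MU/WT/NA triple is drawn from the exact aggregate law
  (`MU ~ Bin(N, 1 − e^{−λ_mu})`, then `WT ~ Bin(N − MU, 1 − e^{−λ_wt})`),
  which is distributionally identical to materialising every droplet
  but O(1); the molecule-level assignment simulator is kept in the test
  suite as the independent oracle. A droplet with any mutant molecule
  reads MU (dominant FAM signal). `false_mu_rate` (default 0) can flip
  non-MU droplets to stress the detection limit. Total droplets per run
  is a free parameter (default 5e6) since instrument run sizes vary.
* **Cohorts** — per-subject Bernoulli mosaicism at sex-specific rates
  (defaults 3/18 and 2/453), mosaic MAFs uniform over the observed
  somatic range 6.5–38.1%. Fixture generation can instead fix the
  mosaic counts to `round(rate × n)` so an end-to-end run has a known
  truth table.
* **Tissue panels** — named scenarios emit per-tissue droplet data over
  the fixed vocabulary (blood, saliva, hair, buccal, urine, semen
  Sp/L1/L2/Ot): `germline_only` (motile-sperm layer only, MAF 1.4%),
  `germline_only_sp_ot`, `early_embryonic` (all semen fractions 7.55%
  plus saliva 0.43% and blood 0.28%), `negative_control`.

What the generators do **not** emulate — alignment artefacts, strand
bias, mapping-quality structure, clustered errors, fluorescence
"rain" between droplet clusters, true between-site error-rate
variation — means passing calibration tests certify the estimators
against their own sampling assumptions, not against every failure mode
of real libraries. The screening stage deliberately omits the read-level
filters a production mosaic caller layers on top.

## Calibration studies (`mosaicmap.validation`)

Calibration and recovery simulations draw reads bottleneck-free
(binomial at the error-folded success probability): the posteriors
model read sampling only, and the template-bottleneck variance of real
libraries is a property of the material that the read-level interval
cannot see (and is exercised separately by the generator tests).
Problem sizes are 2000 sites for screening calibration (coverage
standard error ~0.5%), 200 replicates per MAF set-point
{0.5%, 1%, 6.5%, 20%, 38%} for amplicon recovery — coverage is assessed
over the pooled 1000 replicates, where its Monte-Carlo error (~0.7%)
resolves the nominal band — and 500 droplet runs per power point.

## Pipeline conventions

Candidates route to ddPCR when the variant is on the hotspot list
(shipping default: the ten classical recurrent *MECP2* coding changes,
fully user-overridable), otherwise to amplicon validation; a
`require_both` switch demands concordance instead of any-one
confirmation. Every confirmed call in the output VCF carries its
validation MAF and interval (INFO keys MAF, MAF_CI95_LO, MAF_CI95_HI,
CALL, METHOD), 1-based coordinates, and the run writes a manifest and a
JSONL event log so reports are byte-reproducible from config + seed.

## Known limitations

* The screening prior is flat over the MAF; no genotype-class prior
  odds are used, so the class decision is entirely threshold-based.
* The amplicon error hierarchy pools a single Beta across sites; motif-
  or strand-specific error structure is out of scope.
* The Poisson-corrected interval is a transformed raw interval, not a
  joint-likelihood interval for the two concentrations.
* Fisher/odds-ratio machinery covers a single pre-specified 2×2
  comparison; no multiple-testing control is provided.
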