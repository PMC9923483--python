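# Methods

## Growth and age assignment

Total length is converted to age with the von Bertalanffy curve
`L(t) = L_inf (1 - e^{-k(t - t0)})` at the blue-skate parameters
`L_inf = 149 cm`, `k = 0.18 /yr`, `t0 = -0.49 yr`, inverted analytically
and floored to whole years ("rounding down to the year").  A `1e-9`
nudge inside the floor keeps lengths that are exact curve values on
their lattice age.  Lengths at or above `L_inf` raise an error rather
than clamping, so impossible measurements surface upstream.  Near the
asymptote the inversion is very steep — between 142 and 148 cm the
implied age runs from 16 to 27 years — which is why the CKMR stage caps
usable ages (default 15): above the cap a 1-cm measurement error moves
an individual across several cohorts.

## Kinship classification

Each relationship hypothesis is a kappa triple (probability of sharing
0/1/2 alleles IBD at a locus): PO (0,1,0), FS (1/4,1/2,1/4),
HS (1/2,1/2,0), FC (3/4,1/4,0), U (1,0,0).  The joint probability of a
genotype pair is the kappa mixture of the 0/1/2-IBD joint distributions
under Hardy-Weinberg at the locus's observed frequency.  Observed calls
pass through a symmetric error channel: with probability `eps` (default
0.005) a call flips to one of the two other genotypes.  The channel
prevents single bad calls from producing infinite log-likelihood
ratios; with `eps = 0`, genuinely impossible pairs (opposing
homozygotes under PO) have probability zero, and the log tables are
clamped at `log 1e-300` only so that the matrix-algebra scoring path
stays finite.  Fixed (monomorphic) loci and missing calls contribute
nothing to a pair's score.

All `n(n-1)/2` pair scores are computed as nine indicator-matrix
products (one per ordered genotype-pair class), which reduces the
2×10^5-pair problem to a handful of BLAS calls.

Thresholds are calibrated per dataset, not hard-coded.  Genotype pairs
are simulated under each hypothesis from the observed frequencies; the
HS-vs-U threshold is the smallest lambda whose expected false positives
over all comparisons stay below a budget (default 0.1 pairs).  Because
the relevant false-positive rates (~10^-7) are far below what naive
Monte Carlo can resolve, tail probabilities are importance-sampled:
for lambda = log(P1/P0), the H0 tail mass above a threshold equals the
H1 expectation of `e^{-lambda}` over that region, so draws from H1
estimate it with low variance.

Candidates above the HS-vs-U threshold are then tested FS-vs-HS and
PO-vs-FS (midpoint thresholds, 0 by default), and pairs that remain HS
but fail HS-vs-FC are labelled FC and excluded from the HSP list.  This
conservatism trades a small loss of true half-siblings (the HS and FC
lambda distributions overlap; at 1,500 loci roughly 2% of true HSPs
fall below the midpoint) against contamination of the HSP pool by the
much larger population of second/third-order relatives, whose inclusion
would bias abundance downward.  Grandparent-grandchild and avuncular
pairs share HS's kappa class and are genetically indistinguishable from
half-siblings at any panel size; in the target design the sampled age
range (2-15 years over a 6-year survey window) makes grandparent pairs
impossible, and the simulator's truth tables label avuncular pairs
(AV/HAV) so validation can separate them from genuine errors.

Allele frequencies are taken from the full post-QC sample including the
pair under test; at n ≈ 660 the bias is negligible and it matches the
frequency set used in calibration.

## The CKMR model

Cross-cohort pairs are the recapture unit.  With birth years
`b_i < b_j`, `P(HSP) = 4 / N_{b_j} * phi^{b_j - b_i}`, with
`N_t = N_0 e^{rt}` and model year 0 the birth year of the earliest
retained cohort.  `N_{b_j}` is the post-survival, post-recruitment
breeding population of year `b_j`.  The formula assumes a closed
population, two sexes in equal number among breeders, and sex- and
age-aggregated dynamics — the simplifications forced on data-deficient
species.

Individuals older than the age cap are dropped; same-birth-year pairs
are excluded (litter mates violate independent sampling; exclusion
removes pairs, not individuals); full-sibling and flagged
distant-relative pairs are excluded from both the HSP and comparison
pools.  The remaining pairs aggregate into per-(b_i, b_j) cells of
(HSP count, comparison count) — the likelihood's sufficient statistic —
and the aggregated log pseudo-likelihood equals the naive per-pair
product exactly (tested to 1e-8).  The pseudo-likelihood's
non-independence across pairs is accepted as-is; no over-dispersion
correction is applied, so credible intervals are, if anything, slightly
narrow.

Priors: `r ~ U(-1, 1)`, `phi ~ U(0, 1)`, and `N_0` log-uniform on
[10^2, 10^7] (configurable).  "Non-informative" abundance priors are
not innocuous here: with zero observed HSPs the likelihood only rules
out small `N_0`, posterior mass piles against the upper bound, and the
reported abundance is then a prior artifact — the bound is therefore
echoed in every summary.

Sampling is component-wise Gaussian random-walk Metropolis-Hastings on
`(log N_0, r, phi)`.  Step sizes adapt every 500 iterations during
burn-in toward 0.3 acceptance and then freeze, so all retained draws
come from a fixed kernel.  Defaults mirror a production run (10^6
iterations, thin 100, burn-in 10^5); the bundled analysis uses 4×10^5
and the test-suite fits 10^5 iterations, which on the desk-scale data
give effective sample sizes above 2,000 for every parameter.  ESS is
computed with arviz's autocorrelation estimator.  Abundance
trajectories `N_t` are derived per draw and summarised by mean and
central 95% interval; as with any exponential-growth posterior, the
mean trajectory bows upward toward both ends of the time series.

Age error is not propagated through the likelihood (the age-length key
carries no usable uncertainty bounds).  Instead, `sensitivity_refit`
re-draws lengths under the measurement-noise model, re-assigns ages and
cohorts, and refits by maximum pseudo-likelihood; the spread of the
refits shows how much the estimates depend on the age assignment.

`expected_hsp_count` sums the pair probability over a design's
cross-cohort sample-size products, so the expected number of kin pairs
grows quadratically with sample size — the planning heuristic for "how
many more samples until ~45 kin pairs".

## Diversity and LD effective population size

Per locus: `H_o` is the heterozygote fraction of called genotypes,
`H_e = 2p(1-p)` (sample-size-uncorrected, matching the usual toolkit
default), `F = 1 - H_o/H_e` on polymorphic loci; groups report means and
SEs across loci.  The LD method uses the mean squared genotype-dosage
correlation over locus pairs (pairwise-complete observations, loci
below a critical MAF of 0.05 excluded), subtracts the expected sampling
contribution (`1/S + 3.19/S^2` for harmonic-mean sample size S ≥ 30;
the small-sample coefficient set below that), and inverts the published
random-mating bias-corrected relation to Ne.  A drift signal ≤ 0
reports infinite Ne; confidence intervals jackknife the mean r^2 over
individuals and transform the ±1.96 SD band through the same inversion
(so a lower band at or below zero gives an infinite upper CI).  Two
caveats are attached to every result: physical linkage is ignored
(genome-wide SNPs), and a mixed-age sample does not estimate Ne per
generation.

## Survey metrics

Weight from length by the allometry `W(g) = 0.0038 L^3.1201`; unit
effort is net length (km) × soak time (h); abundance CPUE is count per
unit effort and biomass CPUE summed weight (kg) per unit effort.
Repeat visits to a station within a year are averaged within the
station before averaging across stations, both for all stations and
for a fixed prime-station subset.  Capture distances use the haversine
great-circle formula (Earth radius 6371.0088 km); printed coordinates
at two decimals reproduce published pair distances to ±2 km.  The kin
proximity test compares sibling-pair distances against all potential
pairs with a two-sample KS statistic; since the reference set is highly
non-independent and tied at zero for same-haul pairs, the p-value is
computed by permuting which pairs carry the kin label (the asymptotic p
is reported alongside).  Whether the sibling pairs themselves belong in
the reference set is a judgment call; they are included here.

## The simulator

The generator realises exactly the process the estimator assumes:
overlapping generations; deterministic adult trajectory
`N_t = round(N_0 e^{rt})`; per-adult annual survival `phi` with the
shortfall recruited from the cohort reaching maturity (parentless
founders stand in for cohorts born before the modelled window); every
living mature adult a candidate parent every year, drawn uniformly
within sex.  Under this scheme the realised probability that two
cross-cohort offspring share a parent is `4/N_{b_j} phi^{gap}` up to
O(1/N^2) terms — verified against the pedigree over 200 replicate
populations.  Genotypes descend by Mendelian transmission from founder
Hardy-Weinberg draws at frequencies uniform on the configured MAF band,
through the same error channel the classifier models; only sampled
individuals and their ancestor closure are genotyped.  Surveys sample
without replacement among cohort members alive in each survey year
within an age window; lengths are curve values plus Gaussian noise
(sd 3 cm), truncated into (0, L_inf); with site fidelity enabled,
captures scatter around the mother's home site (Gaussian, default sd
15 km), which induces the sibling spatial clustering the proximity test
is meant to detect.

Defaults are the desk-scale study conditions: N0 = 5,000, r = 0.05,
phi = 0.85, maturity 10 yr, cohorts 1996-2015, surveys 2011/2014/2015/
2017 at 165 samples each, ages 2-15, 1,500 loci with MAF ≥ 0.05 and
0.5% call error — sized to yield a few tens of HSPs in minutes while
preserving the real design's geometry.  Litter size is effectively one
egg-case draw per mating event; fecundity-at-age is unknown for the
species and not modelled.

What the simulator does not emulate — and hence what passing tests do
not demonstrate about field data: age-dependent or sex-biased
fecundity, non-random (spatially clustered) sampling when site
fidelity is on but the estimator assumes it off, gear selectivity
beyond the hard age window, linkage between loci, allele-frequency
estimation error in small samples, and real genotyping artefacts
(allelic dropout, batch effects) beyond the symmetric flip channel.

## Numerical and design choices

- HWE exact test: Monte-Carlo permutation of alleles (1,000 replicates
  by default), two-sided by conditional-probability ordering on
  Levene's distribution, with mid-p tie handling — without it the
  discrete support makes null p-values visibly conservative and the
  uniformity property fails.  Monomorphic loci return p = 1.
- LD pruning removes, from each offending pair (dosage r^2 > 0.8), the
  locus with the lower call rate, ties broken by dropping the later
  index; pairs are visited in index order, so output is deterministic
  and re-running removes nothing.
- The QC cascade re-applies locus filters after any duplicate-sample
  removal (call rates and MAFs change with the sample set), making the
  pipeline a fixed point of itself.
- Duplicate loci (the same marker assayed twice) are collapsed via an
  explicit clone-id map — they are not inferable from genotypes — and
  duplicate samples via a 10% pairwise-mismatch threshold, keeping the
  highest call rate in each group.
- MH initial state: a moment estimate `N_0 ~ 2 * comparisons / HSPs`
  (clipped into the prior); mid-prior when no HSPs.
- Test problem sizes: unit tests run a 400-adult, 15-cohort, 180-sample
  population at 300 loci; the end-to-end suite uses the full desk-scale
  scenario with 10^5-iteration fits (20 replicates for coverage) and a
  100-replicate generative-consistency study on 200-adult populations.

## Known limitations

Pseudo-likelihood intervals ignore pair dependence; abundance is
breeding adults only (a PO-pair design would be needed for total
abundance); the age-length key is itself preliminary, so cohort
assignment error is systematic, not just noisy — the sensitivity refit
probes it but cannot remove it; HS/FC separation is probabilistic and
the conservative exclusion slightly thins true HSPs; LD-Ne from
mixed-age samples has no per-generation interpretation.
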