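# skatekin

Close-kin mark-recapture (CKMR) demographic inference for data-limited
elasmobranch populations, built around the half-sibling-pair (HSP)
design used for long-lived benthic species such as the blue skate
(*Dipturus batis*): genotypes act as tags and detected relatives as
recaptures, so abundance, population growth, and adult survival can be
estimated from a single capture of each animal.

The package is aimed at fisheries geneticists and stock-assessment
scientists working with survey biopsies genotyped at thousands of SNPs.
It covers the full path from raw genotype matrix to posterior abundance
trajectory, together with the companion estimators usually reported
alongside a CKMR fit (genetic diversity, LD effective population size,
catch per unit effort, and the spatial distribution of kin pairs), and a
pedigreed forward simulator so every stage can be validated end to end
without any external data.

## The model

Ages are assigned from total length `L` (cm) by inverting the von
Bertalanffy growth curve and rounding down to whole years:

    L(t) = L_inf (1 - exp(-k (t - t0))),   L_inf = 149, k = 0.18, t0 = -0.49

Birth cohorts follow as capture year minus age.  For two individuals
with birth years `b_i < b_j`, the probability that they are half
siblings is

    P(HSP) = 4 / N_{b_j} * phi^(b_j - b_i)

where `N_t = N_0 exp(r t)` is the number of breeding adults and `phi`
the annual adult survival: individual *i*'s parent must survive the
cohort gap and then be one of *j*'s two parents among `N/2` candidates
of each sex.  Every cross-cohort pair contributes `P` (if it is an HSP)
or `1 - P` to a pseudo-likelihood — a product over non-independent
pairs — which is sampled by a component-wise random-walk
Metropolis-Hastings on `(log N_0, r, phi)` with uniform priors on
`r ∈ (-1, 1)` and `phi ∈ (0, 1)` and a log-uniform prior on `N_0`.

Kin pairs themselves are found by summed per-locus log-likelihood
ratios between relationship hypotheses defined by IBD-sharing
probabilities (kappa coefficients), with thresholds calibrated per
dataset from Monte-Carlo simulations at the observed allele frequencies
and far-tail false-positive rates estimated by importance sampling.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
bundled simulator (adults: N0 = 5,000, r = 0.05, phi = 0.85; four
survey years, 660 samples, 1,500 SNPs, 0.5% call error):

```bash
python analysis/01_simulate.py      # survey + genotypes + true pedigree
python analysis/02_qc.py            # SNP/sample filtering cascade
python analysis/03_kin.py           # threshold calibration + classification
python analysis/04_ckmr.py          # Metropolis-Hastings CKMR fit
python analysis/05_popgen.py        # heterozygosity + LD-Ne
python analysis/06_cpue_spatial.py  # CPUE + kin proximity test
```

Outputs land under `results/`.  A run at the default seeds prints,
among other things:

```
true related pairs among samples: {'HS': 52, 'HAV': 43, 'PO': 2}
n_comparisons: 217470
expected_false_positives: 0.04077
recovered_hs: 51    dropped_as_fc: 1    false_hs: 0

194621 cross-cohort comparisons, 41 HSPs, model year 0 = 1996
quantity     mean    lo2.5    hi97.5
      n0 6478.037 1972.776 16805.080
       r    0.042   -0.053    0.135
     phi    0.843    0.732    0.952
```

Reading this: of 52 true half-sibling pairs, 51 are recovered and one
is conservatively dropped as a possible distant relative; no unrelated
pair is flagged (the calibrated threshold budgets 0.1 expected false
positives over all 217k comparisons).  After age assignment from noisy
lengths, the age cap at 15 and same-cohort exclusion leave 41 HSPs in
194,621 comparisons, and the posterior 95% credible intervals bracket
the generative truth (5,000 / 0.05 / 0.85) for all three parameters.
The proximity test in `06` finds no sibling clustering in the spatially
random default (D = 0.11, p = 0.59) and strong clustering in the
site-fidelity control (D = 0.44, p = 0.0002).

A `skatekin` command-line interface exposes the same stages
(`simulate`, `qc`, `kin`, `ckmr`, `ne`, `cpue`, `all`) for use on real
genotype CSV/VCF and metadata files; see `skatekin --help`.

## Layout

- `src/skatekin/` — the library: `growth`, `simulate`, `qc`, `kin`,
  `ckmr`, `popgen`, `survey`, plus I/O, configuration, pipeline and CLI.
- `analysis/` — numbered narrative drivers (see above).
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — the model, its assumptions, and design choices.
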