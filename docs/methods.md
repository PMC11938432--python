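# Methods

## The estimation problem

Five phase-3, open-label randomized trials in treatment-naive pediatric
growth hormone deficiency each compare one weekly long-acting growth hormone
(LAGH) with daily somatropin at a 52-week time point. Because no trial
compares two LAGHs directly, every LAGH-vs-LAGH effect must be estimated
indirectly through the shared daily-somatropin comparator. The package does
this with a Bayesian network meta-analysis under the arm-based generalized
linear modelling formulation of evidence synthesis, restricted to fixed
effects: the network is too small to identify a between-study heterogeneity
variance or to test consistency formally, so one true relative effect per
contrast is assumed.

## Model

Let `i` index trials, `k` arms, `t_ik` the treatment in arm `k` of trial
`i`, and `t_i1` the trial's baseline treatment (the network reference when
present in the trial, otherwise its first treatment in network order).

* **Continuous outcomes** (annualized height velocity in cm/year; change
  from baseline in height SDS, weekly-average IGF-1 SDS and bone
  age-to-chronological age ratio): identity link,
  `y_ik ~ Normal(mu_i + d[t_ik] - d[t_i1], se_ik^2)` with
  `se_ik = sd_change_ik / sqrt(n_ik)` treated as known. Contrasts are mean
  differences.
* **Binary outcome** (serious adverse events by week 52): logit link,
  `r_ik ~ Binomial(n_ik, p_ik)`, `logit(p_ik) = mu_i + d[t_ik] - d[t_i1]`.
  Contrasts are odds ratios; the exact binomial likelihood is used rather
  than a normal approximation because event counts are small, and zero-event
  arms need no continuity correction — the likelihood remains proper under
  the priors.

Trial baselines `mu_i` are nuisance parameters; basic parameters `d_k` are
relative to daily somatropin with `d[reference] = 0`. The arm-based and
contrast-based parameterisations give identical fixed-effects estimates for
two-arm trials; the arm-based form was chosen because it generalises to
multi-arm trials (none exist in the shipped networks, but the engine
edge-expands them and is tested on synthetic ones). Point estimates are
posterior medians, intervals are central 95% credible intervals (2.5th and
97.5th percentiles), matching how such analyses are conventionally reported.

## Priors and sampling

Priors are `Normal(0, 100^2)` on both `d_k` and `mu_i` on the model scale
(outcome units, or log-odds), the conventional vague default for this model
family; both SDs are configurable. With the arm SEs known, the continuous
model is conditionally conjugate, so it is sampled by Gibbs (every full
conditional is normal); the binomial-logit model is sampled by random-walk
Metropolis-within-Gibbs whose proposal scales adapt toward ~44% acceptance
during burn-in only and are frozen afterwards, preserving detailed balance
in the retained draws. Defaults: 4 chains x 20,000 iterations with 5,000
burn-in and no thinning (60,000 retained draws). All chains advance in
lock-step from one seeded generator, so a given seed reproduces draws
bit-for-bit.

Every fit is gated on convergence: split-R-hat ≤ 1.05 and bulk ESS ≥ 400
(computed via arviz) for every basic parameter, else the run raises instead
of returning silently. The gate's thresholds are the package's own
reproducibility requirement, not an external prescription. Chain-shaped
networks induce strong posterior correlation among basic parameters under
component-wise Metropolis, so binary fits on non-star topologies need a
generous draw budget; the Gibbs sampler is essentially unaffected.

## Preprocessing

Publications rarely report everything the likelihood needs. Three
reconstructions are supported, each recorded in a per-arm ledger
(reported vs derived vs imputed):

* **SE from interval**: `se = (upper - lower) / (2 z)`, `z = 1.959964` for
  95% intervals (the exact normal quantile, not 1.96, so reconstructions are
  reproducible to more digits than the printed intervals).
* **Change-SD imputation**: `sd_c = sqrt(sd_b^2 + sd_f^2 - 2 r sd_b sd_f)`
  from baseline/follow-up SDs and a correlation `r`. A reported change SD
  always wins; imputation is a fallback only.
* **Pooled correlation**: inverting the same identity per complete
  (baseline, follow-up, change) SD triple and averaging with equal weights
  across all outcomes, clamped to [-1, 1]. The unweighted mean is the
  simplest defensible pooling rule given the very small pool of complete
  triples such data sets offer; the number of pairs used is carried in the
  estimate's metadata. The two operations are exact mutual inverses, which
  the tests verify to 1e-12.

The sign convention is "A vs B" = A - B everywhere, with the LAGH as A and
daily somatropin as B in direct estimates.

## Evidence networks and feasibility

Networks are built per outcome and analytic scenario (base case:
thornton2021, deal2022, miller2022; sensitivity analysis 1 adds
khadilkar2007/LB03002; sensitivity analysis 2 adds horikawa2022, a second
somatrogon trial). Two rules gate analysis: at least two studies in the
scenario must report the outcome at week 52 at approved doses, and the
network must be one connected component containing the reference. The
approved-dose criterion is data (a per-arm flag), not something derivable
from first principles. The shipped networks are stars around daily
somatropin; the code never assumes that for arbitrary inputs.

## Rankings

Within each retained draw treatments are ranked on `d` (descending for
benefits — height velocity, height SDS, IGF-1 SDS; ascending for harms —
SAEs; bone-age ratio defaults to lower-better but is configurable since its
clinical direction is arguable). SUCRA is
`(1/(K-1)) * sum_{j<K} P(rank <= j)`; its mean over treatments is exactly
0.5 for any valid rank-probability matrix, probability-best is the first
column of that matrix, and for K = 2 SUCRA equals probability-best — all
three identities are tested. Ties (measure-zero under continuous
posteriors) break deterministically toward the treatment earlier in the
network's node order. Reports round SUCRA to whole percent but store full
precision.

## Synthetic data

The generator simulates individual patients and then aggregates, so the
summary-level structure the analysis assumes — change SDs, the
baseline/follow-up correlation (default `r_true = 0.6`, a typical value for
growth measures a year apart), binomial event counts — is emergent rather
than asserted, which makes the imputation path honestly testable. The
base-case-shaped network uses the published arm sizes (105/56, 109/115,
132/68; 91/87 and 22/22 for the sensitivity trials) and true contrasts equal
to the published direct mean differences, with within-arm SDs set to
plausible magnitudes per outcome (2.2 cm/year for height velocity, 0.5 for
height SDS, 1.0 for IGF-1 SDS, 0.12 for the bone-age ratio) and a 5%
reference SAE rate. The generator does not simulate dropout, dose
titration, visit-window jitter or non-normal outcome distributions, so
passing tests demonstrate correctness of the estimator under its own
assumptions, not robustness to real-data pathologies.

## Bundled fixtures

The analysed trials' arm-level 52-week tables are unpublished (available
only on request from the original investigators), so the bundled CSVs are
reconstructions: arm-level cells are synthetic values constrained so each
trial's direct contrast reproduces the published trial-level estimate
(provenance `derived`), plausible synthetic values elsewhere (`synthetic`),
with published baseline characteristics carried verbatim. The
`direct_estimates.csv` fixture holds the published contrasts themselves;
the somapacitan-vs-daily direct estimates are not published individually and
are derived by star-network consistency with SEs by variance subtraction.
Because a fixed-effects star network is fully determined by its trial-level
contrasts, worked examples built this way must — and do — reproduce the
published indirect estimates; that is a check of the engine, not of the
fixture.

## Numerical and design choices

* Treatment and trial ids are case-insensitive tokens; display labels are
  carried separately.
* Missing CSV cells are missing values; 0 is always a legal value.
* Node order is reference-first then lexicographic; network construction is
  order-independent and idempotent.
* The frequentist inverse-variance (WLS) network estimator is implemented
  solely as an independent validation oracle — it equals the Bayesian
  posterior in the vague-prior normal limit — and raises on rank-deficient
  designs rather than pseudo-inverting.
* Degenerate inputs fail loudly: non-positive SEs, events outside [0, n],
  disconnected networks, single-study outcomes, inverted intervals.

Validation suites use reduced problem sizes chosen as the package's own
defaults for routine checking: oracle-equivalence on 30 continuous and 20
binary random connected networks (K ≤ 5, ≤ 8 trials) at ~10-44k retained
draws per fit, and credible-interval coverage over 200 simulated base-case
networks at 5,000 retained draws per fit, pooled across the three basic
parameters and tested against the nominal 95% level by a two-sided binomial
test at alpha = 0.01. Headline worked examples always use the full 60,000
retained draws.

## Limitations

* Fixed effects only: no heterogeneity variance, no node-splitting
  inconsistency assessment, no meta-regression — the network is too sparse
  for any of them.
* Arm SEs are plug-in values; uncertainty in reconstructed or imputed SDs
  (including the correlation `r`) is not propagated.
* The pooled correlation estimator's algebra is verifiable, but the original
  analysis's numeric `r` is unpublished, so it cannot be reproduced.
* SUCRA values depend on the whole network; with unpublished arm-level data
  only the headline probabilities can be sanity-checked, not the full
  supplementary ranking tables.
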