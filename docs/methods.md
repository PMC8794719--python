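# Methods

This note documents the statistical machinery, the defaults and why
they were chosen, and what the synthetic-data tests do and do not show.

## Demographic year and data structures

The demographic year runs March–February (month index 1 = March),
matching the survival-monitoring year; a calendar-year label is the
year containing March. Seasons tile the year as breeding (Apr–Jul),
fall (Aug–Nov) and winter (Dec–Mar), so within one demographic year the
winter block is months 10–12 plus month 1. A yearling (SY) alive at the
end of February is an adult (ASY) the following March; the reader
applies this transition only to confirmed-alive birds — a February
censoring leaves the recorded age untouched, since the transition is
conditional on survival that censoring cannot confirm.

Encounter data are long-format CSV (one row per observed interval)
rather than packed capture-history strings: transparent, diff-able,
and round-trip exact. A one-way exporter to known-fate "LDLD" strings
is provided for interoperability with legacy tools but is never read
back.

## Closed-form rates

Nest initiation is a sample proportion with variance pq/n, pooled
across years by summing integer successes and trials (the
sample-size-weighted mean). When only printed proportions are
available, integer numerators are reconstructed as round(p·n) before
pooling; this reproduces pooled multi-year rates exactly, which
averaging rounded proportions does not. Re-nest clutch sizes are
first-nest clutch means minus fixed meta-analytic offsets (1.39 eggs
for yearlings, 1.63 for adults); re-nest SDs default to 0.40 (SY) and
0.30 (ASY) and are config-overridable. Hatchability pools eggs hatched
over eggs laid among successful nests.

Juvenile survival (54 days post-hatch to first breeding, ~7 months) is
derived from annual adult survival as 0.7 · S_ASY^(7/12): the exponent
rescales the annual rate to 7 months and 0.7 is the juvenile:adult
survival ratio (0.53/0.83) from a reference population. The exact
fraction 7/12 is used rather than the rounded 0.58; the difference is
below 0.002 on the survival scale. The derived rate carries a fixed SE
of 0.07 (carried from the reference study, not propagated). An additive
GPS-vs-VHF transmitter bias correction (+0.05 on annual survival,
capped at 1) is available for field data; an additive constant leaves
SEs unchanged. It is off in the synthetic pipeline, which does not
simulate transmitter effects.

## Known-fate survival engine

Interval survival is Bernoulli with a logit-linear predictor; animals
contribute only monitored intervals (staggered entry, censoring).
Designs combine year, age, season/month/day categoricals, a within-
window linear trend T (scaled to [0, 1] for conditioning) and the
incubation start date (scaled similarly). Categorical terms use
drop-first reference coding; `a * b` expands to main effects plus
products.

Fitting is deterministic quasi-Newton (BFGS, zero start, analytic
gradient, gradient tolerance 1e-8). Complete or quasi-complete
separation — e.g. a year in which every monitored bird survived — is
detected as a coefficient beyond ±10 logits and handled by a weak ridge
refit (prior variance 100 on the logit scale) with a logged flag, so
boundary datasets produce finite, flagged estimates instead of
failures. AICc uses n_effective = number of monitored
individual-intervals (exposure days for nests, bird-months for
females); models whose AICc small-sample term is undefined
(n − K − 1 ≤ 0) are assigned infinite AICc and effectively excluded,
which is why the saturated year×interval designs are not in the default
sets. Deviance columns of legacy software are not reproduced; the
tables report −2 log L.

Model averaging uses Akaike weights with the unconditional variance
Σ wᵢ (varᵢ + (θᵢ − θ̄)²). Window products (27-day nest survival,
4-month seasonal and 12-month annual female survival) take the product
of per-interval estimates with delta-method SEs; a per-model exact
variant propagates the coefficient covariance through the product.

Nest analyses run separately for SY first nests, ASY first nests and
pooled re-nests; the female analysis is a single run whose model set
keeps year + age in every candidate.

## Brood-count chick survival

Brood counts follow a latent-count state-space model: A₀ = eggs
hatched (treated as exact — the initial count comes from the nest bowl,
not a flush), Aₜ | Aₜ₋₁ ~ Binomial(Aₜ₋₁, φₜ), yₜ | Aₜ ~
Binomial(Aₜ, ρₜ). The likelihood marginalizes the latent counts by an
exact forward dynamic program (states 0..A₀; no truncation is needed at
grouse brood sizes). φ and ρ carry logit-linear year / trend /
count-interval structures; selection is two-stage (detection structures
under year-varying survival, then survival structures under the winning
detection model). 54-day chick survival per year is the product of the
five interval survivals. Zero counts are ordinary observations — the
field rule that declares a brood failed after two empty flushes is a
data-collection stopping rule, not a likelihood term. Ages are pooled.
Brood adoption is not modeled.

## Matrix model and bootstrap

The point λ per year is the dominant eigenvalue of the matrix built
from mean vital rates, computed in closed form for the 2×2 case
(λ = (tr + √((a₁₁−a₂₂)² + 4a₁₂a₂₁))/2) and checked against the general
solver to 1e-12. The bootstrap redraws every stochastic lower-level
rate per replicate — beta distributions moment-matched to (mean, SE)
for probabilities, normals truncated to [1, 15] eggs for clutch sizes —
rebuilds both fecundities and the matrix, and records λ; the 95% CI is
the 2.5/97.5 percentile over 10,000 replicates. Zero-SE rates are held
fixed; hatchability is fixed by default (SE 0.001; a flag resamples
it). Infeasible beta moment matches (variance ≥ m(1−m)) are clipped to
0.95·m(1−m) with a warning, preserving the mean at maximal proper
dispersion. A single seeded generator drives a run; per-stage
substreams make runs bit-reproducible and insensitive to stage order.

**Juvenile-survival mode.** The tabled S_juv values are not all
consistent with the stated derivation from adult survival, so the mode
is explicit. The default, `sjuv_mode="derived"`, recomputes S_juv from
each adult-survival draw (0.7 · S_ASY^(7/12)), keeping the two rates
coherent within a replicate; it reproduces the published multi-year λ
summaries closely (geometric mean 0.644 point / 0.634 replicate mean
vs 0.63 printed). `sjuv_mode="table"` draws S_juv as an independent
beta from its tabled mean/SE; that mode reproduces the published
qualitative CI classifications (declines supported in 2013, 2014 and
2018; CIs overlapping 1.0 in 2015–2017). Re-nest clutch size
analogously: `cs2_mode="table"` (independent draw of the tabled CS2,
the default) or `"offset"` (recomputed per draw as CS1 − offset);
missing CS2 rows always fall back to the offset rule.

Annual classification: decreasing if the CI lies below 1, increasing if
above, stable only in the degenerate equality case, otherwise
uncertain. The multi-year geometric mean is reported on two pathways:
geometric mean of annual point estimates, and mean/percentiles of
per-replicate geometric means with replicates paired across years by
index (independent annual draws).

## LTRE

Sensitivities are analytic: ∂λ/∂a_kl = v_k w_l / ⟨v, w⟩ from the left
and right eigenvectors, chained through the matrix entries and the
fecundity equation's partials; they match central finite differences to
better than 1e-5 relative and are invariant to eigenvector scaling (the
implementation normalizes ⟨v, w⟩ = 1). Contributions are
(x_treatment − x_reference) · sensitivity, reported treatment-minus-
reference so a rate that improved after the reference year contributes
positively. Vital rates enter as independent parameters, with S_juv
taken from the table (it carries its own estimate there).

The evaluation matrix is selectable: `reference`, `treatment`, or
`midpoint`. The default is `reference` — sensitivities evaluated at the
reference-year matrix — which reproduces the published contribution
totals almost exactly (adult survival 1.289, juvenile 0.335, adult
first-nest NS 0.119, chick 0.091); the midpoint rule, the usual
two-treatment choice, yields the same ranking with larger totals and
remains available for sensitivity analysis. First-order adequacy is
checked by comparing Σ contributions with the actual λ difference.

## Synthetic data

The generator emulates the field design: staggered spring entry and
Bernoulli monthly survival at S_annual^(1/12) for females (optional
censoring, default 2%/month); Bernoulli nest initiation, daily nest
survival at NS^(1/27) and re-nesting after failed first attempts;
binomial chick thinning at S_chick^(1/5) with binomial flush counts
under an increasing detection trajectory (0.3 → 0.9, matching the
fitted range). Default truth values and cohort sizes mirror the
packaged 2013–2018 table, so recovery tests carry the study's actual
information content.

What the generator does not emulate: individual heterogeneity and
overdispersion, within-year survival seasonality (unless injected),
transmitter effects, brood adoption or double counting, and
non-random censoring. Passing tests therefore demonstrate correctness
of the estimators under the assumed generating processes at realistic
sample sizes — not robustness to the violations above.

## Problem sizes in the test suite

The suite simulates at the study's cohort sizes (tens of females and
nests per year, ~60 broods). Recovery checks use 60–100 replicate
datasets; the female-survival recovery check runs at 50 females/year,
the study's upper-range yearly cohort, where the binomial information
supports the 0.05 median-error criterion. The full
simulate→estimate→λ closure runs 20 seeded studies with reduced model
sets and 500 bootstrap replicates; across the ~120 year-by-seed
comparisons the standardized error has median ≈ 1, i.e. the bootstrap
spread is calibrated, with occasional heavy-tailed years from very
small cohorts (8–16 birds) — the test asserts that calibration plus a
90% three-sigma coverage floor rather than a hard every-comparison
bound.

## Known limitations

- No density dependence, environmental stochasticity beyond parameter
  uncertainty, male demography, or stage structure beyond two ages.
- Clutch sizes and hatchability cannot be estimated from encounter
  histories (they come from egg counts), so the estimation pipeline
  passes them through from a base table.
- The brood model's SE for 54-day survival in the pipeline uses a
  binomial-scale approximation on the brood sample rather than the
  full information matrix.
- LTRE is the classical fixed-design decomposition; random-effects and
  transient variants are out of scope.
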