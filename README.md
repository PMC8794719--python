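# sagepop

Demographic analysis of a greater sage-grouse (*Centrocercus
urophasianus*) population recovering from a mega-wildfire: vital-rate
estimation, stochastic age-structured matrix models of annual population
growth, and a life-table response experiment (LTRE) attributing
variation in growth to individual vital rates.

The package is aimed at quantitative wildlife ecologists who work with
telemetry-based encounter data: daily nest fates over a 27-day
incubation window, monthly known-fate records for radio-marked females
(March–February, staggered entry, censoring), and repeated brood flush
counts with imperfect detection.

## The model

Annual dynamics of yearling (SY) and adult (ASY) females follow a 2×2
pre-birth-pulse projection matrix

```
A = | F_SY · S_juv   F_ASY · S_juv |
    | S_SY           S_ASY         |
```

with age-specific fecundity built from the lower-level rates

```
F_j = [ NI1·CS1·NS1 + (1 − NS1)·NI2·CS2·NS2 ] · H · 0.5 · S_chick
```

(NI = nest initiation, CS = clutch size, NS = 27-day nest survival,
subscripts 1/2 = first nest / re-nest, H = hatchability, S_chick =
54-day chick survival; 0.5 is the offspring sex ratio). The finite rate
of population change λ is the dominant eigenvalue of A. Uncertainty
comes from a parametric bootstrap (10,000 replicates; beta draws for
probabilities moment-matched to mean/SE, truncated normals for clutch
sizes). The LTRE decomposes λ differences between a reference year and
each later year into per-rate contributions (rate difference ×
analytic sensitivity ∂λ/∂x via the eigenvectors and the chain rule
through the fecundity equation).

Estimation layers below the matrix: closed-form proportions for nest
initiation and hatchability, a known-fate Bernoulli-logit likelihood
with AICc model selection and model averaging for daily nest survival
and monthly female survival, and an exact latent-count state-space
likelihood (binomial thinning + binomial detection) for chick survival
from brood counts.

## Worked example

The packaged vital-rate table (2013–2018, Trout Creek Mountains,
Oregon/Nevada) drives the whole pipeline:

```
sagepop all --seed 1 --out run1
```

which prints (abridged):

```
| year | lambda | boot mean | 95% CI | classification |
|------|--------|-----------|--------|----------------|
| 2013 | 0.312 | 0.312 | (0.18, 0.47) | decreasing |
| 2014 | 0.588 | 0.586 | (0.35, 0.86) | decreasing |
| 2015 | 1.057 | 1.052 | (0.81, 1.30) | uncertain |
| 2016 | 0.741 | 0.740 | (0.56, 0.92) | decreasing |
| 2017 | 0.768 | 0.768 | (0.58, 0.96) | decreasing |
| 2018 | 0.647 | 0.646 | (0.41, 0.88) | decreasing |

Geometric mean lambda 2013-2018: 0.644 (replicate mean 0.634, 95% CI 0.54-0.73)

## LTRE totals (treatment minus reference)
NS1_ASY    0.1186
S_chick    0.0907
S_juv      0.3346
S_SY       0.2756
S_ASY      1.2893
```

(the LTRE block of the report lists all 15 lower-level rates; the five
shown here are the dominant ones)

Reading: the population declined in most years (λ < 1, CI below 1),
with a possible recovery year in 2015. Relative to the first post-fire
year, later years' higher λ is attributed overwhelmingly to improved
adult female survival (total contribution 1.29), then juvenile and
yearling survival; among fecundity components, adult first-nest
survival (0.12) and chick survival (0.09) lead. Equivalent library
calls: `bootstrap_lambda`, `multi_year_summary`, `ltre_contributions`
(see docstrings).

Synthetic studies with known truth — the basis of every recovery test —
come from `sagepop simulate --seed 0 --out sim/` or the
`sagepop.synthetic_data` API, and can be re-estimated with
`sagepop rates`.

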