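# Methods

This note records the models, conventions and numerical choices behind
`tempbeta`, and what the synthetic-data tests do and do not demonstrate.

## Dissimilarity partition

All dissimilarities are presence/absence (Sørensen family).  Pairwise
matching components `a` (shared), `b`, `c` (exclusive) are kept as exact
integers; division happens once at the end, so the additivity identity
`β_sor = β_sim + β_sne` holds to machine precision rather than to rounding.

Multiple-site dissimilarities are computed from the sums
`Σ_i S_i` (total of per-site richness), `S_T` (pooled richness), and
`Σ_{i<j} min(b_ij, b_ji)`, `Σ_{i<j} max(b_ij, b_ji)` over pairwise
exclusive-species counts:

```
β_SIM = Σmin / ((Σ_i S_i − S_T) + Σmin)
β_SOR = (Σmin + Σmax) / (2(Σ_i S_i − S_T) + Σmin + Σmax)
β_SNE = β_SOR − β_SIM
```

These are genuine whole-set measures, not averages of pairwise values; at
exactly two sites they reduce to the pairwise formulas, which the tests
assert exactly.

**Degenerate pairs.**  Temporal comparisons require non-empty assemblages
at both dates; sites empty at either census are removed up front (and
reported), because every denominator vanishes for two empty assemblages.
In *spatial* pairwise matrices a pair with exactly one empty assemblage is
assigned the nested-case limit `β_sor = 1, β_sim = 0, β_sne = 1` (the
richer assemblage's species are "lost" entirely; there is no replacement),
and the pair is distinguishable downstream because only two-empty pairs are
NaN.  This convention is a package choice for completeness of the matrices;
the temporal analysis never relies on it.

## FE null model

The null hypothesis is stochastic occupancy dynamics over a fixed regional
pool: each species keeps its regional frequency while its presences land on
uniformly random sites (frequencies Fixed, sites Equiprobable).  Each
replicate re-draws every species' site subset independently via the
rank-of-uniforms construction, which yields a uniform k-subset per column
and conserves column sums exactly — a hard assertion in the tests.
The default reshuffles the *later* census's frequencies, since the null
assemblage stands in for the later state in the temporal comparison; a flag
selects the earlier one (the two differ only when frequencies changed).

Per-site null temporal dissimilarities compare the earlier census with each
null assemblage.  A null assemblage can leave a site empty; that draw is
undefined for the site (NaN) and excluded from its null distribution,
mirroring the removal of empty sites in the observed analysis.  Sites with
fewer than 100 defined draws are flagged unreliable rather than silently
tested.

**Percentile test.**  Two-sided at level α = 0.05: a site is `lower` /
`higher` if its observed value falls strictly below / above the empirical
2.5 / 97.5 percentile (linear-interpolation order-statistic quantiles) of
its defined null draws.  The strict inequality is deliberately
conservative: per-site null distributions are discrete (small integer
counts), ties at the bounds are common, and a tie never rejects.  On
neutral data the realised two-sided rejection rate is therefore ≈ 2–3%
rather than the nominal 5%; the calibration test asserts the rate inside
the 99% binomial envelope around 5%, averaged over ten data realisations
to suppress single-run Monte-Carlo noise.

**Distribution comparison.**  One two-sample Kolmogorov–Smirnov test per
null replicate (observed per-site values vs that replicate's), reporting
the distribution of (D, p) across the 1000 replicates.  Asymptotic
two-sided p-values are used; at ~252 values per sample the exact and
asymptotic versions are practically indistinguishable.

**ANOVA by significance class.**  One class (e.g. `higher` for turnover)
against all other sites, one-way two-group ANOVA with df (1, n−2), reported
with r² = SS_between/SS_total.  Because "intensity" of land-cover change is
ambiguous between signed and absolute change, both are computed per
variable.

## Piecewise regression with breakpoint at zero

Temporal dissimilarity components are regressed on per-site land-cover
change with separate lines for losses (`x < 0`) and gains (`x > 0`),
discontinuous at zero.  Sites with exactly zero change — common in
practice, since a cover absent at both dates has not changed — form their
own level at the breakpoint.  With all three classes populated the model
has five estimable coefficients, so the overall F against the
intercept-only model carries df (4, n−5): (4, 247) at 252 sites.  Without
exact zeros the zero level is empty and df become (3, n−4); with a
single-signed predictor the model falls back to one line (flagged).  This
form was chosen over the four-coefficient two-line design (shared global
intercept, zeros merged into one branch) because the five-coefficient
model is what a saturated two-indicator interaction fit estimates when
zero-change observations exist, and its df match the study design above.
Reported coefficients are translated to
(negative-branch intercept, negative slope, level shift at 0⁺, slope
difference).

Standardised change `(v2 − v1)/(v2 + v1 + 1)` weights absolute change by
the cover present (the +1 avoids 0/0 and bounds the measure in (−1, 1));
both raw and standardised fits are always produced.  Bonferroni correction
defaults to m = number of fits per family (12 = 6 variables × 2
components), configurable because the appropriate family is a judgement
call.

## Spatial change

`multisite_resample` draws site subsets uniformly without replacement
(default 50 sites, 1000 samples).  `compare_distributions` reports
p = P(value₂ < value₁) + ½·P(tie) over all n² cross pairs: the probability
of observing the ordering opposite to a rise between censuses.  The
direction is fixed by argument order, which makes the measure exactly
antisymmetric under swapping (p → 1 − p); the significance of an observed
*decline* is 1 − p, and drivers report min(p, 1 − p) as the one-sided
significance of the observed difference.  A replicate-paired variant is
available behind a flag.

`mantel` correlates lower-triangle entries (Pearson) and permutes the site
labels of one matrix jointly over rows and columns,
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm), one-sided "greater" (the
question is whether pairwise structure is *preserved*).  n_perm defaults
to 999; an `exact=True` mode enumerates all n! permutations and is tested
against an independent enumeration oracle at n = 4.

## Synthetic metacommunity generator

The generator emulates the study system the pipeline targets, with
defaults frozen so tests are stable:

| parameter | default | meaning |
|---|---|---|
| `n_sites`, `n_species` | 256, 47 | study scale |
| `mean_richness` | 7.1 | calibrates occupancy level (per-site richness ≈ 0–18) |
| `occupancy_sigma` | 1.1 | log-normal spread: few widespread, many scarce species |
| `lambda_det` | 0 | determinism weight: 0 = FE-style stochastic turnover, 1 = land-cover-driven |
| `effect_scale` | 3.0 | sd of per-species habitat-affinity coefficients |
| `softmax_temperature` | 1.0 | sharpness of suitability → site choice |
| `landcover_noise` | 6.0 | site-level sd of the crop↔woodland/grassland exchanges (points) |
| `dirichlet_concentration` | 3.0 | heterogeneity of first-date land-cover mosaics |

**Land cover.**  First-date covers are Dirichlet mosaics around regional
means (woodland 25%, grassland 33%, crop 27%, fallows 8%, an unmapped
remainder for housing/roads; hedgerow ~169 m from a shifted gamma, ~4% of
sites hedge-free).  Covers under 1% are set to absent, so zero-change sites
exist as in real digitised data.  Change is modelled as *area conversion*:
each site loses a Beta-distributed fraction of its grassland and fallows
(mean fractions set so the regional mean losses are −16, −2, −2 points) and
the freed area is reallocated to crop and woodland in 18:2 proportion, plus
availability-damped symmetric crop↔woodland and crop↔grassland exchanges.
This conserves the per-site percentage budget, keeps every change feasible,
and hits the regional mean drifts (crop +18, grassland −16, woodland +2
points; hedgerow −27 m) by construction rather than after clipping.

**Censuses.**  Species occupancy probabilities are log-normal weights
rescaled to the target mean richness.  The first census places each
species' Binomial(n, p) presences by Gumbel-top-k sampling over a habitat
suitability score (dot product of standardised covers and the species'
affinity vector) scaled by `lambda_det` — uniform at 0.  The second census
keeps each species' frequency exactly and, per species, either reshuffles
uniformly (probability 1 − `lambda_det`) or re-places presences fully
suitability-weighted against the *second-date* covers.  Frequencies are
thus identical between censuses for every `lambda_det`, so at
`lambda_det = 0` the data-generating process *is* the FE null and the
pipeline's rejection rate measures pure type-I error.

**What the synthetic tests show — and don't.**  Passing calibration and
power tests shows the pipeline is statistically sound on data whose
generating process matches its assumptions: no spatial autocorrelation of
occupancy, no dispersal limitation, no species interactions, no abundance
structure, frequencies exactly conserved.  Real censuses violate all of
these to some degree (detection error alone breaks exact frequency
conservation), so results on real data inherit the usual caveats of FE
null models; the tests certify the machinery, not the ecology.

## Problem sizes and runtime choices

The default test suite and the acceptance script run the full study scale
(256 × 47, 1000 null replicates, 1000 resampling draws, 999 Mantel
permutations); a single full pipeline pass takes a few seconds because the
reshuffle and the per-site components are vectorised.  Exhaustive oracles
(all reshuffles, all subsets, all permutations) run on deliberately tiny
systems — 5 sites × 3 species, C(10,4) subsets, 4! permutations — where
enumeration is exact.

## Known limitations

* The one-empty-pair convention in spatial matrices is a defined limit, not
  an estimate; analyses sensitive to near-empty sites should drop them.
* KS tests across null replicates reuse the same observed sample, so the
  1000 (D, p) pairs are dependent; they describe robustness, not 1000
  independent tests.
* The Mantel permutation p is one-sided for positive association; testing
  for *dissimilarity structure reversal* would need the other tail.
* `anova_by_class` is the classical equal-variance two-group test; with
  strongly unbalanced classes (a handful of flagged sites) its p-values are
  approximate at best — effect sizes (r²) are reported alongside for this
  reason.
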