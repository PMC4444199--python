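# tempbeta

Temporal beta-diversity analysis for paired presence/absence censuses of the
same sites, built for the question: **when a community changes over decades,
how much of that change is driven by environmental (land-cover) change, and
how much is indistinguishable from stochastic colonisation and extinction?**
The motivating setting is bird point counts in a mosaic agricultural
landscape (~256 sites, ~47 species, two censuses 25 years apart, six
land-cover variables per site), but every stage works on any pair of
site × species 0/1 tables.

## What it computes

**Partition of dissimilarity.** For two assemblages with `a` shared species
and `b`, `c` species unique to each,

```
β_sor = (b + c) / (2a + b + c)            total (Sørensen) dissimilarity
β_sim = min(b, c) / (a + min(b, c))       turnover (Simpson): true replacement
β_sne = β_sor − β_sim                     nestedness-resultant: nested gain/loss
```

applied per site through time (`temporal_partition`), across all site pairs
within a census (`spatial_pairwise`), and as multiple-site dissimilarities
`β_SOR/β_SIM/β_SNE` built from sums of pairwise exclusive-species counts
(`multisite_partition`), which reduce exactly to the pairwise formulas at
two sites.

**FE null model.** `null_dissimilarity_ensemble` reshuffles each species'
presences to uniformly random sites while keeping its occupancy frequency
fixed (null model FE: Frequencies fixed, sites Equiprobable), builds 1000
null assemblages, and measures null temporal dissimilarities against the
first census.  Observed values are tested two-sided per site at the
empirical 2.5/97.5 percentiles (`site_significance`), whole distributions
are compared with one Kolmogorov–Smirnov test per null replicate
(`ks_compare`/`ks_repeated`), and two-group ANOVAs ask whether flagged sites
experienced different land-cover change (`anova_by_class`).

**Spatial heterogeneity through time.** `multisite_resample` draws 1000
random 50-site subsets per census and compares the two multiple-site
dissimilarity distributions empirically (`compare_distributions`);
`mantel` runs a permutation Mantel test between the censuses' pairwise
dissimilarity matrices.

**Land-cover association.** `compute_change` gives per-site raw change
`Δv = v2007 − v1982` and standardised change `(v2007 − v1982)/(v2007 + v1982 + 1)`;
`piecewise_fit`/`fit_all` regress each dissimilarity component on each
change variable with a breakpoint at zero (separate lines for losses and
gains; unchanged sites form their own level, so the overall F carries
df (4, n−5), e.g. (4, 247) at 252 sites).

**Synthetic metacommunity.** `tempbeta.synthetic_data` generates paired
censuses and land-cover tables at study scale, with a determinism weight
`lambda_det` sliding between pure frequency-preserving stochastic turnover
(0) and fully land-cover-driven reassignment (1), so calibration and power
of the whole pipeline are testable without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1), writing tables under `results/`:

```
python analysis/01_simulate.py 1
python analysis/02_temporal_partition.py
python analysis/03_landcover_regression.py
python analysis/04_spatial_beta.py 1
python analysis/05_null_model_test.py 1
```

prints, among other lines:

```
[neutral] 256 sites kept (0 empty-either removed); turnover mean 0.62 (SD 0.20), nestedness mean 0.07 (SD 0.09)
[neutral] top fits: sim~woodland: r2=0.025, F(3,252)=2.15, p=0.095; ...; 0/24 significant after Bonferroni
[neutral] KS D in [0.016, 0.133], p<0.05 in 0% of replicates; sim lower/higher = 3/1, sne lower/higher = 0/6 of 256 sites
[planted] top fits: sim~crop: r2=0.146, F(3,252)=14.41, p=1.07e-08; ...; 6/24 significant after Bonferroni
[planted] KS D in [0.105, 0.605], p<0.05 in 99% of replicates; sim lower/higher = 103/0, sne lower/higher = 11/53 of 256 sites
```

Reading this: in the *neutral* scenario (pure stochastic turnover) the
land-cover regressions explain essentially nothing (all r² ≤ 0.03), the
observed dissimilarity distribution is indistinguishable from the null
model's, and roughly the nominal share of sites is flagged — the pipeline
does not invent signal.  In the *planted* scenario (species reassigned by
crop affinity) the crop regression dominates by an order of magnitude, the
KS test rejects in 99% of null replicates, and the turnover component falls
outside its null percentile bounds at 40% of sites (25% for nestedness) — the pipeline recovers the planted driver.

The CLI mirrors the same stages on arbitrary CSV inputs:

```
tempbeta --seed 1 --out-dir run simulate
tempbeta --seed 1 --out-dir run temporal run/birds_t1.csv run/birds_t2.csv \
    run/landcover_t1.csv run/landcover_t2.csv
tempbeta --seed 1 --out-dir run nulltest run/birds_t1.csv run/birds_t2.csv
tempbeta --seed 1 --out-dir run spatial run/birds_t1.csv run/birds_t2.csv
tempbeta --seed 1 --out-dir run report
```

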