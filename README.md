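# ptbstrat

Municipality-level **preterm-birth (PTB) risk stratification** from
socioeconomic (SES) microdata, via a two-level consensus-clustering
pipeline: a multiple-k-means centroid ensemble over municipality SES
profiles, target-filtered by each cluster's preterm rate, merged by
DBSCAN over centroid correlation profiles, and mapped back to
municipalities as high-/low-risk strata.

It is aimed at epidemiologists and health-policy analysts who want
area-level risk strata from administrative registries (birth records,
social-programme person/household microdata, population estimates)
without clustering on the outcome itself.

## The metric and the method

For each municipality the **preterm municipal rate** is

    PMR = NNP / NP

with `NNP` the number of resident births under 37 weeks of gestation and
`NP` the total population (population, not births: small birth
denominators make the rate explode). Clustering uses only SES features —
one-hot category shares averaged per municipality; PMR is held out and
re-enters solely to select **clusters of interest (CoI)**: base clusters
whose mean member PMR deviates at least 10% (relative) from the national
rate.

The pipeline: outlier removal (±3 SD on PMR) → PCA to 95% variance →
Yeo–Johnson / row-L2 / min-max cascade → N = 290 k-means models (centre
counts 2..30, ten seeds each; all L = Σ Nc_i = 4640 centroids pooled) →
CoI filter → Pearson correlation between surviving centroids → PCA to
99% → min-max → DBSCAN (eps 0.06, min 50 occurrences) → per-municipality
dominant cluster, high/low type and signed intensity. An evaluation
layer adds pairwise Welch t-test matrices (with seeded half-split
self-controls), per-cluster feature contrasts against the national
average, PMR distribution summaries and t-SNE/SVM segment maps.

Because the source registries are not redistributable at record level,
the package ships a synthetic generator that emulates their schemas and
plants latent SES strata with a stratum-linked preterm probability, so
the whole pipeline runs and is validated end to end with no downloads.
See `docs/methods.md` for assumptions, defaults, and what the synthetic
benchmark does and does not demonstrate.

## Worked example

```python
from ptbstrat import (PTBStratification, benchmark_config,
                      EnsembleConfig, DBSCANParams)
from ptbstrat.synthdata import generate_municipality_table

cfg = benchmark_config(n_per_stratum=100, seed=1)   # 2 high + 2 low strata
a0, labels = generate_municipality_table(cfg)

res = PTBStratification(
    a0,
    ensemble=EnsembleConfig(nc_values=tuple(range(2, 13)), reps_per_nc=5, seed=1),
    dbscan=DBSCANParams(eps=0.06, min_points=10),   # scaled-down ensemble
    seed=1,
).fit()
print(res.summary())
```

```
Preterm-birth municipal stratification
======================================================
municipalities (input A0)           400
PMR outliers removed                  1
retained components (H)              11
national PMR                      1.594e-04
ensemble models (N)                  55
pooled centroids (L)                385
clusters of interest                374
noise centroids                       9
final clusters                        4
------------------------------------------------------
final cluster   type   centroids   municipalities
            0   high          90              100
            1   high          82               99
            2   low           95              100
            3   low           98              100
------------------------------------------------------
municipality types: high=199  low=200  unclassified=0
```

The four planted strata come back as four final clusters (two high-PMR,
two low-PMR), each base-model cluster recurring ~80–100 times across the
55-model ensemble; the national PMR of ~1.6e-4 is the mean rate over
retained municipalities. `res.municipalities` holds the per-municipality
counts, dominant cluster, type and intensity;
`res.significance_matrix()`, `res.cluster_profiles()`,
`res.pmr_distributions()` and `res.segment_maps(...)` expose the
evaluation layer.

The same run is available from a shell, stage by stage with persisted
CSV intermediates and a reproducibility manifest:

```sh
ptbstrat all --seed 1 --outdir runs/demo
# or: simulate / ingest / prep / mkm / consensus / report
```

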