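# Methods

## Problem and model

`ptbstrat` stratifies area-level preterm-birth (PTB) risk from
socioeconomic (SES) microdata. The unit of analysis is the municipality;
the outcome metric is the **preterm municipal rate**

    PMR = NNP / NP

where `NNP` counts registered births with gestation strictly below 37
weeks among residents of the municipality and `NP` is the municipality's
total population. Population, not birth count, is the denominator: with
tiny birth denominators the preterm fraction of births is wildly unstable
(registries can report most of a small municipality's births as preterm
simply through missing records), while the population-based rate degrades
gracefully.

The stratification never clusters on PMR itself. Municipalities are
clustered on SES features alone; PMR is held out and used only to decide
which discovered clusters are epidemiologically interesting. The procedure
is a two-level consensus clustering:

1. **Preparation.** Municipality SES means (one column per one-hot
   category, averaged over the municipality's person/household records)
   are cleaned of PMR outliers (|PMR − mean| > 3 sample SDs, computed once,
   no iteration), reduced by PCA to the smallest number of components
   retaining 95% of variance, and normalised by a three-step cascade:
   per-column Yeo–Johnson (maximum-likelihood lambda), per-row L2
   normalisation, per-column min-max to [0, 1].
2. **Multiple k-means (MkM).** N independently seeded k-means models run
   on the prepared matrix, the number of centres sweeping 2..30 with ten
   instances each (N = 290). All centroids are pooled (L = Σ Nc_i rows)
   and every municipality's label under every model is recorded.
3. **Clusters of interest (CoI).** Each base cluster is scored by the mean
   PMR of its member municipalities; clusters deviating from the national
   PMR (mean over retained municipalities) by at least 10% relative —
   boundary inclusive — are kept, the rest discarded.
4. **Consensus (DBSCAN).** The Pearson correlation matrix between the
   surviving centroid vectors is reduced by PCA to 99% variance, min-max
   normalised, and clustered with Euclidean DBSCAN (eps = 0.06,
   min_points = 50). Recurring, mutually similar base clusters merge into
   final clusters; unsupported centroids become noise. `min_points` is a
   recurrence-evidence threshold over ensemble centroids and should be
   scaled down proportionally for smaller ensembles (the four-stratum
   benchmark uses 10 with a 55-model ensemble).
5. **Mapping.** Each municipality is assigned the final cluster it lands
   in most often across the ensemble (ties to the lowest label, logged),
   typed high/low by majority between memberships of high- and low-typed
   final clusters, with intensity = high-count − low-count. A final
   cluster is typed high/low by the mean of its member centroids' cluster
   mean PMRs relative to the national rate. Municipalities never assigned
   to any CoI are unclassified.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `outlier_k` | 3 | PMR outlier cut, in sample SDs of the full table |
| `variance_target` | 0.95 | explained-variance share kept by the feature PCA |
| `nc_values`, `reps_per_nc` | 2..30, 10 | ensemble centre counts and instances per count |
| `tol`, `max_iter` | 1e-7, 10 000 | per-model Lloyd convergence control |
| `coi_threshold` | 0.10 | relative PMR deviation flagging a cluster of interest |
| `corr_variance_target` | 0.99 | variance kept when reducing the correlation matrix |
| `eps`, `min_points` | 0.06, 50 | DBSCAN radius and recurrence threshold |
| `alpha` | 0.05 | significance level of the evaluation t-tests |

## Design choices where the design was open

* **Sample (n−1) standard deviation** in the outlier rule; the tests'
  brute-force oracle makes the same choice.
* **National PMR is computed after outlier removal**, so the 10% rule and
  the outlier rule refer to the same retained row set.
* **Age bounds inclusive**: the fertile-age filter keeps women aged
  exactly 14 and exactly 40 (what is removed is *under* 14 and *over* 40).
* **Municipalities with births but zero preterm births keep PMR = 0**
  rather than dropping out of the join: a true-zero rate is informative.
* **Random-point initialisation, single run per model, no k-means++**:
  the ensemble itself supplies the replication, and diversity of
  initialisations is the point. k-means++ is available behind a switch.
* **Per-model seeds are positional** (`SeedSequence(master, spawn_key=i)`),
  so extending the ensemble never perturbs earlier models.
* **The correlation matrix is computed on the CoI-filtered centroid set**;
  a switch allows correlating the full pool first and filtering after.
* **Pearson correlation** between centroid vectors (Spearman behind
  config); DBSCAN neighbour counts include the point itself.
* **The CoI boundary is inclusive with a 1e-12 epsilon** so an exact ±10%
  deviation is not lost to floating-point rounding of the ratio.
* **Welch (unequal-variance) t-tests** for the cluster contrasts —
  cluster sizes are very unequal — with no multiple-testing correction by
  default (a Benjamini–Hochberg switch exists). The significance matrix
  reports the fraction of variables *below* alpha (significantly
  different); alpha is configurable because both 5% and 1% conventions
  are in use for this kind of display.
* **Nonzero high/low ties** in municipality typing (equal high and low
  membership counts) fall back to the dominant cluster's type.
* **PCA sign convention**: the largest-magnitude loading of every
  component is forced positive, for cross-run and cross-backend
  reproducibility. Columns are centred but not scaled (the features are
  commensurable one-hot means in [0, 1]); scaling is a config switch.

## Synthetic data

The real inputs (live-birth registry, social-programme person/household
registries, population estimates) are not redistributable at record
level, so the generator emulates their statistical structure:
municipalities belong to latent strata, each with its own categorical SES
profile (race, education, employment, income bracket; water supply,
sewage, garbage, lighting, rooms band — small stand-in vocabularies,
configurable) and a multiplicative effect on the per-birth preterm
probability applied on the logit scale so noise cannot leave (0, 1).
Births per municipality are `round(population × birth_rate)`; preterm
status is Bernoulli per birth. All features are categorical by
construction so every aggregated municipality feature is a one-hot mean
in [0, 1] — the commensurability the unscaled PCA step expects.

Defaults are fixed once: crude birth rate 0.014 and base per-birth
preterm probability 0.01, so the national PMR lands near 1.4e-4, the
magnitude observed for Brazilian municipalities (under-ascertainment of
preterm status in the registry is folded into the per-birth probability);
populations uniform in 20 000–50 000; 60 persons and 20 households per
municipality. The four-stratum benchmark plants two high-PMR strata
(multipliers 2.0, 1.6) and two low-PMR strata (0.55, 0.35) of 100
municipalities each, with logit noise SD 0.05 and each stratum
concentrating 55% of every categorical feature's mass on a
stratum-specific category.

What the generator does **not** emulate: real Brazilian marginal
distributions, the 5 570-municipality geography, spatial autocorrelation
between neighbouring municipalities, within-municipality correlation
between SES features, household-size heterogeneity, and registry
coverage bias. Passing the recovery benchmark therefore shows the
pipeline can find planted, well-separated SES strata linked to PMR — not
that real administrative data contain such strata.

## Numerical notes and problem sizes

* Scale: the test suite and the acceptance script run the reference
  290-model ensemble on ~400 synthetic municipalities (the package's
  chosen desk scale) and the recovery benchmark with a reduced 2..12 × 5
  ensemble and `min_points` 10; both complete in seconds.
* Degenerate inputs: constant feature matrices are rejected by PCA;
  constant centroid vectors make the correlation undefined and raise an
  error naming the (model, cluster) tag; an ensemble with zero clusters
  of interest, or one whose CoI all end as DBSCAN noise, stops with an
  explicit message rather than an empty result.
* k-means empty clusters are repaired by scikit-learn's standard
  relocation; occurrences are counted and logged.
* Zero rows stay zero through the L2 step; (near-)constant columns map to
  0 through the min-max step.

## Known limitations

* `eps = 0.06` was calibrated on the reference data's correlation
  geometry; very small ensembles can leave all centroids as noise. The
  mapping then reports every municipality as unclassified.
* The final-cluster count is data-dependent; it is reported, never
  asserted.
* The evaluation layer's t-tests are descriptive contrasts, not
  confirmatory inference: municipalities are not independent samples and
  no correction for spatial structure is attempted.
* t-SNE segment maps are visual diagnostics; their SVM boundary accuracy
  is a separability indicator on the training embedding only.
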