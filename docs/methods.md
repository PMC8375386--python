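# Methods

This note records the models, defaults and numerical choices behind
`geotrace`, and what the synthetic validation does and does not establish.

## Data model and grouping

The unit of classification is the *city-year group* (`CITY_YY`): samples
from one city collected in different years are distinct classes. This is a
deliberate modelling choice — multi-year collections are subject to batch
effects, and folding years together would let technical variation
masquerade as biological signal. The cost is more classes and fewer samples
per class; the `year_confusion` statistic (how often a test sample's top
vote is its own city in another year) quantifies how much the split actually
separates years.

Taxa at the order, family and species ranks are treated as independent
features, tagged `o__`/`f__`/`s__`. Species resolved only to genus appear as
`Genus.spp`. Genus itself is omitted because the species names subsume it.

## Preprocessing

* **Depth filter.** Per group, each sample's total count over *order*-rank
  taxa is compared with 0.2 × the group median of that total; strictly lower
  sums are removed. The boundary is decided with a 1e-9 absolute guard so a
  sample exactly at the cutoff is retained regardless of float rounding. A
  group that would drop below 2 samples is kept unfiltered (with a warning).
* **Ubiquity filter.** A taxon is kept when present (count > 0) in strictly
  more than 60% of the retained samples; exactly 60% is excluded. Ubiquity
  is computed *after* depth filtering.
* **Normalization.** `log2((c + 0.5) / (L + 1) × 1e6)` with the library size
  L summed over the taxa of the matrix being normalized. The 0.5/1 offsets
  are the limma-voom convention; both are exposed as arguments. voom's
  precision weights are not computed — only the normalized values feed the
  classifiers. Normalization happens before elastic-net selection
  (numerically safer than selecting on raw counts; the library-size basis
  can be switched to the whole table via the function arguments).

## Elastic-net retention counting

Each one-vs-rest fit minimizes the elastic-net-penalized binomial deviance
(mixing α = 0.4; features standardized before fitting, matching glmnet's
default). λ is searched on a data-driven geometric grid (30 points from
λ_max down to 10⁻³ λ_max) by stratified cross-validation (10 folds by
default, capped at the minority class size; fold assignment seeded) and
chosen at minimum mean deviance. Degenerate fits fall back to the median
grid penalty, logged. Class imbalance is left unweighted by default
(`class_weight="balanced"` available). Retained = nonzero coefficient;
cutoff selection uses ≥, so feature sets are nested across cutoffs. Limiting
cases behave as theory requires: α = 0 (ridge) and λ = 0 (unpenalized)
retain every feature.

## Classification protocol

* **Splits.** Test = round-half-up(0.2 × group size), minimum 1, fixed
  across repetitions; per repetition, validation = round-half-up(0.2 ×
  remainder) (capped so at least 2 training samples remain per group), the
  rest trains. 100 repetitions by default; analyses in the tests and the
  acceptance script use 25 with correspondingly fewer vote levels.
* **Learners.** Random forest: 1,000 trees, √p features per split
  (validation unused). SVM: RBF kernel, γ ∈ {10⁻³…10¹} × C ∈ {10⁻¹…10³} by
  decades chosen on validation accuracy, features standardized on the
  training fold. MLP: standardized inputs, ReLU trunk (64, 32), inverted
  dropout 0.3, one softmax head, Adam (lr 10⁻³, weight decay 10⁻⁴,
  ≤300 epochs, batch 32), early stopping on validation loss with patience
  25 and best-weight restore. The MLP is a compact in-package
  implementation so that dropout and (below) multiple categorical output
  heads are available in one deterministic, seedable learner.
* **Vote metrics.** Top-1: a sample is correct when its true group is in
  the argmax set of its votes (ties count in the truth's favour; a strict
  rule would only change exact-tie samples). Top-2: correct when the truth
  is among classes holding the two highest *distinct* vote values; classes
  with zero votes hold no rank, so a unanimous tally is not trivially
  top-2-correct. Top-2 error ≤ top-1 error by construction. Per-group
  errors restrict the same correctness mask to each group's test samples;
  their sample-weighted mean is the overall error.

## Mystery inference

Per repetition, 20% of the unknown-origin samples are held out and the rest
join the full main training set under the label `mystery`; an MLP (same spec
as above, with a seeded 15% validation carve-out for early stopping) votes
on the held-out samples. Votes therefore accumulate only over the
repetitions in which a sample was held out (≈20% of repetitions each); the
detection rate is the fraction of unseen-city samples whose top-voted class
is `mystery`.

The trait model is one network with a shared trunk and six softmax heads,
per-head cross-entropies summed unweighted; training labels are city-level
(years merged, since climate and geography do not change year to year).
Averaged per-city predicted levels are matched to known city profiles by
rounding each averaged level to the nearest integer and ranking cities by L1
distance — the simplest metric that makes "the pattern of X resembles city
Y" precise, and on binary traits the distance equals the number of
mismatched traits.

## City-trait discretization

Monthly records are remapped to meteorological seasons (Dec–Feb = northern
winter, mirrored for southern-hemisphere cities) and the seasonal mean of
the monthly `*_mean` stat feeds each of the four climate traits. k is chosen
by maximum mean silhouette over k ∈ 2…4 with a parsimony margin of 0.02:
a larger k must beat the incumbent's silhouette by more than the margin,
which prevents splitting a tight small cluster on a hair-thin gain
(an ensemble-of-indices chooser could be substituted via the per-trait
`k_overrides`). k-means runs 10 restarts, seeded, and labels are re-ordered
by ascending cluster mean so a higher label always means a higher value.
Urbanization binarization uses score ≥ median (ties go high).

## Synthetic data

Per sample, taxon proportions are a softmax over
`baseline + city signature + year batch shift + sample noise`:

* baseline log-abundances N(0, 1.5) — wide enough that a realistic fraction
  of taxa fails the ubiquity filter;
* signature: 10 planted taxa per city shifted by `signature_effect`
  (default 1.0 ≈ e-fold 2.7× enrichment);
* batch: per city-year N(0, 0.3) per taxon;
* sample noise: N(0, 0.5) per sample per taxon — within-city compositional
  variation, without which any two cities would be separable from
  multinomial noise alone and penalty selection would degenerate.

Counts are multinomial given the proportions and a log-normal library size
(median 1e5, log-sd 0.6). Outliers are planted purely by depth: 6.5% of
samples have their library multiplied by 0.05, guaranteed below the 20%
depth cutoff (the config rejects factors ≥ 0.2). Default design mirrors the
MetaSUB main dataset (23 cities, 28 groups, 193/288/1394 taxa per rank, 35
samples per group); tests and the acceptance script use `small_config`
studies (4–12 cities, 5–15 samples per group, 200 taxa) to keep runs in
seconds. Planted trait levels cycle over a shuffled city order so levels are
balanced, with at least half of the cities planted urban so the median
binarization provably recovers the plant. Climate series are built so the
hemisphere-correct seasonal means sit `gap` apart per level (gaps 8 °C /
15–20 percentage points versus ≤1-unit noise).

**What the simulations do not emulate:** phylogenetic correlation between
taxa, overdispersion beyond multinomial + log-normal noise (no
Dirichlet-multinomial), compositional differences in outlier samples (the
depth filter is depth-based, so outliers are planted by depth only),
gradual climate similarity between neighbouring cities, and any
relationship between a city's microbiome and its traits other than through
city identity. Passing recovery tests therefore shows the machinery is
correct and calibrated, not that real-city error rates will match.

## Determinism and degenerate inputs

Every stochastic step is seeded; pipeline stages derive sub-seeds from the
single run seed via `SeedSequence`. Repeated runs with one seed are
bit-identical (enforced by tests). Degenerate inputs: empty tables, zero
library sizes, missing city/year, mismatched feature sets, unknown biome
labels and k > distinct values all raise with the offending item named; a
learner failure inside a repetition is retried with a fresh sub-seed and
aborts after five failures.

## Known limitations

* The silhouette-based k chooser is a single index; with very few cities per
  level it can under- or over-split despite the parsimony margin.
* One-vs-rest fits are unweighted, so with many groups the positive class is
  heavily outnumbered; strong penalties can then zero out an entire fit.
* Vote counts are not calibrated probabilities; top-2 inclusion of all tied
  classes slightly favours tallies with many ties.
* The mystery class is a discriminative stand-in for open-set recognition:
  detection depends on the held-in unknown samples resembling the unseen
  test samples.
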