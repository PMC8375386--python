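# geotrace

Microbial geolocation of urban samples: given OTU count tables (order,
family and species ranks) for swabs collected in many cities, `geotrace`
selects city-discriminative taxa, predicts which city — and which collection
year — a sample came from, flags samples that come from no known city, and
predicts categorical city traits (climate, coastality, urbanization) to
narrow candidate origins for those unknowns.

The package targets studies shaped like the MetaSUB/CAMDA 2020 geolocation
challenge (≈1,000 mass-transit samples, 23 cities, some sampled in both 2016
and 2017), but all stages work on any samples × taxa count table with
city/year metadata. A synthetic-data module generates tables with planted
city signatures, batch shifts, depth outliers and matching city covariates,
so every stage can be validated against known ground truth.

## Method

**Preprocessing.** Per city-year group, samples whose total order-rank count
falls below 20% of the group median are removed. Taxa present in more than
60% of the retained samples are kept, and counts are normalized to
log2 counts-per-million with voom offsets:
`log2cpm = log2((c + 0.5) / (L + 1) × 10⁶)`.

**Feature selection.** For each city-year group *g*, a binomial elastic-net
model is fitted for "*g* vs the rest",

```
min_{β0,β}  −(1/N) Σᵢ [ yᵢ(β0 + xᵢᵀβ) − log(1 + e^{β0 + xᵢᵀβ}) ]
            + λ [ (1−α)‖β‖₂²/2 + α‖β‖₁ ]
```

with α = 0.4 and λ chosen by cross-validated deviance. A taxon's *retention
count* is the number of one-vs-rest models giving it a nonzero coefficient;
thresholding the count ("retained by ≥ c models") yields nested feature sets
whose classification error is compared in a cutoff sweep.

**Classification.** 20% of each group is fixed as a test set; the remainder
is re-split 80/20 into train/validation 100 times. Each repetition fits a
learner (random forest with 1,000 trees and √p variables per split; RBF SVM
with a validated γ/C grid; or an MLP with ReLU hidden layers, softmax output
and dropout) and votes on the test samples. A sample is correct when its
true group holds the highest vote (top-1) or one of the two highest distinct
vote ranks (top-2). Samples from one city in different years are distinct
classes, so same-city-different-year confusions are counted separately.

**Mystery detection.** Unknown-origin samples are added to training under an
extra class label `mystery` (20% of them held out per repetition); a test
sample whose top vote is `mystery` is flagged as coming from an unseen city.

**Trait prediction.** Continuous city covariates are discretized: monthly
climate is remapped to hemisphere-aware meteorological seasons, seasonal
means are k-means-clustered into ordered levels, and the three neighboring
Anthromes biomes (wildlands 0 … dense settlements 5) are summed and
binarized at the median into an urbanization score. A shared-trunk
multi-output MLP (one softmax head per trait) predicts the six traits from
microbial profiles; averaged per-city predictions are matched to known
cities by L1 distance after rounding.

## Worked example

```sh
geotrace run-all --out demo --seed 2
```

simulates a six-city study (one city sampled in two years, two unseen
mystery cities), runs the full pipeline and prints the summary. Output from
that exact command:

```
n_samples_before_filter: 84
n_samples_after_filter: 79        # the 5 planted low-depth outliers removed
n_taxa_after_ubiquity: 198
chosen_cutoff: 2
n_selected_features: 198
method: mlp
top1_error: 0.0                   # every test sample's top vote is its true group
top2_error: 0.0
year_confusion_count: 0           # of 4 test samples from the two-year city
trait_errors: {summer_temperature: 0.0, ..., urbanization: 0.0}
mystery_detection_rate: 1.0       # all unseen-city samples top-voted "mystery"
```

With the default strong planted signatures the cities are cleanly separable,
so the vote errors sit at zero; lowering `signature_effect` toward zero
drives the top-1 error to the chance level 1 − 1/G. The same stages are
available individually (`geotrace simulate / preprocess / discretize /
select / classify / mystery`) and as library functions; see
`docs/methods.md` for the model and parameter details.

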