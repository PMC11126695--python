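# Methods

## The problem

When a fecal microbiota transplant (FMT) moves a donor's gut community
into a recipient, some donor taxa establish themselves in the new host
(*colonizers*) and some do not. Even among taxa that do colonize, how
abundant each becomes in the recipient differs from its abundance in
the donor, and it does so differently for different taxa. `rdrkit`
quantifies these *dispersal* differences pairwise, because pairwise
log-ratios are the natural compositionality-safe currency for
relative-abundance data.

## The RDR statistic

For two taxa *a* and *b* that both colonize during one FMT experiment
(a donor / recipient-pre / recipient-post sample triad):

```
RDR(a, b) = log10( (R_a / R_b) / (D_a / D_b) )
```

where *R* are relative abundances in the recipient post-FMT sample and
*D* in the donor sample. Properties that the test suite enforces to
1e-12:

* **antisymmetry** — RDR(a, b) = −RDR(b, a);
* **additivity** — RDR(a, b) + RDR(b, c) = RDR(a, c) within one
  experiment;
* **compositional invariance** — the statistic is a ratio of
  within-sample ratios, so rescaling either sample or re-closing it
  after adding/removing unrelated taxa changes nothing. This is why the
  per-sample normalization constant (sequencing depth, closure) cannot
  confound the analysis;
* **scale law** — doubling R_a adds exactly log10(2).

RDR is only defined for co-colonizers: all four abundances are strictly
positive by construction. Zeros are treated as true biological
absences; no pseudo-counts are ever added, which is precisely the
situation the colonizer definition guarantees.

## Preprocessing and colonization classes

Samples with fewer than 2,000 reads are removed (a sample with exactly
2,000 is kept); counts are closed to relative abundances; taxa are kept
when their abundance exceeds 0.05% in at least 5% of samples
(prevalence counted with a ceiling; the filter is applied per study by
default, and a taxon passing in any study is kept globally); surviving
rows are re-closed. Presence is strictly positive abundance. Each
taxon's (donor, pre, post) presence bits map to one of eight
colonization classes; (1,0,1) is the colonizer class that feeds the RDR.
Recipients sampled at several post-FMT timepoints contribute one
experiment per timepoint, with the subject and donor identities carried
along as grouping factors.

## Per-pair inference

A pair's observations across experiments are modelled as

```
RDR ~ 1 + (1 | subject_id) + (1 | donor_id)
```

an intercept plus crossed random intercepts for recipient and donor,
fitted by REML (statsmodels `MixedLM`; the crossed layout is expressed
as two variance components over a single trivial group). The intercept
estimates the pair's mean RDR; its Wald statistic is referred to a *t*
distribution with containment-style degrees of freedom — one less than
the number of levels of the sparsest retained grouping factor (n − 1
for the t-test fallback). This df choice is deliberately conservative
where replication is thin; under the null synthetic model
(σ_u = 0.1, σ_e = 0.2, 20 observations in 10 subject clusters) the
acceptance suite verifies the empirical size stays within [0.03, 0.07]
at α = 0.05.

A grouping factor whose levels are all singletons is uninformative and
dropped before fitting; if a fit fails numerically the model walks a
fallback chain (drop donor → drop subject → one-sample t-test), each
step logged. Pairs with constant observations short-circuit (p = 1 at
zero, else 0). Pairs are tested only when they co-colonize in at least
2 studies and 10 experiments (both inclusive); all tested pairs form a
single Benjamini–Hochberg family and pairs with q strictly below 0.1
are called *differentially dispersing*. The dominant partner is the
taxon favoured by the sign of the intercept.

Leave-one-study-out (LOSO) consistency refits the intercept without
each study in turn and compares its sign against the pair's within-study
mean RDR. It is reported over the differentially dispersing pairs;
pairs with no true effect have coin-flip within-study signs by
construction, so a consistency guarantee over all pairs would be
meaningless.

## C-scores

On a cross-sectional cohort the standardized checkerboard score

```
c_ij = (r_i − S_ij)(r_j − S_ij) / (r_i + r_j − S_ij)
```

(occupancies r, co-occurrences S) measures pairwise segregation.
Differential pairs are compared against background pairs with an
unpaired two-sided rank-sum test by default — the sets are unpaired and
of unequal size — with a `paired` override available for positionally
matched sets. The C-score/RDR association uses Spearman correlation of
c_ij against |mean RDR| (the display orientation lists the dominant
partner first, making mean RDR positive), average ranks on ties.
Agreement with external dominance calls (e.g. in-vitro co-culture
outcomes) is reported as raw proportion plus Cohen's kappa on the
binary is-the-first-listed-taxon-dominant labels.

## Reverse ecology

Each genus's KO repertoire expands into a directed compound graph: for
every reaction of every present KO, one edge per (substrate, product)
combination; reversible reactions add both directions (default
irreversible); an optional currency-metabolite exclusion list is
honoured (default empty). Seed compounds — what the organism must take
from its environment — are the members of source strongly connected
components of that graph, each with confidence 1/|SCC|. Derived scores:

* **nutritional flexibility** = |seeds| / |compounds|, in (0, 1];
* **competition index**(focal, other) = confidence-weighted fraction of
  the focal taxon's seeds present in the other's seed set, normalized
  by the focal total confidence. It is asymmetric by design: it reads
  as the competition the focal taxon experiences in the other's
  presence, which is why we normalize by the focal seed set rather than
  symmetrizing;
* **pathway scores** count KOs per pathway with multi-pathway KOs
  split fractionally (mass conserved).

Dominant and minor partners of differential pairs are compared by
paired two-sided signed-rank tests (flexibility; competition felt by
dominant vs felt by minor). Pathways are first screened to those with
at least a two-fold difference between the per-group mean scores (a
zero minor mean with a positive dominant mean passes), then tested
per pathway by rank-sum with BH correction at q < 0.1. The screen uses
the ratio of per-group means; per-pair ratios would be undefined
whenever a partner's score is zero, which is common for sparse KO
content.

## Predictability

One random-forest regressor per taxon predicts its post-FMT abundance
from the concatenated donor and recipient-pre profiles (2 × n_taxa
features). Evaluation pools out-of-fold predictions from grouped
10-fold cross-validation — folds are grouped by recipient so a
subject's experiments never straddle train and test (leakage guard) —
and scores them with Spearman's rho plus R² = 1 − SS_res/SS_tot.
The rho p-value uses a cluster-aware t approximation: a recipient's
experiments at different timepoints share their donor and pre-FMT
feature rows, so their out-of-fold predictions coincide, and the
correlation's effective sample size is the number of recipients rather
than of experiments (empirically, the naive n-based null is inflated by
exactly this duplication). P-values are BH-corrected across taxa;
rho > 0.3 and q < 0.05 defines *well-predicted*. Default forest: 500 trees, library defaults
otherwise, fixed seed (tests and the acceptance script use smaller
forests where the property under test does not depend on ensemble
size).

Feature attributions use an exactly additive tree-path decomposition:
walking root to leaf, each split's change in node mean is credited to
the feature split on, so baseline + Σ contributions reconstructs every
forest prediction to floating-point accuracy (asserted in the tests).
This attribution is computed on a refit of the forest on all
experiments. Features are categorized per model as Self (the predicted
taxon), Partner (co-members of differentially dispersing pairs) or
Non-partner, and per-model mean absolute attributions are compared
across categories by rank-sum tests with BH correction, pooled and
split by donor/recipient source.

## The synthetic meta-cohort

The generator emulates the triad structure of an FMT meta-analysis with
planted ground truth; its defaults define the study conditions used
throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_studies × n_subjects × n_timepoints | 4 × 15 × 2 | 120 experiments |
| n_taxa | 40 | genus-level scale |
| delta | evenly spaced in ±0.5 | per-taxon log10 dispersal propensity |
| sigma_u | 0.1 | subject-level SD, shared across timepoints |
| sigma_e | 0.2 | per-observation SD |
| removal_prob | 0.5 | donor taxon absent from recipient-pre |
| donor_sharing | 0.2 | chance a subject uses the study's shared donor |
| base log10 abundance | uniform(−3, −1), SD 0.4 | donor profile scale |

Donor communities are log-normal; recipient-pre communities are
independent draws with per-taxon deletions (never fully emptied — one
resident is kept if all taxa would be deleted); colonizers enter at
donor abundance × 10^(delta + u + ε); retained residents carry over;
all samples are closed. Because closure cancels in the RDR, the
generator's internal unclosed effects equal the closed-table RDRs to
1e-10 (tested), and the expected RDR of a pair is exactly its delta
difference.

What the generator does **not** emulate: phylogenetic correlation among
taxa, sequencing (multinomial count) noise, depth variation, taxon-taxon
interactions, or donor-recipient abundance dependence. Passing the
recovery tests therefore demonstrates correctness of the estimator under
its own model assumptions, not robustness to real-data artefacts such
as undersampled zeros — which the zero-as-absence rule explicitly
assumes away.

Side generators provide planted-segregation presence matrices for the
C-score path, toy and random metabolic universes for reverse ecology,
and partner-driven prediction targets (`planted_prediction_targets`)
for the attribution analysis.

## Numerical and design choices

* Pair orientation is canonical lexicographic; mean RDR is re-signed
  only for display.
* The q < 0.1 and rho > 0.3 / q < 0.05 thresholds are strict
  inequalities.
* Read TSV tables whose sample sums never exceed 1 + 1e-6 are treated
  as relative and re-closed exactly, so finite-precision round-trips
  keep the sums-to-one invariant.
* All stochastic routines take an explicit seed (default 17); CLI
  output uses a fixed float format, making the whole
  simulate → prep → rdr → cscore → revecol → predict pipeline
  byte-reproducible (tested).
* Problem sizes in the test-suite and acceptance script (e.g. 2,000
  null replicates; 60-experiment prediction cohorts; 40–80 tree
  forests) were chosen as the smallest scales at which the Monte-Carlo
  error is comfortably below the asserted margins.

## Known limitations

* Satterthwaite degrees of freedom are not available from the fitting
  backend; the containment df is a documented approximation and can be
  conservative for highly unbalanced grouping.
* Random-forest evaluation is invariant to feature column order only
  statistically, not bitwise: tree construction consumes the random
  stream in feature order.
* BIOM input requires the optional `biom-format` package; TSV is the
  first-class format.
* The C-score module compares raw scores only; no swap-based null
  models are implemented.
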