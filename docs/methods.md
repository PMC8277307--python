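# Methods

This note records the models, conventions and design choices behind
`vaxtopics`, in the order the pipeline applies them.

## Collection hygiene

Keyword pruning keeps a search keyword when the median of its weekly
retrieval counts is strictly positive. The median of an even-length
vector is the mean of the two middle order statistics (so `[0, 0, 1, 5]`
has median 0.5 and survives). Zero-median keywords index dead discourse
and are dropped.

De-duplication is a streaming pass with a persistent seen-ID set: the
first occurrence of each `tweet_id` is kept in first-seen order. A
retweet embeds its original, so the original's ID is checked too — if it
was already registered the retweet is redundant and dropped; otherwise
both IDs are registered and the retweet record kept. This makes the
operation idempotent and means an original arriving *after* one of its
retweets is treated as already collected. The alternative reading (store
the embedded original as its own record) was rejected because the
wrapped text is already carried by the retweet record.

## Features

Tokenization is tweet-aware: `#hashtag` and `@mention` survive as single
tokens, plain words are lowercased (keeping internal apostrophes and
digits, so `sb276` is one token), punctuation separates tokens, and
stop-word *unigrams* are removed. The stop-word list is the standard
English list shipped with scikit-learn plus a configurable augmentation
(`TweetVectorizer(extra_stopwords=...)`); URLs receive no special
handling beyond tokenization. Hashtags and mentions are never treated as
stop words.

The feature space contains one column per unigram, adjacent-pair bigram,
hashtag and mention occurring in the corpus, in lexicographic order, with
raw within-tweet frequencies as values (sparse CSR). Bigrams are formed
*after* stop-word removal.

By default the vocabulary is built once on the full corpus before
cross-validation, accepting the mild information leakage implied by a
preprocess-then-split order; `cross_validate(per_fold_vocabulary=True)`
rebuilds it inside each training fold for a strictly leakage-free
estimate.

## Stance model

One binary L1-penalized logistic model per class (anti / pro / neutral),
each against the rest, fitted with liblinear. The inverse penalty C
defaults to 1 and is deliberately not tuned; the penalty-weight
convention is λ = 1/C. liblinear's formulation penalizes the intercept
along with the weights (via the augmented-feature trick); the test
suite's independent gradient-free oracle minimizes exactly that
objective.

Class imbalance is handled by random minority oversampling of the
*training* portion only: all original examples are retained and extra
indices are drawn with replacement from each minority class until every
class matches the majority count. Prediction takes the argmax of the
per-class sigmoid confidences σ(**w**·x + w₀); exact ties fall to the
fixed class order anti < pro < neutral (ties essentially never occur with
continuous scores; the rule only pins down degenerate cases such as an
all-zero model).

Evaluation is stratified k-fold (default k = 10) with a seeded shuffle,
a freshly trained model per fold, and one pooled confusion matrix in
class order anti / pro / neutral. Reported percentages are rounded to
one decimal; internal values keep full precision. A zero column sum
makes that class's precision undefined (NaN, with a warning) rather than
zero. The binary collapse merges anti+pro rows and columns to score
stance-vs-neutral screening.

## Topic clustering

K-means (Lloyd, `n_init = 10` seeded restarts, best inertia kept) on the
same raw count-feature space used by the classifier, Euclidean distance
throughout; rows are not length-normalized by default
(`kmeans_fit` / `select_k` accept `normalize_rows=True` for L2 row
normalization, but the reference procedure clusters raw counts). k is selected by maximizing the mean
silhouette coefficient over a caller-supplied range, computed on all
points (no subsampling); ties prefer the smallest k. Mean silhouettes on
sparse short-text counts are characteristically tiny (order 0.01), and
coarse partitions often win: the selected k is a property of the
silhouette landscape, not a recovery guarantee.

Handle-only clusters — closed conversation loops whose content is
@-mentions — are detected by ranking a cluster's top 50 *word-kind*
terms (unigrams, hashtags, mentions; bigrams excluded from this ranking,
since the rule is about words) by summed within-cluster frequency, ties
lexicographic, and flagging the cluster when every ranked term is a
mention. Clusters so flagged are excluded from all later analysis.

A cluster is *prominent* when its size reaches
`ceil(fraction × total)` with fraction 0.05 by default. The base total
is configurable; the default is the stance group's tweet count net of
handle-excluded clusters, which is the only base that reconciles the
reference thresholds (472 ≈ 0.05 × 9,440 for a group of 11,103 tweets
with three handle clusters removed). Remaining non-prominent clusters
form the "rest" set; prominent ∪ rest ∪ excluded always partitions the
clusters.

## Topic geometry

* **Radius** (intratopic consistency): mean Euclidean distance from a
  cluster's members to its centroid. Larger radius = less consistent
  topic.
* **Distinctiveness** (intertopic separation): centroid distance divided
  by the sum of the two radii. The exact published formula is not
  available in legible form; this normalization is an inference, forced
  by the documented decision rule that a score below 1 means substantial
  overlap and 1 or more means distinct clusters, and by the description
  that the measure involves the points and centers of both clusters. It
  should be read as this package's operationalization, not a
  transcription. Degenerate conventions: coincident centroids score 0;
  two distinct point masses (both radii 0) score +inf; scores are
  symmetric, translation-invariant, and scale-invariant (radii scale
  linearly).

Group comparison collects one score per (prominent, rest) ordered pair
and runs a two-sample t-test between the stance groups: pooled variance
(df = n₁ + n₂ − 2) two-tailed by default, with Welch
(Welch–Satterthwaite df) and one-tailed modes available; the one-tailed
p tests mean(a) > mean(b). Pair scores sharing a cluster are correlated,
so inference on all pairwise scores of one clustering is
anti-conservative — the recovery suite therefore uses disjoint topic
pairs (see below). Radii are compared the same way over retained
clusters.

The visualization places prominent clusters on a small inner ring and
the rest on an outer ring at range proportional to their mean
distinctiveness from the prominent set, drawing each cluster as a circle
with radius proportional to its intratopic radius (zero-radius clusters
get a minimum visible marker annotated `r=0`) and labelling each
prominent-rest edge with its score. Layout is deterministic per seed and
the SVG output is byte-reproducible (volatile timestamp metadata is
stripped; the SVG hash salt is fixed from the seed).

## Reliability

Unweighted two-coder Cohen kappa from a square contingency table:
p_o = trace/n, p_e = Σ row-margin × column-margin / n², κ =
(p_o − p_e)/(1 − p_e), with κ defined as 1 when both coders agree
perfectly on a single category (p_e = 1). The coding-record structures
support the two phases (topic, then frame) and the four message-framing
categories (problem definition, causal interpretation, moral evaluation,
remedy recommendation); the agreement table works for any category count,
so the 2-category and 3-category readings of a validation set are both
supported. Frame assignment itself is human work; no automation is
attempted.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes,
not real language:

* Each stance has `n_topics_per_stance` planted topics with disjoint
  vocabularies (`vocab_size_per_topic`, a `hashtag_fraction` of which
  are rendered as `#` tokens) plus one shared pool
  (`shared_vocab_size`).
* A tweet from topic t draws ~Poisson(`tokens_per_tweet`) tokens (floor
  3) from a two-component mixture: topic vocabulary with weight
  w = separation/(1 + separation), shared pool otherwise. separation = 0
  therefore makes all topics statistically indistinguishable, and the
  planted intertopic distinctiveness grows monotonically with it.
* `dispersion` jitters the per-tweet weight with a Beta draw of mean w
  and concentration 1/dispersion, creating within-topic variability;
  dispersion = 0 gives every tweet of a topic the same distribution.
* `mention_rate` injects random `@user` tokens; `topic_weights`
  (largest-remainder allocation, deterministic) controls topic sizes,
  since no per-topic size distribution is prescribed beyond the
  prominent ones; `separation_per_stance` lets the stance groups differ
  in planted separation.
* Duplicates re-emit an existing tweet verbatim under a second keyword
  channel (same `tweet_id`, different `source_keyword`), mirroring
  multi-keyword retrieval. Retweets wrap an existing original under a
  new ID with `original_tweet_id` set. Handle clusters are closed loops
  of four accounts whose tweets consist entirely of mention tokens — the
  all-mention top-terms signature the handle filter keys on.
* Default class counts are the annotated-set conditions (1639 pro, 1550
  anti, 2422 neutral); identical spec + seed reproduces the corpus
  byte-for-byte.

What it does **not** emulate: real English syntax or vaccine-debate
vocabulary, Zipfian token frequencies, author-level effects, URLs,
emoji, spelling variation, or temporal drift. Passing tests therefore
demonstrate that the algorithms recover planted statistical structure
under the stated noise model — not that any particular accuracy carries
over to real platform data, where tokenizer and stop-list details alone
shift metrics by small amounts.

The planted geometry generator places pairwise-equidistant centroids at
regular-simplex vertices (requires dim ≥ n_clusters) with isotropic
Gaussian spread, for testing the geometry statistics against ground
truth without the text layer.

## Recovery-suite design and problem sizes

The test and acceptance suites use sizes chosen to make each property
sharp at modest cost:

* CV recovery: 3 × 150 tweets, separation 6, dispersion 0.05 — accuracy
  ≥ 99% when separable, ≈ 1/3 under permuted labels. The penalty-sweep
  stability check uses 3 × 400 tweets, since at very small corpora a
  strong L1 penalty (λ = 10) legitimately collapses the model.
* k-selection recovery: 2–6 planted blobs, centroid distance 10,
  dispersion 1, 40 points per blob in 8 dimensions, candidate range
  2–8.
* Separation-difference detection: corpora of 10 topics × 20 tweets per
  stance, distinctiveness computed on the *true* topic assignments over
  the five disjoint topic pairs per group. Disjoint pairs come from
  disjoint tweet sets and are therefore independent, keeping the
  two-sample t-test at its nominal level (~5% false positives under
  equal separation); all-pairs scores from one clustering are correlated
  and were measured to reject far above nominal level, so they are
  reported descriptively but not used for the calibrated recovery
  check. The planted difference (separation 1.5 vs 3.0) is sized for a
  well-powered design: an effect of the magnitude the reference analysis
  reports (difference ≈ 0.03 with SDs ≈ 0.08 at ~60 pairs per group)
  has only ~50% power at α = 0.05, so demanding ≥ 90% detection at that
  effect size would be incoherent; the summary-statistic t oracle in the
  test suite covers that regime instead.

## Known limitations

* The distinctiveness normalization is an inference (above); absolute
  score levels are comparable within this package only.
* Silhouette-selected k on sparse counts is conservative; planted topic
  counts are recovered reliably only for well-separated low-dimensional
  geometries, which is the regime the k-recovery suite tests.
* The t-test on prominent-vs-rest scores inherits the dependence caveat
  above; p-values from `distinctiveness_comparison` in pipeline reports
  should be read descriptively.
* liblinear penalizes the intercept; with C = 1 and corpus-scale data
  the effect is negligible, but at tiny n it differs from an
  unpenalized-intercept formulation.
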