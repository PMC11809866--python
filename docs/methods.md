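# Methods

This note records the modelling choices behind `saferec`, the defaults and
why they were chosen, and what the synthetic study scenario does and does
not establish.

## Candidate pools

The pool of a target *u* is built by neighbourhood expansion on the
directed follow graph. Levels count from the target: level 1 = *u*'s
followees, level 2 = their followees, candidates = followees of level-2
accounts (`depth = 3` by default; `depth` is a knob because deeper
expansions are defensible and the sizes reported for real crawls do not
pin the hop count down). The harmlessness filter applies at level 1 only:
it decides which of *u*'s own followees seed the expansion, which is where
a platform can intervene most cheaply.

The pool is a **multiset**: a candidate's multiplicity is the number of
distinct level-2 accounts following it, and `|C_u|` is the sum of the
retained multiplicities. Sampling draws `pool_size` (default 100)
*distinct* candidates uniformly without replacement, then keeps each
sampled candidate's pre-sampling multiplicity. If instead the multiset
itself were sampled and deduplicated, every occurrences ratio would
degenerate to `1/|C_u|` and the topology score would lose its
frequency component. Candidate ids are sorted before the seeded draw so
pools are identical across platforms and runs.

Eligibility: the target and *all* of its direct followees are excluded
(recommending an account the user already follows is vacuous); level-2
accounts remain eligible when they arrive as followees of other level-2
accounts. Pool composition statements in this package are
multiplicity-weighted for the same reason `|C_u|` is.

The filtering threshold defaults to 0.5 (the classifier's natural decision
boundary); it is a config knob because a deployment may trade recall of
harmless seeds against purity.

## Interest vectors and content score

Interests are bag-of-topics counts over a fixed `TopicVocabulary`
(keyword → topics map, supplied as YAML; a demo vocabulary ships with the
package). Three sources contribute, each capped at 200 texts: the
account's own posts, its liked posts, and the biographies of its followees
(carried on the account record by `attach_followee_bios`). Source weights
default to (1, 1, 1); nothing in the problem favours one source a priori.

Normalisation is min-max. For platform accounts it is **global** — min and
max taken jointly over all (owner, topic) raw entries of the cohort, which
preserves between-user intensity differences; a per-topic variant is
exposed because the joint convention is a genuine coin-flip. For survey
participants it is **per-owner** (each participant's own min/max), because
survey scores have no cross-participant intensity meaning. A degenerate
range maps to zeros. Content score is the cosine of the normalised
vectors, with all-zero vectors scoring 0 by convention.

Survey profiles: each subcategory's 0–5 score propagates to the
subcategory's topics and, through a keyword → related-concepts map, to the
concepts related to every free keyword the participant supplied.
Collisions keep the **maximum** propagated score rather than summing, so
one enthusiastic keyword cannot be double-counted through overlapping
concept sets. Unresolvable keywords are logged and skipped.

Tokenisation everywhere: lowercase, punctuation stripped, whitespace
split. Term ranking (for topic-frequency reports) counts unigrams and
bigrams, descending frequency, ties lexicographic.

## Screening classifiers

Both screening tasks (contemplation-stage detection; harmful vs harmless)
use the same machinery on user-level documents — one document per account,
the concatenation of its texts.

- **TF-IDF bag of words**: word 1–3-grams, raw term counts, smoothed idf
  `ln((1+N)/(1+df)) + 1`, L2-normalised rows. The token pattern admits
  single-character tokens so short n-grams are not silently dropped.
- **Lexicon model**: one feature per curated term list, valued as term
  occurrences per token. The shipped demo set has 84 lexicons in five
  groups (24 linguistic, 29 affective, 12 personal-concern/biological, 10
  suicide-risk, 9 eating-disorder); the lists are synthetic stand-ins and
  configuration-driven, since clinically curated lists are not
  redistributable.

Class imbalance is handled with SMOTE (implemented here: each synthetic
point is `x + λ(x_nn − x)`, `λ ~ U(0,1)`, `x_nn` among the 5 nearest
minority neighbours, seeded). Oversampling runs **inside** training folds
and on the training split only — the methodologically safe reading; the
held-out 30% stratified test split is never oversampled or seen during
fitting, so reported precision/recall/F1/accuracy are uncontaminated.
Classifiers: logistic regression (default), random forest, SVM (with
probability calibration), all seeded. The harmlessness score of an account
is the harmless-class probability of the fitted model; the contemplation
cohort is selected at probability > 0.95, descending, ties by id.

## Ranking and quota

`rank = h · avg(content, topology)` for general candidates; `h · content`
for pro-recovery candidates, whose topology signal is structurally absent
(they rarely appear in the pool). The quota (default 20% of K, round
half-up) is filled by the top pro-recovery candidates and the remaining
slots by the top general candidates; the final list is merged by
descending rank score, ties by ascending id, so quota slots earn their
position rather than being pinned to fixed display ranks. Whether quota
candidates keep the harmlessness factor is exposed as a flag
(`use_harmlessness` on `rank_score`); the default keeps it, since a
pre-labelled pro-recovery account with a low harmlessness probability is a
labelling anomaly worth penalising. With quota 0 and `h ≡ 1` the system
reduces exactly to a plain content + topology recommender, which is the
`no_filter` baseline in the pipeline.

Scores are never rounded inside computation; reporting rounds half-up to
2 decimals.

## Evaluation metrics

Average precision divides the sum of precisions at followed positions by
the number of follows **within the top K** (the denominator convention is
isolated in one function so it can be swapped; with full-window K it
coincides with the usual definition). Recall divides follows in the top K
by follows in the whole annotated window, 0 when nothing was followed.
All 0/0 ratio cells (followed-over-suggested of an unsuggested type,
APHR at AP = HLFRK = 0) are defined as 0. Cohort aggregation means each
metric over targets and recomputes APHR from MAP and the mean HLFRK
rather than averaging per-target APHRs, matching how the composite is
defined at cohort level.

## Synthetic scenario

The generator emulates the structural facts the method relies on, not the
language of real accounts:

- **Groups and homophily.** Four groups — 6 contemplation targets, 60
  harmful, 50 neutral, 15 pro-recovery — with independent Bernoulli
  follow edges at group-pair probabilities. Intra-group probabilities
  (0.20 harmful→harmful, 0.15 neutral→neutral, 0.20 within pro-recovery)
  dominate cross-group ones, and targets follow harmful accounts at 0.30
  versus 0.08/0.02 for neutral/pro-recovery — the homophily trap. Under
  these defaults a target's unfiltered pool is ~60% harmful by
  multiplicity while the filtered pool is ~30% harmful, the qualitative
  regime in which filtering matters. Contemplation accounts carry the
  harmful label for screening purposes: peers likely to share pro-ED
  content must not be recommended.
- **Texts.** Unigram sampling, no grammar — sufficient for the n-gram and
  lexicon featurisers under test. Each token comes from the account's
  group vocabulary (40 words per group) with probability δ, else from a
  shared topic-keyword channel driven by the account's own Dirichlet
  topic profile. δ = 0 makes groups textually identical in distribution;
  δ = 1 makes their vocabularies disjoint; the shipped default δ = 0.8
  yields a hard-but-learnable screening problem. 20 posts + 5 likes + a
  bio of 15 tokens each per account.
- **Follow decisions.** Bernoulli with
  `logit = β0 + β_content · content + β_harm · 1[harmful]`, defaults
  (−1.0, 2.0, 1.0): follows increase with shared interests, and this
  population is *more* likely to follow harmful accounts — the bias the
  recommender must work against.

What passing tests on this scenario do **not** show: performance on real
language (no syntax, sarcasm, code-switching, or topic drift), robustness
to adversarial vocabulary overlap between harmful and pro-recovery
communities, degree heterogeneity (edges are not degree-corrected), or
calibration of the screeners on real class priors. The scenario
establishes that the pipeline's machinery — filtering, multiplicity
bookkeeping, harmlessness weighting, quota injection, metric suite — does
what it claims under planted ground truth.

## Problem sizes and numerical choices

The shipped scenario (131 accounts, ~1,500 edges) makes a full pipeline
run take a few seconds, so the multi-seed planted-structure checks in the
test suite (10 seeds) complete in well under a minute; the scale was
chosen to be the smallest at which the pools, quotas and metric
denominators are non-trivial. Determinism is end-to-end: every stochastic
step (graph, corpus, pool sampling, SMOTE, classifier seeds, follow
decisions) derives from explicit integer seeds, and identical
configurations produce byte-identical artifacts. Degenerate inputs are
defined rather than erroneous wherever a convention exists (empty pools,
all-zero vectors, empty documents, 0/0 ratios); contract violations
(scores outside [0,1], mismatched vector lengths, single-class corpora)
raise.
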