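# Methods

This note documents the models, conventions and numerical choices behind
`distcat`, and what the synthetic study does and does not establish.

## Corpus representation and pre-processing

Input corpora are PoS-tagged utterance sequences of adult (child-directed)
speech, consumed in a plain tagged-text format (`word/tag` per token, one
utterance per line, or a vertical token-per-line dialect). Utterance order
is treated as chronological. Wordforms are lower-cased; no lemmatization is
performed.

Fine tags map deterministically onto five coarse categories: **N** (nouns,
including pronouns), **V** (verbs, including auxiliaries, copulas, modals
and non-finite forms), **ADJ**, **ADV**, and **FUNCT**, the residual bucket
into which all remaining categories collapse. The shipped table covers the
common CHILDES-style (MOR) tag inventory; the exact membership of every
minor category in the residual bucket is a convention of this package, and
the table can be overridden (`tag_mapping` config, `strict_tags` to make
unknown tags an error instead of FUNCT).

Homographs are kept distinct by fine tag: a wordform carrying *m* distinct
fine tags within a corpus yields word keys `form-1 … form-m`, numbered by
first occurrence. Identity is the pair (wordform, fine tag), both for the
rows of the co-occurrence matrix and for the elements of context keys, so
counts for the verb *lead* and the noun *lead* never merge. Sense indices
are assigned per corpus independently; cross-corpus identity always goes
through (wordform, fine tag).

## Contexts and longitudinal counting

For each token, up to five lexically specific contexts are extracted: L1
(`w₋₁_X`), R1 (`X_w₊₁`), L2 (`w₋₂_w₋₁_X`), R2 (`X_w₊₁_w₊₂`) and the frame
(`w₋₁_X_w₊₁`). Exactly one boundary symbol (`#start`, `#end`) exists on each
side of an utterance and may fill the slot immediately outside it; a
template that would need a slot *beyond* a boundary is skipped rather than
padded with a second dummy. Consequently a token always has the three
contexts L1, R1 and FRAME, gains L2 from position 1 onward and R2 up to the
penultimate position.

Counting is longitudinal: the word × context matrix is accumulated over
growing utterance prefixes covering 40%–100% of the corpus in steps of 10%
(seven time slices, indexed 0–6). Prefix size is `max(1, floor(fraction ×
N))` — the floor-with-clamp rule is our deterministic reading of
"the first 40% of utterances", safe for tiny corpora. No frequency floor is
applied: all words and all contexts enter the matrix. Row and column order
is first-occurrence order, making runs bit-reproducible.

## Categorization

Leave-one-out 1-nearest-neighbor: at each slice, every word row is compared
with every other row and the closest row's coarse tag is the prediction;
gold tags are consulted only for scoring (hit ⇔ the neighbor shares the
target's coarse tag), so the learner is fully unsupervised and permuting
the tag assignment changes hits but never neighbors.

Two metrics are implemented:

* **cosine**: `1 − A·B/(‖A‖‖B‖)`; invariant under positive rescaling of a
  vector (insensitive to absolute frequency).
* **numeric overlap**: `Σᵢ |Aᵢ − Bᵢ|/(max(i) − min(i))` with per-column
  ranges taken over all rows of the current slice's matrix. A column whose
  range is zero contributes 0 (all rows agree there, so the difference is
  necessarily zero too). The per-column scaled term is the normative
  quantity: for the illustration rows [1,0,9], [0,10,90], [50,30,2] the
  three terms are 0.02, 0.33… and |9−90|/(90−2) = 0.92, whose sum is
  ≈ 1.27 — not the 1.24 sometimes quoted for this example, a discrepancy
  of the printed total that no range convention we could construct
  reproduces. By construction numeric overlap is *not* scale invariant.

Ties: two distances count as equal when `|d₁ − d₂| ≤ tol · max(d₁, d₂, ε)`
with relative tolerance `tol = 1e−9` — exact float equality would make the
cascade ill-defined. Among tied nearest neighbors the most frequent ones
are retained (token frequency in the current prefix — the only frequency a
learner would have at that point), and if several remain one is drawn
uniformly at random. A single process-level seeded generator is consumed
in row order, so runs are reproducible. The categorizer is validated
against a naive all-pairs brute-force scan implementing the same cascade.

## Predictors

Per word, corpus and slice:

* **log frequency** — natural log of the token count in the prefix.
  Natural logs throughout; the base only rescales regression coefficients.
* **log contextual diversity** — natural log of the number of distinct
  contexts. Diversity is bounded by 5 × frequency (each token contributes
  at most five contexts), and both frequency and diversity are
  non-decreasing in time.
* **average conditional probability** — mean over the word's contexts of
  `count(word, context) / freq(context)`; the operationalization of
  predictability, in (0, 1], equal to 1 exactly when every co-occurring
  context occurs with nothing else. The averaging is direction-agnostic;
  the pipeline applies it word-given-contexts.
* **median information gain** — per context,
  `IG(c) = H(Y) − [P(c)·H(Y|c) + P(¬c)·H(Y|¬c)]`
  with natural-log entropies, where the binary feature is co-occurrence
  with `c` and Y is the coarse tag distribution. The default weights word
  types by their token frequency (token weighting), matching the count
  data the pipeline owns; a type-weighted variant is available
  (`ig_weighting="type"`). Which weighting the construct "ought" to use is
  underdetermined; the default is a documented choice, and IG always lies
  in [0, H(Y)] ≤ ln 5. A word's contexts are summarized by their median
  IG (midpoint convention for even counts), which is robust to the heavily
  skewed IG distributions that singleton contexts produce.

## Statistical analysis

The analysis table keeps one row per (word, corpus, slice) surviving three
filters: the word occurs in **all** sub-corpora of the run; it already
occurs within the first 50% prefix of each corpus (time index ≤ 1), so
that most slices contribute a measurement; and individual observations
with frequency 1 are discarded (a hapax has a perfectly determined
diversity, which would hard-wire collinearity). A fourth, optional filter
removes FUNCT words for the content-word replication.

Hits are modelled with logistic mixed-effects regression:
`hit ~ time + predictors + (1 | corpus) + (1 + time | word)`.
The by-word time slope absorbs the autocorrelation between outcomes for
the same word at successive slices. Time enters as a numeric 0–6 term;
predictors enter unstandardized on their stated scales. The random
structure is fixed rather than re-searched. Estimation is delegated to R's
`lme4::glmer` through an Rscript subprocess (binomial family; the fast
`nAGQ = 0` approximation by default, Laplace `nAGQ = 1` on request);
convergence messages and singular fits are propagated into the result and
a degenerate (constant) response is reported as non-convergence rather
than raised. Where no R toolchain exists, a fixed-effects logistic
approximation with corpus and word indicator terms is fitted instead and
flagged as `fixed_fallback`.

Model selection is AIC-based: single-predictor fits over the time-only
baseline (ranked by AIC), then forward selection adding the best candidate
per step until no candidate reduces the AIC or the augmented fit stops
converging. Failed candidate fits are recorded and skipped.

Variance explained is summarized with marginal and conditional r²:
`mr² = σ²_f / (σ²_f + σ²_r + π²/3)` and
`cr² = (σ²_f + σ²_r) / (σ²_f + σ²_r + π²/3)`,
where σ²_f is the population variance of the fixed-effect linear predictor
and σ²_r averages `zᵢᵀ Σ zᵢ` over observations for each random term
(intercept-and-slope covariance Σ from the fit), with the logit
distribution-specific variance π²/3.

The error analysis cross-tabulates correct against predicted coarse tags,
computes expected counts under independence (row × column / total) and
standardized Pearson residuals `(O − E)/√(E(1 − r/N)(1 − c/N))`, flagging
cells at |residual| > 1.96 without multiplicity correction — the
conventional mosaic-plot shading criterion. A minimal mosaic rendering is
available; counts are never modified by the residual computation.

## The synthetic study

The generator emulates the structure of longitudinal child-directed-speech
corpora rather than English itself. Utterances are short concatenations of
chunks (Poisson-distributed chunk count targeting a mean utterance length
of ~5 tokens, matching the short sentences of speech to children). Each
chunk realizes a context template of one coarse class: an optional left
and/or right function-word marker around one open slot. Markers are
optional because in real utterances content words are frequently adjacent;
without that, every context would be a frequent closed-class combination
and predictability would simply track frequency. The slot is filled from
the template's preferred class with probability `selectivity` (default
0.75), else uniformly from another class — the knob controlling how
category-informative contexts are, and hence categorization accuracy.

Word frequencies are Zipfian within each class (exponent 1.0). Two
word-level mechanisms create genuine, frequency-decorrelated variation in
diversity and predictability:

* **stereotypy** — each word has a Dirichlet preference over its class's
  templates with a word-specific concentration (log-uniform in
  [0.15, 5]), so at matched frequency some words spread over many
  contexts and others keep recurring in a few;
* **fixed-phrase collocation** — each word owns a dedicated partner word
  and a probability (uniform in [0, 0.8]) of being produced immediately
  after it. Because the partner rarely occurs without its word, such
  occurrences drive the word's conditional probability given its contexts
  toward 1 while denying it the shared class-template evidence that 1-NN
  categorization feeds on. This is the generator's implementation of the
  predictability mechanism: highly predictable words are locked into
  private contexts and are therefore hard to categorize.

A core vocabulary (70% of each class) is shared across all sub-corpora and
occupies the frequent Zipf ranks; the remainder is idiosyncratic per
corpus (so only core words and partners can survive the all-corpora
filter). A configurable fraction of wordforms is shared between two
classes under distinct fine tags (homographs, default rate 0.06, e.g. a
noun/verb pair). Everything is deterministic given
(`rng_seed`, corpus index), and a ground-truth (wordform, fine tag) →
class map is emitted alongside.

The **reference study** (`reference_study.yaml`) uses 13 sub-corpora of
3,000 utterances each — thirteen longitudinal corpora of a size that keeps
a full multi-seed analysis on one CPU in minutes while leaving several
hundred words in the filtered analysis table. Under cosine, the full-model
fit recovers a positive diversity coefficient and a negative
conditional-probability coefficient across seeds, reproducing the sign
pattern of the real-corpus analyses.

What passing on synthetic data does **not** show: the generator has no
syntax, morphology, discourse structure or semantic coherence, its class
inventory and context templates are far cleaner than real speech, and its
coefficient magnitudes are not comparable to those estimated on real
corpora. It establishes that the pipeline's machinery is correct and that
the qualitative diversity/predictability effects emerge from the stated
mechanisms — not that the real-data coefficient values are reproduced.

## Numerical and engineering choices

* Sparse matrices with stable first-occurrence orderings throughout;
  per-corpus context extraction runs once and each slice is a prefix
  filter over flat event arrays.
* Cosine distances are computed from row-normalized sparse products and
  clipped to [0, 2]; numeric overlap scales columns by reciprocal range
  and uses Manhattan distances.
* Distance-tie tolerance 1e−9 (relative); tie randomness comes from one
  seeded generator consumed in row order.
* Nakagawa r² is computed in Python from the lme4 variance components and
  the model frame, so the same code path serves both engines.
* GLMM fits run with derivative checks disabled for speed; convergence
  and singularity diagnostics are carried through instead of re-derived.
* All pipeline artifacts (outcome/predictor CSVs, matrix exports, model
  JSON) are listed in a manifest keyed by a hash of the full run
  configuration.

## Known limitations

* The residual FUNCT bucket of the default tag table is a convention;
  analyses sensitive to the composition of the function-word class should
  supply their own mapping.
* The fixed-effects fallback approximates, but does not equal, the
  mixed-model estimates; its r² analogue treats the indicator-term
  variance as the "random" component.
* Numeric overlap degrades on high-diversity (noisy) vectors by design of
  the metric; this mirrors its behavior on real data and is not corrected.
* The generator's conditional-probability variation is driven by a single
  mechanism (fixed phrases); real corpora mix many sources of
  predictability that are not modelled.
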