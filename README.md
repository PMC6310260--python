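# distcat

**Distributional bootstrapping of lexical categories**: what properties of a
word's co-occurrence pattern make it easy to group with other words of its
syntactic class?

Children plausibly learn that words behave categorically (nouns pattern with
nouns, verbs with verbs) by tracking which local contexts words share in the
speech they hear. `distcat` implements a complete, reproducible analysis of
this hypothesis for researchers in computational psycholinguistics and
language acquisition:

1. **Longitudinal co-occurrence modelling.** Each tagged corpus of
   child-directed speech is traversed chronologically; for every token, five
   lexically specific contexts are collected — the bigrams `w₋₁_X` and
   `X_w₊₁` and the trigrams `w₋₂_w₋₁_X`, `X_w₊₁_w₊₂` and `w₋₁_X_w₊₁`, with
   `#start`/`#end` boundary symbols — and accumulated into a sparse
   word × context count matrix at seven growing prefixes of the corpus
   (the first 40%, 50%, …, 100% of utterances).
2. **Unsupervised categorization.** At every time slice each word is
   categorized by its single nearest neighbor (leave-one-out 1-NN) under
   either cosine distance,
   `d(A,B) = 1 − (A·B)/(‖A‖‖B‖)`,
   or numeric overlap,
   `d(A,B) = Σᵢ |Aᵢ − Bᵢ| / (max(i) − min(i))`,
   with distance ties resolved by keeping the most frequent tied neighbors
   and then sampling uniformly. Gold part-of-speech tags (mapped to the five
   coarse classes N, V, ADJ, ADV, FUNCT) are used only to score the outcome
   as a *hit* or *miss* — never during learning.
3. **Distributional predictors.** Per word and slice: log frequency, log
   contextual diversity (distinct contexts), average conditional probability
   of the word given its contexts (predictability), and the median
   information gain of its contexts (context usefulness).
4. **Statistics.** The hit/miss outcome is modelled with logistic
   mixed-effects regression (by-corpus random intercepts, by-word random
   intercepts and time slopes) via R's `lme4` behind a Python interface,
   with AIC-based forward selection, Nakagawa marginal/conditional r²
   (logit distribution-specific variance π²/3), and a correct-vs-predicted
   contingency error analysis with standardized Pearson residuals.

Because the original transcribed corpora cannot be redistributed, the package
ships a **synthetic corpus generator** that emulates their structure —
multiple longitudinal sub-corpora of short utterances, Zipfian frequencies,
category-selective local contexts with tunable selectivity, fixed-phrase
collocations, homographs — with full ground truth, so the entire analysis
runs end to end with no downloads.

## Worked example

```python
import distcat as dc
from distcat.synthetic_data import SyntheticSpec

spec = SyntheticSpec(n_corpora=5, n_utterances_per_corpus=1000, rng_seed=42)
corpora, truth = dc.generate_study(spec)
outcomes, predictors = dc.study_tables(corpora, truth, metrics=("cosine",), seed=42)

print(outcomes.groupby("time_index")["hit"].mean().round(3))

table = dc.assemble_table(outcomes, predictors)
result = dc.fit_logistic_mixed(table, ["time", "log_diversity", "avg_cond_prob"])
print(result.coef_frame().round(4))
```

prints (exactly, given the seed):

```
hit rate by time slice:
time_index
0    0.547
1    0.585
...
6    0.657

analysis table: 6077 observations, 190 words

converged: True   AIC: 5893.2
marginal r2: 0.0635   conditional r2: 0.5736
         term    beta     se       z
  (Intercept) -0.1634 0.3806 -0.4293
         time  0.0181 0.0225  0.8041
log_diversity  0.6568 0.0901  7.2873
avg_cond_prob -2.2061 0.3803 -5.8009
```

Categorization accuracy rises as more input is processed. Contextual
diversity has a significantly **positive** effect (words seen in many
different contexts are easier to categorize) while the average conditional
probability has a significantly **negative** effect (words that are easy to
predict from their contexts are *harder* to categorize): categorization
thrives on uncertainty in the co-occurrence pattern.

## Command line

```bash
distcat generate --seed 1 --out corpora/          # emit a synthetic study
distcat run --config run.yaml                     # full pipeline from YAML
distcat analyze --metric cosine --exclude-funct --seed 1 --out results/
distcat report --run-dir results/
```

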