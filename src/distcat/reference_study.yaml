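# Reference synthetic study: 13 longitudinal sub-corpora of short tagged
# utterances emulating transcribed child-directed speech.
n_corpora: 13
n_utterances_per_corpus: 3000
vocab_sizes:
  N: 120
  V: 80
  ADJ: 36
  ADV: 28
  FUNCT: 36
core_fraction: 0.70
zipf_exponent:
  N: 1.0
  V: 1.0
  ADJ: 1.0
  ADV: 1.0
  FUNCT: 1.0
n_context_templates:
  N: 8
  V: 8
  ADJ: 5
  ADV: 5
  FUNCT: 5
selectivity: 0.75
homograph_rate: 0.06
mean_utterance_length: 5.0
stereotypy_range: [0.15, 5.0]
rng_seed: 0
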