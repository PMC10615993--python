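# dsitext

Divergent semantic integration (DSI) scoring for narrative text: the score of
a story is the **mean pairwise cosine distance** between the word embeddings
of its tokens, so higher values mean the text connects ideas from more
divergent semantic contexts. The package also ships:

- deterministic story preprocessing (rule-based sentence splitting, a bundled
  174-word English stop list, separate static/contextual tokenization routes);
- three embedding backends — static word-vector files (word2vec-text and
  GloVe-text dialects), a contextual 24-layer transformer adapter (optional
  `bert` extra; layers 6+7 pooled by default), and a fully offline seeded
  synthetic backend with controllable topic-cluster structure;
- the lexical covariate battery (word count, Flesch–Kincaid readability,
  frequency/prevalence/age-of-acquisition norm means, MTLD lexical diversity);
- a text-length bias audit by random without-replacement subsectioning;
- psychometric validation statistics (Fisher-z correlation CIs, dependent and
  independent correlation-difference tests, single-rater-average agreement,
  McDonald's omega from a one-factor ML model, two-way random-effects ICCs,
  hierarchical incremental-validity regression with bootstrap ΔR² CI,
  Welch t / Cohen's d group comparisons);
- synthetic fixture generators (cluster-structured corpora and simulated
  raters) with known ground truth.

## CLI

The console script `dsitext` has four subcommands. Inputs are delimited
tables (UTF-8, header row, `--delimiter` override) with configurable id/text
column names; every output gets a `.meta.json` sidecar recording the config,
seed and library versions.

```sh
# score stories (synthetic backend shown; use --backend static --vectors vec.txt
# for word-vector files, or --backend contextual with the bert extra installed)
dsitext score --input stories.csv --backend synthetic --seed 1 --output scores.csv

# lexical covariates (norm table optional)
dsitext covariates --input stories.csv --norms norms.csv --output covariates.csv

# validate scores against a ratings table (id + one column per rater);
# add --covariates to run the incremental-validity regression
dsitext validate --scores scores.csv --ratings ratings.csv --output report.json

# text-length bias audit
dsitext length-curve --input stories.csv --lengths 10,25,50,100 \
    --truncate-to 100 --seed 1 --output-dir curve/
```

## Library example

```python
from dsitext import Story, SyntheticConfig, dsi, embed_synthetic, prepare_static

story = Story("s1", "A grandmother sent a digital letter to an alien fleet.")
tokens = prepare_static(story)                    # stop words/numbers/punct removed
emb = embed_synthetic(tokens, SyntheticConfig(seed=7))
print(dsi(emb).value)                             # mean pairwise cosine distance
```
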