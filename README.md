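# dyadkl

Relative-entropy features of dyadic verbal interaction.

When two people interact, the topics of their joint conversation are not
simply a blend of what each of them talks about elsewhere: a significant
relationship imposes mutual constraints and produces an emergent topical
signature of its own. `dyadkl` turns that idea into a measurable pipeline
for speaker-attributed scripts (TV transcripts, therapy sessions, chat
logs): it extracts dyadic interactions, maps text to lexicon-based topic
distributions, computes Kullback-Leibler interaction features and
perspective-taking scores, and evaluates how well each feature separates
significant from non-significant relationships. It is aimed at
computational behavioral scientists who want an information-theoretic,
fully reproducible alternative to black-box text classifiers.

## The model

For a dyad with main character *G* and partner *C*, three discrete topic
distributions are formed over a lexicon's categories:

- **G** — everything *G* says across all her interactions,
- **C** — the same for the partner,
- **GC** — the joint text both produce within their mutual interaction.

Relative entropy (in bits, base-2),

```
D_KL(P‖Q) = Σₓ P(x) · log₂( P(x) / Q(x) ),
```

is the coding price of approximating one distribution by another. Four
divergences characterise the dyad — `D(GC‖G)`, `D(GC‖C)`, `D(C‖G)`,
`D(G‖C)` — and the two three-step paths around the G/C/GC triangle yield
signed *perspective-taking* scores and a *redundancy*:

```
Persp_G = D(GC‖C) + D(C‖G) − D(GC‖G)
Persp_C = D(GC‖G) + D(G‖C) − D(GC‖C)
ρ(G,C)  = | D(GC‖G) + D(G‖C) − (D(GC‖C) + D(C‖G)) |⁻¹
```

`Persp_G` is large when *G* can "see" the joint activity better through the
partner's constraints than directly; `ρ` is large when the two parties'
divergence paths to the joint activity converge. Because interaction
*length* is itself a near-perfect (and uninteresting) predictor of
significance, the package also implements the two controls needed to test
the features on their own merits: merging non-significant partners into
length-matched pseudo-characters, and replacing all text by neutral tokens
of identical length.

Each feature's discriminative power is measured with a balanced-resampling
protocol: repeatedly subsample the majority class to the size of the
minority class and average the stratified 3-fold cross-validated AUC of a
single-feature logistic regression `log(Pr[y=1]/Pr[y=0]) = a·f + b`, plus a
Mann-Whitney U test with a Monte-Carlo permutation p-value.

## Worked example

A synthetic corpus with a known generative structure: one main character,
13 significant partners whose dyads carry a strong emergent topic component
(δ = 0.8), 100 non-significant partners whose dyads are pure mixtures, and
equalised interaction lengths.

```python
from dyadkl import (SyntheticConfig, generate_corpus, generate_lexicon,
                    extract_dyad_interactions, apply_min_word_filter,
                    label_interactions, feature_table, evaluate_all)

config = SyntheticConfig(seed=1, n_mains=1, partners_per_main=(13, 100),
                         emergence_delta=0.8, confound_lengths=False)
lexicon = generate_lexicon(config.n_topics, config.words_per_topic, seed=1)
corpus, truth = generate_corpus(config, lexicon)

interactions = extract_dyad_interactions(corpus)
interactions = apply_min_word_filter(interactions, corpus, min_words=100)
labelled, excluded = label_interactions(interactions, truth.registry)
table = feature_table(labelled, lexicon)
print(f"{len(labelled)} dyads "
      f"({sum(i.label == 'significant' for i in labelled)} significant)")

for r in evaluate_all(table, features=["persp_g", "persp_c", "d_gc_g"], seed=1):
    print(f"{r.feature:8s}  mean AUC = {r.mean_auc:.3f}   "
          f"z = {r.mw_z:+.2f}   p = {r.mw_p:.4f}")
```

prints

```
113 dyads (13 significant)
persp_g   mean AUC = 1.000   z = -5.85   p = 0.0001
persp_c   mean AUC = 1.000   z = +5.85   p = 0.0001
d_gc_g    mean AUC = 1.000   z = +5.85   p = 0.0001
```

With the lengths equalised, the perspective-taking and dyad-divergence
features recover the planted emergent signal essentially perfectly (mean
balanced AUC 1.0; Mann-Whitney |z| ≈ 5.8, permutation p ≈ 10⁻⁴), while the
same pipeline with `emergence_delta=0` yields AUCs near 0.5 for every
feature. The sign of z shows the direction: significant dyads have *lower*
`persp_g` and *higher* `persp_c` under this generative law.

The same steps are available from the shell:

```bash
dyadkl simulate --seed 1 --out corpus.csv --lexicon-out lexicon.json --truth-out truth.json
dyadkl features --corpus corpus.csv --lexicon lexicon.json --out features.tsv
dyadkl evaluate --features features.tsv --seed 1 --out report.tsv
```

For a real script table (e.g. a TV-series transcript CSV with speaker and
text columns), use `read_script_table` with a column map and the built-in
significant-partner registry, or supply your own registry JSON.

## Layout

- `dyadkl.corpus_io` — script tables, sliding-window dyad extraction,
  volume filter, significance labelling
- `dyadkl.topic_model` — lexicons, topic distributions, support alignment
- `dyadkl.entropy_features` — KL features, perspective scores, redundancy
- `dyadkl.balancing` — length-matched partner merging
- `dyadkl.evaluation` — balanced AUC protocol, logistic/LDA fits,
  Mann-Whitney Monte Carlo
- `dyadkl.synthetic_data` — generative corpus simulator and the
  neutral-text control
- `docs/methods.md` — the model, its assumptions and every numerical choice
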