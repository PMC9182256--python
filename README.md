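# lexcat

**lexcat** implements the *lexical categorization model* (LCM) of left
ventral occipito-temporal cortex (lvOT) activation during visual word
recognition, together with the competitor neurocognitive models and the
benchmark / model-comparison machinery needed to evaluate it.

The package is aimed at researchers in computational cognitive
neuroscience and psycholinguistics who want to simulate lvOT responses
to letter strings, score those simulations against the published
benchmark contrasts, or compare them quantitatively with their own
region-of-interest (ROI) fMRI data.

## The model

The LCM holds that word-sensitive lvOT performs a *lexical
categorization* — a word/non-word decision — on every perceived letter
string, and that its BOLD activation tracks the **difficulty** of that
decision. Word-likeness is operationalized by OLD20, the mean
Levenshtein distance from a string to its 20 nearest words in a
reference lexicon. From a joint pool of words and non-words the model
estimates the conditional probability p(W | OLD20) that a string with a
given word-likeness is a word, and simulated activation is the binary
entropy of that probability:

    E = − p(W|OLD20) · log2 p(W|OLD20) − p(nW|OLD20) · log2 p(nW|OLD20)

Entropy is 0 where the categorization is certain (very word-like
strings are words; consonant strings are not) and 1 bit where words and
non-words are equally likely — reproducing the non-linear lvOT response
profile with peak activation at intermediate word-likeness.

The model has no free parameters: its output is fully determined by the
lexicon.

## What is in the package

| module | contents |
|---|---|
| `lexcat.lexicon` | SUBTLEX-style TSV reading, length/case filtering, frequency truncation, and a synthetic-lexicon generator (Zipf frequencies; morphological, CV-template and bigram-Markov letter models) |
| `lexcat.wordlikeness` | Levenshtein / optimal-string-alignment distances, OLD20 with a pruned but exact nearest-20 search, Coltheart's N, positional n-gram frequencies |
| `lexcat.stimuli` | pseudoword generation (vowel replacement until the string leaves the lexicon), consonant strings, the balanced W/PW/CS stimulus set, covariate matching |
| `lexcat.model` | the categorization curve (exact-bin and kernel-density estimators), binary entropy, and the LCM simulation |
| `lexcat.alternatives` | the lexicon-search, local-combination-detector, engagement-and-effort (E&E) and interactive-account (IA) competitor models |
| `lexcat.evaluation` | the nine-contrast benchmark registry with Bonferroni-corrected linear-model tests, qualitative model scoring, the SD-standardized simulation-vs-ROI comparison, model correlation matrices, subset-stability and lexicon-size robustness analyses |

A thin `lexcat` command-line interface wraps the library
(`lexcat lexicon synth`, `lexcat stimuli`, `lexcat simulate`,
`lexcat benchmark`, `lexcat compare`, `lexcat robustness`).

## Worked example

Everything below runs without any download: the synthetic lexicon
emulates the structure of a natural frequency lexicon (Zipf-distributed
frequencies, dense morphological families, loanword-like isolates).

```python
from lexcat.pipeline import run_canonical_study
from lexcat import run_benchmark_contrasts

run = run_canonical_study(n_words=2000, seed=0)
print(run.simulation.activation_by_category("median"))
```

```
category
CS    0.000
PW    0.542
W     0.351
```

Median simulated activation (entropy, in bits) reproduces the canonical
lvOT ordering: pseudowords are hardest to categorize (0.54), words are
intermediate (0.35), consonant strings are trivially rejected (0.00).

```python
for r in run_benchmark_contrasts(run.simulation, table=run.table):
    print(r.id, r.verdict)
```

```
pw_gt_w         correct
w_gt_cs         correct
pw_gt_w_gt_cs   correct
freq_slope      correct
```

The pseudoword > word and word > consonant-string contrasts are
significant in the expected direction (Bonferroni-corrected linear
models over items), their conjunction holds, and activation decreases
significantly with log2 word frequency over words and pseudowords
(pseudoword frequency fixed at 0). The pseudohomophone and matched-set
contrasts require external stimulus materials and are skipped with a
warning on the synthetic set.

With a real SUBTLEX-style lexicon the same pipeline applies unchanged:
`load_lexicon("subtlex-de.tsv")`, `filter_lexicon(lex, 5,
initial_uppercase=True)` (3,110 five-letter uppercase words in
SUBTLEX-DE), then exactly the calls above.

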