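# Methods

## The lexical categorization model

The model assumes that word-sensitive left ventral occipito-temporal
cortex (lvOT) classifies each incoming letter string as word or
non-word using only its word-likeness, and that activation reflects the
difficulty of this classification. Word-likeness is OLD20: the mean
edit distance from the string to its 20 closest words in a reference
lexicon. Difficulty is the binary entropy of the conditional
probability p(W | OLD20), estimated from a joint pool of words and
derived non-words. The model is deterministic given the lexicon — there
are no fitted parameters.

Two estimators of p(W | OLD20) are provided:

- **exact-bin** (default): strings are grouped into OLD20 bins of width
  1/20 — the natural granularity of a mean of 20 integer distances —
  and p(W | bin) is the word count divided by the string count. This
  reproduces hand counting exactly: a bin of 137 strings holding 116
  words gives p = .85 (and .15 for the complement). Empty bins are
  absent from the support; queries falling into them interpolate
  linearly between the flanking occupied bins, and queries beyond the
  support take the nearest occupied bin's value (the model is never
  queried there in the canonical studies; the rule exists so new
  strings always get an answer).
- **kde**: separate Gaussian kernel densities for words and non-words
  (Silverman's rule by default) combined as a density ratio with
  empirical class priors, p(x) = n_W f_W(x) / (n_W f_W(x) + n_NW
  f_NW(x)). This produces the smooth curves useful for plotting. On
  smooth continuous word-likeness data the two estimators agree within
  0.05 wherever a bin holds at least 50 strings (asserted in the test
  suite on a Gaussian-mixture table). On strongly discrete synthetic
  lexica (see below) the kernel estimator smooths over spikes in the
  OLD20 distribution, and bin-level deviations can be larger; exact-bin
  is therefore the default everywhere.

Simulated activation of an item is `entropy(p(W | OLD20_item))`, in
bits (0–1). Scrambled-letter controls carry no orthographic content and
are fixed at activation 0. Any rescaling (e.g. a 0–6 display range) is
cosmetic and never enters statistics: the comparison metric
z-transforms activations, which absorbs affine maps (property-tested).

Rounding for comparison with printed probabilities is round-half-away-
from-zero to two decimals.

## Word-likeness machinery

Edit distance defaults to plain Levenshtein, matching the reference
implementation used to popularize OLD20; an optimal-string-alignment
variant with adjacent transpositions is available behind a flag but is
not a metric (it violates the triangle inequality) and is excluded from
the metric property tests. The nearest-20 search visits length groups
in order of increasing |Δlength| and stops once that lower bound
exceeds the current 20th-best distance; because |len(a) − len(b)| ≤
d(a,b), the result is bit-identical to a full sort over all distances
(asserted against an independent alignment library on random lexica).
Ties at the 20th rank need no rule: any equal-distance subset yields
the same mean. Strings present in the reference exclude their own
distance-0 match by default, which would otherwise deflate their score.

OLD20 is computed against the full lexicon supplied, not only the
length-filtered word set, mirroring the convention of estimating
word-likeness for selected words against the complete database.

Positional n-gram scores count every occurrence of each n-gram of the
query anywhere in a reference word, weighted by that word's frequency
(`token`) or by one (`type`); `initial`/`final` return the first/last
n-gram's score, `summated` sums across the query's positions, `mean`
divides by the position count. Only token weighting is pinned by a
hand-counted example; the per-occurrence convention for type weighting
is a package choice.

## Stimulus construction

Pseudowords follow the replace-until-non-word rule: vowels are
repeatedly swapped for other vowels (drawn from the lexicon's own vowel
inventory) until the string is no longer a lexicon member. The swaps
accumulate, so in a sparse neighbourhood a single substitution suffices
(Augen → Augon) while in a saturated one the walk drifts further before
escaping — which is exactly what makes pseudowords systematically less
word-like than their base words when the lexicon is dense. An automated
bigram-attestation filter (every bigram of the output must occur
somewhere in the lexicon) stands in for manual orthographic-legality
revision; words whose walk cannot satisfy it within the attempt budget
are skipped together with their derived items, preserving category
balance. Consonant strings replace every vowel with a random consonant
(uniform by default; a letter-frequency-matched mode draws replacement
consonants by their token frequency in the lexicon). Pseudohomophones
cannot be generated without a phonology and are accepted as input
lists; scrambled-letter controls are category-only items without string
content.

Covariate matching (`match_groups`) standardizes the requested features
on the pooled groups and minimizes total Euclidean distance over
pairings by optimal assignment (Hungarian algorithm), which in one
dimension coincides with the sorted-order pairing; a greedy
closest-pair-first method is kept as an option. Optimal assignment was
chosen over greedy because greedy can return provably suboptimal
pairings on tie-heavy inputs while costing the same at these problem
sizes.

## The synthetic lexicon

Real frequency lexica cannot be redistributed with the package, so a
generator provides study-scale stand-ins. Frequencies always follow a
Zipf law (`rank^−s`, s = 1 by default, scaled to one million total
occurrences), and every word is unique, uppercase-initial and contains
a vowel.

The default letter model, `ablaut-morph`, emulates the two structural
features of natural lexica that drive the model's behaviour:

- **Dense morphological families.** Most words are generated as ablaut
  series — 4 (p = 0.4) or 5 (p = 0.6) vowel variants of a shared
  consonant frame plus an inflectional suffix drawn from a small
  Zipf-weighted inventory (en, er, el, an, in, on, et, ut) — over a
  deliberately small consonant alphabet (B D G L N R T). Families
  saturate the stem space the way a full natural lexicon (all lengths,
  all inflections) saturates the neighbourhood of its five-letter
  members: a word's 20 nearest neighbours are dominated by family and
  suffix-class members at distance 1–2, and most single vowel swaps
  collide with existing words.
- **Loanword-like isolates.** 30% of words are drawn as unaffiliated
  CV-template strings. Like real loanwords (Fazit, Bonus) they are
  morphologically unconnected and markedly less word-like, giving the
  word distribution the heavy right tail that places some words in the
  same word-likeness range as pseudowords.

Under this structure the vowel-swap walk started at a family word must
escape through a rare vowel combination, landing well outside the word
cluster, while isolates and their pseudowords populate the intermediate
range. The resulting geometry reproduces the canonical pattern: words
around OLD20 1.0–1.4 with a tail to ~2, pseudowords around 1.7–2.0,
consonant strings beyond 2.4; median entropy orders PW > W > CS and the
item-level frequency slope over words and pseudowords is negative.

What the generator does **not** emulate: real orthographic/phonotactic
constraints beyond CV alternation, cross-length morphology (all words
share one length), semantic or syllabic structure, umlauts, and the
empirical frequency–neighbourhood correlation (synthetic frequency is
assigned by rank independently of a word's neighbourhood). Passing
tests on synthetic data therefore demonstrate that the machinery is
correct and that the model's qualitative predictions follow from
realistic lexicon *geometry*; they do not certify quantitative values
for any particular language. The canonical synthetic study uses 2,000
words (6,000 items) — large enough for stable bin estimates at the 1/20
granularity, small enough that the full pipeline runs in seconds.
Because the pattern criteria compare medians of a discrete entropy
distribution, a minority of generator seeds (roughly one in ten) tie
the word and pseudoword medians; mean-level contrasts are robust across
seeds. The packaged studies fix seed 0.

The `uniform-cv` and `bigram-markov` models draw words independently;
they are kept for generality and for tests that need unstructured
strings. Independent draws give words and derived pseudowords nearly
identical word-likeness distributions (there are no families to anchor
the words), so they cannot reproduce the canonical category ordering —
this is a property of unstructured lexica, not a defect of the model.

## Competitor models

Each alternative account is reduced to a transparent single-knob form
that produces its characteristic effect directions:

- **lexicon**: activation = normalized rank in a frequency-ordered
  serial search; any non-member triggers an exhaustive search
  (activation 1).
- **cd** (local combination detector): activation is linear in word
  similarity, taken as negated min-max-normalized OLD20.
- **ee** (engagement and effort): a decreasing logistic in OLD20
  (engagement) times 1 − normalized log2(1 + frequency) (effort;
  non-words at 1).
- **ia** (interactive account): the same functional form read as
  prediction eligibility × surprise; kept as a separately named model
  with its own parameter block so that richer, diverging forms can be
  dropped in.

The logistic midpoint defaults to the orthographic-legality boundary —
halfway between the median OLD20 of pseudowords and of consonant
strings — because engagement/eligibility in these accounts separates
possible words from obviously illegal strings; placing it at the
word/non-word probability crossover (also available via
`params_from_curve`) puts both words and pseudowords on the same side
of the sigmoid and collapses the contrast the models are meant to
produce. Slope defaults to 4 per OLD20 unit. With slope → 0 the IA
model degenerates to the lexicon model's frequency ordering over words
(tested). All model outputs live in [0, 1]; scrambled-letter items are
0 in every model.

## Benchmarks and comparison metric

The registry encodes nine published lvOT effects: PW>W, W>CS, their
conjunction, PH>W, PH=PW, matched-PW>matched-W, the word-similarity
chain lWS<iWS<hWS=cmW, a negative log2-frequency slope over W∪PW (PW
frequency 0), and a positive log2-bigram-frequency slope (with a
documented quadratic refit). Contrasts are ordinary linear models over
items (items treated as independent observations); p-values are
Bonferroni-corrected over the family of nine. A directional contrast is
correct when significant in the expected direction, incorrect when
significant in the opposite direction, otherwise null; equality
contrasts (PH=PW, hWS=cmW) are correct when the corrected p ≥ .05 — a
pragmatic non-significance criterion; a TOST-style equivalence option
could be added but non-significance is the scoring rule implemented.
The conjunction is scored from its two member contrasts and counts as
one of the nine. Numerically zero effects (degenerate inputs) are
treated as exact nulls rather than trusting float-noise t-statistics.
`score_correct` counts correct verdicts; `score_penalized` subtracts
incorrect ones, with nulls exempt from penalty. Missing conditions or
predictors skip a contrast with a warning — never a silent pass.

The matched conditions (mW/mPW; cmW/hWS/iWS/lWS) are derived by
covariate matching: words to pseudowords on the classic lexical
covariates; high-word-similarity non-words matched on quadrigram
frequency, intermediate on summated bigram frequency, with the
unmatched consonant strings as the low-similarity condition.

The quantitative comparison z-transforms simulated activations across
items and observed percent-signal-change across all
participant-by-condition cells (a per-participant variant is a flag),
then measures, for each condition pair, |Δsim − Δobs| in units of the
standard deviation of the participant-level observed difference scores.
The difference-score SD (rather than a pooled cell SD) is used because
the contrast is a within-participant quantity; a model reproducing the
observed condition means exactly scores 0 on every contrast.

Robustness analyses: `subset_stability` refits the curve on stratified
item subsets (20 draws per proportion by default, one top-level seed)
and correlates subset-based item entropies with full-set entropies —
the full-set proportion returns r = 1 exactly, and mean r rises toward
1 as the proportion grows; `lexicon_size_sweep` truncates the lexicon
to its most frequent words, rebuilds everything, and reports category
medians per size (sizes below 21 cannot support OLD20 with
self-exclusion and are skipped). On the canonical synthetic set the
category ordering emerges only once the lexicon is a few hundred words,
echoing the requirement of a sufficiently stocked lexicon.

## Degenerate inputs and numerical choices

Duplicate lexicon rows collapse by summing frequencies, with a warning.
Comparisons are case-sensitive throughout. Binning snaps values with
round-half-up on the bin index and rounds bin labels to 10 decimals to
keep multiples of 1/20 stable in float arithmetic. Zero-variance inputs
raise (z-transforms, the similarity contrast of the cd model) or mark
the output as undefined (correlation matrix) rather than silently
returning 0. The curve's JSON serialization stores support,
probabilities, entropy and estimator metadata; a deserialized kernel
curve falls back to interpolation on its stored grid because the kernel
objects themselves are not serialized.

## Known limitations

No trial-level dynamics, hemodynamic convolution, or decision model:
regressor values are per-item scalars. No phonology: pseudohomophones
are inputs, not products. The Dual Route model is out of scope; its
simulated activations can be supplied through the same CSV schema for
comparison. Whole-brain analysis, cluster statistics and mixed-model
training analyses are deliberately absent — observed data enter only as
per-participant, per-condition ROI summaries.
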