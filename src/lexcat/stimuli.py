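"""Stimulus construction: pseudowords, consonant strings, matched groups.

The canonical stimulus set behind the lexical categorization model pairs
every base word with one pseudoword (vowels swapped for other vowels,
e.g. *Augen* -> *Augon*) and one consonant string (every vowel replaced
by a random consonant, e.g. *Augen* -> *Zbgtn*), giving balanced
word / pseudoword / consonant-string categories.  Pseudohomophones
cannot be generated without a phonology and are accepted as an input
list; scrambled-letter controls are category-only items with no string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .lexicon import VOWELS, Lexicon

CATEGORIES = ("W", "PW", "CS", "PH", "SL")

_CONSONANTS_UPPER = "BCDFGHJKLMNPQRSTVWXYZ"


@dataclass
class StimulusItem:
    string: str | None
    category: str
    base_word: str | None = None
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "SL":
            if self.string is not None:
                raise ValueError("SL items carry no string content")
        elif not self.string:
            raise ValueError("non-SL items need a non-empty string")


@dataclass
class StimulusSet:
    """Ordered stimulus items plus generation provenance."""

    items: list[StimulusItem]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for it in self.items:
            counts[it.category] = counts.get(it.category, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "string": [it.string for it in self.items],
                "category": [it.category for it in self.items],
                "base_word": [it.base_word for it in self.items],
                "frequency": [it.frequency for it in self.items],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "StimulusSet":
        items = [
            StimulusItem(
                string=None if pd.isna(r.string) else str(r.string),
                category=str(r.category),
                base_word=None if pd.isna(r.base_word) else str(r.base_word),
                frequency=float(r.frequency) if not pd.isna(r.frequency) else 0.0,
            )
            for r in frame.itertuples()
        ]
        return cls(items, provenance or {})


def _vowel_positions(word: str, vowels: str) -> list[int]:
    return [i for i, c in enumerate(word) if c in vowels]


def _match_case(template: str, letter: str) -> str:
    return letter.upper() if template.isupper() else letter.lower()


def _bigrams_attested(s: str, bigrams: set[str]) -> bool:
    return all(s[i : i + 2] in bigrams for i in range(len(s) - 1))


def _lexicon_bigrams(lexicon: Lexicon) -> set[str]:
    cache = getattr(lexicon, "_bigram_set", None)
    if cache is None:
        cache = {w[i : i + 2] for w in lexicon.words for i in range(len(w) - 1)}
        lexicon._bigram_set = cache  # type: ignore[attr-defined]
    return cache


def make_pseudoword(
    word: str,
    lexicon: Lexicon,
    rng: np.random.Generator,
    legality: str = "bigram-attested",
    max_attempts: int = 400,
    vowels: str = VOWELS,
) -> str:
    """Derive a pseudoword by repeatedly swapping vowels for other vowels
    until the string is no longer a lexicon word.

    Vowel substitutions accumulate: each step replaces one vowel slot
    with a different vowel, and the walk stops at the first string that
    is not in the lexicon (in a sparse neighbourhood a single swap
    suffices, e.g. Augen -> Augon; in a saturated one the walk drifts
    further before it escapes — the behaviour that makes pseudowords
    systematically less word-like than the words they derive from).
    The result has the word's length, differs from it only at vowel
    positions, and is never a lexicon member.  Under
    ``legality="bigram-attested"`` every bigram of the output must occur
    somewhere in the lexicon — an automated stand-in for manual
    orthographic-legality revision.
    """
    if legality not in ("bigram-attested", "none"):
        raise ValueError(f"unknown legality {legality!r}")
    positions = _vowel_positions(word, vowels)
    if not positions:
        raise ValueError(f"cannot build a pseudoword from {word!r}: no vowel")
    # replacement vowels come from the lexicon's own vowel inventory, so
    # e.g. an umlaut-free lexicon never yields umlaut pseudowords
    letters = getattr(lexicon, "_letter_set", None)
    if letters is None:
        letters = {c.upper() for w in lexicon.words for c in w}
        lexicon._letter_set = letters  # type: ignore[attr-defined]
    vowel_pool = sorted({v.upper() for v in vowels} & letters) or sorted(
        {v.upper() for v in vowels}
    )
    bigrams = _lexicon_bigrams(lexicon) if legality == "bigram-attested" else None
    current = word
    for _ in range(max_attempts):
        pos = positions[rng.integers(len(positions))]
        choices = [v for v in vowel_pool if v != current[pos].upper()]
        repl = _match_case(word[pos], choices[rng.integers(len(choices))])
        current = current[:pos] + repl + current[pos + 1 :]
        if current == word or current in lexicon:
            continue
        if bigrams is not None and not _bigrams_attested(current, bigrams):
            continue
        return current
    raise RuntimeError(
        f"pseudoword generation for {word!r} exhausted {max_attempts} attempts"
    )


def make_consonant_string(
    word: str,
    rng: np.random.Generator,
    mode: str = "uniform",
    lexicon: Lexicon | None = None,
    vowels: str = VOWELS,
    consonants: str = _CONSONANTS_UPPER,
) -> str:
    """Replace every vowel of *word* with a consonant; consonant
    positions are untouched, so the output has the same length and no
    vowel.  ``letter-frequency-matched`` mode draws replacement
    consonants with probability proportional to their token frequency in
    the lexicon."""
    if mode not in ("uniform", "letter-frequency-matched"):
        raise ValueError(f"unknown mode {mode!r}")
    if not word:
        raise ValueError("word must be non-empty")
    if mode == "letter-frequency-matched":
        if lexicon is None:
            raise ValueError("letter-frequency-matched mode requires a lexicon")
        weights = np.zeros(len(consonants))
        pos = {c: i for i, c in enumerate(consonants)}
        for w, f in zip(lexicon.words, lexicon.frequencies):
            for c in w.upper():
                if c in pos:
                    weights[pos[c]] += f + 1.0  # +1 smooths zero-frequency words
        probs = weights / weights.sum()
    else:
        probs = None
    chars = list(word)
    for i, c in enumerate(chars):
        if c in vowels:
            if probs is None:
                repl = consonants[rng.integers(len(consonants))]
            else:
                repl = consonants[rng.choice(len(consonants), p=probs)]
            chars[i] = _match_case(c, repl)
    return "".join(chars)


def build_stimulus_set(
    word_lexicon: Lexicon,
    rng: np.random.Generator | int,
    legality: str = "bigram-attested",
    cs_mode: str = "uniform",
    max_attempts: int = 400,
    vowels: str = VOWELS,
) -> StimulusSet:
    """One pseudoword and one consonant string per base word, giving the
    balanced W/PW/CS set.  Words without a vowel, or whose pseudoword
    generation exhausts its attempt budget, are skipped (with a warning)
    together with their derived items, preserving category balance."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    words: list[StimulusItem] = []
    pws: list[StimulusItem] = []
    css: list[StimulusItem] = []
    skipped: list[str] = []
    for w, f in zip(word_lexicon.words, word_lexicon.frequencies):
        if not _vowel_positions(w, vowels):
            skipped.append(w)
            continue
        try:
            pw = make_pseudoword(
                w, word_lexicon, rng, legality=legality,
                max_attempts=max_attempts, vowels=vowels,
            )
        except RuntimeError:
            skipped.append(w)
            continue
        cs = make_consonant_string(
            w, rng, mode=cs_mode, lexicon=word_lexicon, vowels=vowels
        )
        words.append(StimulusItem(w, "W", base_word=w, frequency=float(f)))
        pws.append(StimulusItem(pw, "PW", base_word=w, frequency=0.0))
        css.append(StimulusItem(cs, "CS", base_word=w, frequency=0.0))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} base word(s) (no vowel or generation "
            f"budget exhausted): {skipped[:5]}{'...' if len(skipped) > 5 else ''}"
        )
    return StimulusSet(
        words + pws + css,
        provenance={
            "lexicon": word_lexicon.name,
            "seed": seed,
            "legality": legality,
            "cs_mode": cs_mode,
            "skipped": len(skipped),
        },
    )


def match_groups(
    a: pd.DataFrame,
    b: pd.DataFrame,
    features: list[str],
    n_pairs: int,
    method: str = "optimal",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pair items of *a* with items of *b* on standardized feature
    vectors, without replacement.

    ``method="optimal"`` minimizes the total Euclidean distance over all
    pairings (Hungarian assignment); ``"greedy"`` repeatedly takes the
    globally closest unused pair.  The *n_pairs* closest matched pairs
    are returned together with the per-feature standardized mean
    difference (matched-group mean difference over the pooled SD) of the
    matched groups.
    """
    if method not in ("optimal", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    for feat in features:
        if feat not in a.columns or feat not in b.columns:
            raise ValueError(f"feature {feat!r} missing from one of the groups")
    if n_pairs > min(len(a), len(b)):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds smaller group size {min(len(a), len(b))}"
        )
    fa = a[features].to_numpy(dtype=float)
    fb = b[features].to_numpy(dtype=float)
    pooled = np.concatenate([fa, fb])
    mu, sd = pooled.mean(axis=0), pooled.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    za, zb = (fa - mu) / sd, (fb - mu) / sd
    dist = cdist(za, zb)
    if method == "optimal":
        rows, cols = linear_sum_assignment(dist)
    else:
        rows_l, cols_l = [], []
        d = dist.copy()
        for _ in range(min(len(a), len(b))):
            r, c = np.unravel_index(np.argmin(d), d.shape)
            rows_l.append(r)
            cols_l.append(c)
            d[r, :] = np.inf
            d[:, c] = np.inf
        rows, cols = np.asarray(rows_l), np.asarray(cols_l)
    order = np.argsort(dist[rows, cols], kind="stable")[:n_pairs]
    rows, cols = rows[order], cols[order]
    pairs = pd.DataFrame(
        {
            "index_a": a.index[rows],
            "index_b": b.index[cols],
            "distance": dist[rows, cols],
        }
    )
    smd = {}
    for j, feat in enumerate(features):
        diff = za[rows, j].mean() - zb[cols, j].mean()
        smd[feat] = float(diff)
    return pairs, smd
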