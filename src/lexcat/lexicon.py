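"""Frequency lexica: reading, filtering, truncating, and synthesis.

A :class:`Lexicon` is the reference set for every word-likeness metric in
this package: an ordered word -> frequency (occurrences per million)
mapping, e.g. a SUBTLEX-style corpus export.  Comparisons are
case-sensitive throughout (German nouns carry an initial uppercase
letter, and the canonical word set is selected on exactly that).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: German vowel inventory (both cases).  Configurable per call where it matters.
VOWELS = "AEIOUÄÖÜaeiouäöü"

_DEFAULT_CONSONANTS = "BCDFGHJKLMNPRSTVWZ"
_DEFAULT_VOWELS = "AEIOU"


class LexiconFormatError(ValueError):
    """A lexicon file row that does not parse to (word, numeric frequency)."""


@dataclass
class Lexicon:
    """Ordered collection of unique words with per-million frequencies."""

    words: list[str]
    frequencies: np.ndarray
    name: str = "lexicon"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.words) != len(self.frequencies):
            raise ValueError("words and frequencies differ in length")
        if len(set(self.words)) != len(self.words):
            raise ValueError("lexicon words must be unique (case-sensitive)")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        self._index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __iter__(self):
        return iter(self.words)

    def frequency(self, word: str, default: float = 0.0) -> float:
        """Per-million frequency of *word*, or *default* if absent."""
        i = self._index.get(word)
        return float(self.frequencies[i]) if i is not None else default

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Word": self.words, "Frequency": self.frequencies})

    def to_tsv(self, path, header: bool = True) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=header)


def load_lexicon(path, dialect: str = "subtlex-tsv", name: str | None = None) -> Lexicon:
    """Read a tab-separated frequency lexicon.

    Parameters
    ----------
    path
        UTF-8 TSV file.  ``subtlex-tsv``: optional ``Word\\tFrequency``
        header (detected from the first line); ``two-column-tsv``: no
        header, two columns.
    dialect
        ``"subtlex-tsv"`` or ``"two-column-tsv"``.

    Duplicate words are collapsed by summing their frequencies, with a
    logged warning; file order of first occurrence is preserved.
    """
    if dialect not in ("subtlex-tsv", "two-column-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    words: list[str] = []
    freqs: list[float] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    # drop trailing blank lines
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise LexiconFormatError(f"{path}: empty lexicon file")
    start = 0
    if dialect == "subtlex-tsv":
        first = lines[0].split("\t")
        if len(first) >= 2:
            try:
                float(first[1])
            except ValueError:
                start = 1  # header row
    if start >= len(lines):
        raise LexiconFormatError(f"{path}: no data rows")
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0]:
            raise LexiconFormatError(f"{path}: line {lineno}: expected 'word<TAB>frequency'")
        try:
            freq = float(parts[1])
        except ValueError as exc:
            raise LexiconFormatError(
                f"{path}: line {lineno}: non-numeric frequency {parts[1]!r}"
            ) from exc
        if freq < 0:
            raise LexiconFormatError(f"{path}: line {lineno}: negative frequency")
        words.append(parts[0])
        freqs.append(freq)
    if len(set(words)) != len(words):
        seen: dict[str, int] = {}
        out_w: list[str] = []
        out_f: list[float] = []
        n_dup = 0
        for w, f in zip(words, freqs):
            if w in seen:
                out_f[seen[w]] += f
                n_dup += 1
            else:
                seen[w] = len(out_w)
                out_w.append(w)
                out_f.append(f)
        logger.warning("collapsed %d duplicate word(s) by summing frequencies", n_dup)
        warnings.warn(f"collapsed {n_dup} duplicate lexicon row(s) by summing frequencies")
        words, freqs = out_w, out_f
    return Lexicon(words, np.asarray(freqs), name=name or str(path))


def filter_lexicon(lex: Lexicon, length: int, initial_uppercase: bool = False) -> Lexicon:
    """Keep words with exactly *length* letters (and, optionally, an
    uppercase first character).  Order preserved; empty result is legal."""
    if len(lex) == 0:
        raise ValueError("cannot filter an empty lexicon")
    keep = [
        i
        for i, w in enumerate(lex.words)
        if len(w) == length and (not initial_uppercase or w[:1].isupper())
    ]
    return Lexicon(
        [lex.words[i] for i in keep],
        lex.frequencies[keep],
        name=f"{lex.name}|len={length}" + ("|upper" if initial_uppercase else ""),
    )


def truncate_by_frequency(lex: Lexicon, n: int) -> Lexicon:
    """The *n* highest-frequency entries, in non-increasing frequency
    order; ties broken by input order.  ``n`` beyond the lexicon size
    returns the full lexicon with a warning."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(lex):
        warnings.warn(
            f"requested {n} entries but lexicon has only {len(lex)}; returning all"
        )
        n = len(lex)
    # stable sort on descending frequency keeps input order within ties
    order = np.argsort(-lex.frequencies, kind="stable")[:n]
    return Lexicon(
        [lex.words[i] for i in order],
        lex.frequencies[order],
        name=f"{lex.name}|top{n}" if n < len(lex) else lex.name,
    )


def _zipf_frequencies(n: int, exponent: float) -> np.ndarray:
    """Per-million frequencies following a Zipf law over ranks 1..n."""
    ranks = np.arange(1, n + 1, dtype=float)
    mass = ranks ** (-exponent)
    return 1e6 * mass / mass.sum()


#: Inflectional-suffix inventory of the morphological letter model, with
#: Zipf-like popularity weights (the "-en"-type class dominates, as in
#: German five-letter nouns).
MORPH_SUFFIXES = ("en", "er", "el", "an", "in", "on", "et", "ut")
MORPH_SUFFIX_WEIGHTS = (0.30, 0.22, 0.14, 0.10, 0.08, 0.07, 0.05, 0.04)

#: Core consonant inventory; deliberately small so that the ablaut
#: families saturate the stem space the way a full natural lexicon
#: (all lengths, all inflections) saturates the neighbourhood of its
#: five-letter members.
MORPH_CONSONANTS = "BDGLNRT"

#: Fraction of words generated as unstructured "loanword-like" isolates
#: (cf. Fazit, Bonus): morphologically unaffiliated, hence less
#: word-like than family members.
MORPH_ISOLATE_RATE = 0.30

#: Ablaut family sizes (vowel variants per consonant frame + suffix) and
#: their probabilities.  Families of 4-5 mirror the dense morphological
#: neighbourhoods (plural/case/derivation) real words sit in.
MORPH_FAMILY_SIZES = (4, 5)
MORPH_FAMILY_WEIGHTS = (0.4, 0.6)


def _synth_morph_words(
    n_words: int, length: int, rng: np.random.Generator, vowels: str, budget: int
) -> list[str]:
    """Morphologically structured word list: ablaut families sharing a
    consonant frame and suffix, plus unaffiliated isolates."""
    con = MORPH_CONSONANTS
    vow = vowels
    # stem prefix: alternating C(V C)* covering length-2 slots; suffix: V+C
    prefix_len = length - 2
    suffix_cons = [s[1] for s in MORPH_SUFFIXES]
    w_suf = np.asarray(MORPH_SUFFIX_WEIGHTS) / np.sum(MORPH_SUFFIX_WEIGHTS)
    w_fam = np.asarray(MORPH_FAMILY_WEIGHTS) / np.sum(MORPH_FAMILY_WEIGHTS)
    frames = [(c1, c2) for c1 in con for c2 in con]
    rng.shuffle(frames)
    seen: set[str] = set()
    words: list[str] = []

    def add(w: str) -> None:
        if w not in seen and len(words) < n_words:
            seen.add(w)
            words.append(w)

    def fill_prefix(first: str, ablaut: str, last: str) -> str:
        # consonants at even slots, vowels at odd; slot 1 carries the ablaut
        out = []
        for i in range(prefix_len):
            if i == 0:
                out.append(first)
            elif i == 1:
                out.append(ablaut)
            elif i == prefix_len - 1:
                out.append(last)
            elif i % 2 == 0:
                out.append(con[rng.integers(len(con))])
            else:
                out.append(vow[rng.integers(len(vow))])
        return "".join(out)

    tries = 0
    while len(words) < n_words:
        tries += 1
        if tries > budget:
            raise RuntimeError(
                f"could not generate {n_words} unique words within {budget} attempts"
            )
        if rng.random() < MORPH_ISOLATE_RATE:
            w = "".join(
                vow[rng.integers(len(vow))] if i % 2 == 1 else con[rng.integers(len(con))]
                for i in range(length)
            )
            add(w.capitalize())
        else:
            c1, c2 = frames[rng.integers(len(frames))]
            suf = MORPH_SUFFIXES[rng.choice(len(MORPH_SUFFIXES), p=w_suf)]
            k = MORPH_FAMILY_SIZES[rng.choice(len(MORPH_FAMILY_SIZES), p=w_fam)]
            for vi in rng.choice(len(vow), size=min(k, len(vow)), replace=False):
                stem = fill_prefix(c1, vow[vi], c2)
                add((stem + suf).capitalize())
    return words


def synth_lexicon(
    n_words: int,
    length: int = 5,
    zipf_exponent: float = 1.0,
    seed: int = 0,
    letter_model: str = "ablaut-morph",
    vowels: str = _DEFAULT_VOWELS,
    consonants: str = _DEFAULT_CONSONANTS,
    max_attempts_factor: int = 1000,
) -> Lexicon:
    """Generate a Zipf-distributed synthetic lexicon.

    Every word is unique, uppercase-initial, exactly *length* letters and
    contains at least one vowel, so the output passes the canonical
    five-letter/uppercase filter unchanged.  Frequencies follow
    ``rank**-zipf_exponent`` scaled to one million total occurrences.

    Letter models
    -------------
    ``"ablaut-morph"`` (default)
        Morphologically structured: most words come in ablaut families —
        4-5 vowel variants of a shared consonant frame plus an
        inflectional suffix drawn from a small Zipf-weighted inventory —
        over a deliberately small consonant alphabet, so families
        saturate the stem space; the remainder are unaffiliated
        "loanword-like" isolates.  This emulates the neighbourhood
        structure of a natural lexicon (dense morphological families
        plus sparse loanwords), which is what gives real words their
        characteristically low orthographic distances relative to
        derived non-words.  Requires ``length >= 4``.
    ``"uniform-cv"``
        Strict consonant-vowel alternation with uniform independent
        letter draws; words are mutually unrelated, so words and derived
        pseudowords occupy nearly identical word-likeness ranges.
    ``"bigram-markov"``
        Two-state chain favouring CV alternation but permitting
        consonant clusters and vowel digraphs.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if letter_model not in ("ablaut-morph", "uniform-cv", "bigram-markov"):
        raise ValueError(f"unknown letter_model {letter_model!r}")
    rng = np.random.default_rng(seed)
    vow = list(vowels.upper())
    con = list(consonants.upper())
    budget = max_attempts_factor * n_words
    if letter_model == "ablaut-morph":
        if length < 4:
            raise ValueError("ablaut-morph letter model requires length >= 4")
        words = _synth_morph_words(n_words, length, rng, "EAIOU", budget)
    else:
        seen: set[str] = set()
        words = []
        attempts = 0
        while len(words) < n_words:
            attempts += 1
            if attempts > budget:
                raise RuntimeError(
                    f"could not generate {n_words} unique words of length {length} "
                    f"within {budget} attempts; enlarge the alphabet or length"
                )
            if letter_model == "uniform-cv":
                letters = [
                    vow[rng.integers(len(vow))] if i % 2 == 1 else con[rng.integers(len(con))]
                    for i in range(length)
                ]
            else:
                letters = [con[rng.integers(len(con))]]
                for _ in range(length - 1):
                    if letters[-1] in con:
                        pool = vow if rng.random() < 0.75 else con
                    else:
                        pool = con if rng.random() < 0.85 else vow
                    letters.append(pool[rng.integers(len(pool))])
            word = letters[0].upper() + "".join(letters[1:]).lower()
            if word in seen or not any(c in VOWELS for c in word):
                continue
            seen.add(word)
            words.append(word)
    return Lexicon(
        words,
        _zipf_frequencies(n_words, zipf_exponent),
        name=f"synthetic({letter_model},n={n_words},len={length},s={zipf_exponent},seed={seed})",
    )
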