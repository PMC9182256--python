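"""Word-likeness metrics against a reference lexicon.

OLD20 — the mean Levenshtein distance from a letter string to its 20
nearest words — is the word-likeness measure driving the lexical
categorization model; Coltheart's N and positional n-gram frequencies are
the classical alternatives kept for matching covariates and robustness
checks.

The distance kernel is a NumPy dynamic program batched over all
reference words of one length, and the nearest-20 search prunes whole
length groups via the bound ``edit_distance >= |len(a) - len(b)|``; the
result is bit-identical to a full sort over all distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon

if TYPE_CHECKING:  # pragma: no cover
    from .stimuli import StimulusSet

_VARIANTS = ("levenshtein", "osa-transposition")


def edit_distance(a: str, b: str, variant: str = "levenshtein") -> int:
    """Minimal number of insertions, deletions and substitutions (plus
    adjacent transpositions under ``osa-transposition``) turning *a* into
    *b*.

    The plain Levenshtein variant is a true metric; the
    optimal-string-alignment transposition variant is not (it violates
    the triangle inequality) and is offered as a flag only.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if not a or not b:
        raise ValueError("edit_distance requires non-empty strings")
    m, n = len(a), len(b)
    prev2 = None
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                variant == "osa-transposition"
                and i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[n]


# ---------------------------------------------------------------------------
# batched distances


def _encode(s: str, vocab: dict[str, int]) -> np.ndarray:
    # unseen characters get unique negative codes: they mismatch everything
    return np.array([vocab.get(c, -(ord(c) + 1)) for c in s], dtype=np.int32)


def _reference_index(lex: Lexicon) -> dict:
    """Length-grouped integer encoding of the lexicon, cached on it."""
    cache = getattr(lex, "_wordlikeness_index", None)
    if cache is not None:
        return cache
    vocab: dict[str, int] = {}
    for w in lex.words:
        for c in w:
            if c not in vocab:
                vocab[c] = len(vocab)
    groups: dict[int, dict] = {}
    by_len: dict[int, list[int]] = {}
    for i, w in enumerate(lex.words):
        by_len.setdefault(len(w), []).append(i)
    for length, idx in by_len.items():
        enc = np.empty((len(idx), length), dtype=np.int32)
        for r, i in enumerate(idx):
            enc[r] = _encode(lex.words[i], vocab)
        groups[length] = {"indices": np.asarray(idx), "enc": enc}
    cache = {"vocab": vocab, "groups": groups}
    lex._wordlikeness_index = cache  # type: ignore[attr-defined]
    return cache


def _batch_distances(q: np.ndarray, enc: np.ndarray, variant: str) -> np.ndarray:
    """Edit distances from one encoded query to every row of *enc*."""
    n_words, L = enc.shape
    m = len(q)
    prev2 = None
    prev = np.broadcast_to(np.arange(L + 1, dtype=np.int32), (n_words, L + 1)).copy()
    for i in range(1, m + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        qi = q[i - 1]
        for j in range(1, L + 1):
            sub = prev[:, j - 1] + (enc[:, j - 1] != qi)
            np.minimum(sub, prev[:, j] + 1, out=sub)
            np.minimum(sub, cur[:, j - 1] + 1, out=sub)
            if variant == "osa-transposition" and i > 1 and j > 1:
                trans = (enc[:, j - 1] == q[i - 2]) & (enc[:, j - 2] == qi)
                sub = np.where(trans, np.minimum(sub, prev2[:, j - 2] + 1), sub)
            cur[:, j] = sub
        prev2, prev = prev, cur
    return prev[:, L]


def distances_to_reference(
    s: str, reference: Lexicon, variant: str = "levenshtein"
) -> np.ndarray:
    """Edit distance from *s* to every reference word, in lexicon order."""
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    index = _reference_index(reference)
    q = _encode(s, index["vocab"])
    out = np.empty(len(reference), dtype=np.int32)
    for grp in index["groups"].values():
        out[grp["indices"]] = _batch_distances(q, grp["enc"], variant)
    return out


def old20(
    s: str,
    reference: Lexicon,
    exclude_self: bool = True,
    k: int = 20,
    variant: str = "levenshtein",
) -> float:
    """Mean edit distance from *s* to its *k* (default 20) nearest
    reference words.

    Length groups are visited in order of increasing ``|len(word) -
    len(s)|`` and a group is skipped entirely once that lower bound
    exceeds the current k-th best distance; ties at the k-th rank are by
    distance only, so any equal-distance subset yields the same mean.
    ``exclude_self`` removes exact matches of *s* before ranking (a
    word's distance-0 self-match would deflate its own score).
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if not s:
        raise ValueError("old20 requires a non-empty string")
    n_self = 1 if (exclude_self and s in reference) else 0
    if len(reference) - n_self < k:
        raise ValueError(
            f"old20 needs >= {k + n_self} reference words "
            f"(got {len(reference)}, excluding self: {bool(n_self)})"
        )
    index = _reference_index(reference)
    q = _encode(s, index["vocab"])
    groups = sorted(index["groups"].items(), key=lambda kv: abs(kv[0] - len(s)))
    best = np.empty(0, dtype=np.int32)
    for length, grp in groups:
        bound = abs(length - len(s))
        if len(best) >= k and bound > best[k - 1]:
            break
        d = _batch_distances(q, grp["enc"], variant)
        if n_self and length == len(s):
            self_rows = np.array(
                [reference.words[i] == s for i in grp["indices"]], dtype=bool
            )
            d = d[~self_rows]
        best = np.sort(np.concatenate([best, d]))[: k + 1]
    return float(best[:k].mean())


def coltheart_n(s: str, reference: Lexicon) -> int:
    """Number of same-length reference words differing from *s* by
    exactly one substituted letter; *s* itself is never counted."""
    if len(reference) == 0:
        raise ValueError("reference lexicon is empty")
    index = _reference_index(reference)
    grp = index["groups"].get(len(s))
    if grp is None:
        return 0
    q = _encode(s, index["vocab"])
    return int(((grp["enc"] != q).sum(axis=1) == 1).sum())


def _ngram_counts(reference: Lexicon, n: int, weighting: str) -> dict[str, float]:
    key = ("_ngram_counts", n, weighting)
    cache = getattr(reference, "_ngram_cache", None)
    if cache is None:
        cache = {}
        reference._ngram_cache = cache  # type: ignore[attr-defined]
    if key in cache:
        return cache[key]
    counts: dict[str, float] = {}
    for w, f in zip(reference.words, reference.frequencies):
        weight = f if weighting == "token" else 1.0
        for i in range(len(w) - n + 1):
            g = w[i : i + n]
            counts[g] = counts.get(g, 0.0) + weight
    cache[key] = counts
    return counts


def ngram_score(
    s: str,
    reference: Lexicon,
    n: int = 2,
    position: str = "summated",
    weighting: str = "token",
) -> float:
    """Positional n-gram frequency of *s* from the reference.

    Each occurrence of an n-gram anywhere in a reference word contributes
    that word's frequency (``token``) or one (``type``).  ``initial`` /
    ``final`` return the first/last n-gram's score, ``summated`` sums
    over all ``len(s) - n + 1`` positions, ``mean`` divides the sum by
    that position count.
    """
    if position not in ("initial", "final", "summated", "mean"):
        raise ValueError(f"unknown position {position!r}")
    if weighting not in ("token", "type"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if n > len(s):
        raise ValueError(f"n={n} exceeds length of {s!r}")
    counts = _ngram_counts(reference, n, weighting)
    grams = [s[i : i + n] for i in range(len(s) - n + 1)]
    if position == "initial":
        return counts.get(grams[0], 0.0)
    if position == "final":
        return counts.get(grams[-1], 0.0)
    total = sum(counts.get(g, 0.0) for g in grams)
    if position == "mean":
        return total / len(grams)
    return total


@dataclass
class WordLikenessTable:
    """Per-string word-likeness measures; one row per stimulus item.

    ``data`` columns: ``string``, ``category``, ``frequency`` plus one
    column per requested measure (``old20``, ``coltheart_n``,
    ``bigram_*`` ...).  Scrambled-letter (SL) items carry no string and
    get NaN measures — their simulated activation is fixed elsewhere.
    """

    data: pd.DataFrame
    reference_name: str = ""

    def __len__(self) -> int:
        return len(self.data)


_NGRAM_MEASURES = {
    "initial_bigram": (2, "initial"),
    "final_bigram": (2, "final"),
    "summated_bigram": (2, "summated"),
    "mean_bigram": (2, "mean"),
    "trigram": (3, "summated"),
    "quadrigram": (4, "summated"),
}


def build_table(
    items: "StimulusSet | Iterable",
    reference: Lexicon,
    measures: Sequence[str] = ("old20",),
    variant: str = "levenshtein",
    exclude_self: bool = True,
    ngram_weighting: str = "token",
) -> WordLikenessTable:
    """Compute the requested word-likeness measures for every item.

    Measures: ``old20``, ``coltheart_n`` and the n-gram shorthands
    ``initial_bigram``, ``final_bigram``, ``summated_bigram``,
    ``mean_bigram``, ``trigram``, ``quadrigram``.  Words present in the
    reference carry their lexicon frequency; non-words carry 0.
    """
    item_list = list(getattr(items, "items", items))
    rows = []
    for it in item_list:
        string = getattr(it, "string", it)
        category = getattr(it, "category", None)
        if category is None:
            category = "W" if string in reference else "PW"
        row: dict = {"string": string, "category": category}
        if string is None:  # SL: category-only item
            row["frequency"] = 0.0
            for meas in measures:
                row[meas] = np.nan
            rows.append(row)
            continue
        row["frequency"] = (
            reference.frequency(string) if string in reference else 0.0
        )
        for meas in measures:
            try:
                if meas == "old20":
                    row[meas] = old20(
                        string, reference, exclude_self=exclude_self, variant=variant
                    )
                elif meas == "coltheart_n":
                    row[meas] = coltheart_n(string, reference)
                elif meas in _NGRAM_MEASURES:
                    n, position = _NGRAM_MEASURES[meas]
                    row[meas] = ngram_score(
                        string, reference, n=n, position=position,
                        weighting=ngram_weighting,
                    )
                else:
                    raise ValueError(f"unknown measure {meas!r}")
            except ValueError as exc:
                raise ValueError(f"measure {meas!r} failed for {string!r}: {exc}") from exc
        rows.append(row)
    return WordLikenessTable(pd.DataFrame(rows), reference_name=reference.name)
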