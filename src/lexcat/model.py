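"""The lexical categorization model (LCM).

The model holds that word-sensitive left ventral occipito-temporal
cortex implements a word/non-word categorization of incoming letter
strings, and that its activation tracks the *difficulty* of that
categorization: the binary entropy

    E(x) = -p(W|x) log2 p(W|x) - p(nW|x) log2 p(nW|x)

of the conditional probability that a string with word-likeness x (its
OLD20 value) is a word.  p(W|x) is estimated from the joint pool of
words and non-words: either by exact counting within OLD20 bins (take
all strings in a bin, count the words, divide) or by a Gaussian
kernel-density ratio with empirical class priors.  Entropy is 1 bit
where words and non-words are equally likely and 0 where the
categorization is certain — reproducing the non-linear lvOT response
profile (peak activation at intermediate word-likeness).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .stimuli import StimulusSet
from .wordlikeness import WordLikenessTable

#: OLD20 is a mean of 20 integer distances, so 1/20 is its natural granularity.
DEFAULT_BIN_WIDTH = 1.0 / 20.0

WORD_CATEGORY = "W"


def entropy(p):
    """Binary entropy in bits, with the 0*log2(0) := 0 convention.

    Accepts a scalar or array of probabilities in [0, 1]; symmetric in
    p <-> 1-p, maximal (1.0) at p = 0.5, zero at certainty.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -arr * np.log2(arr) - (1 - arr) * np.log2(1 - arr)
    out = np.where((arr == 0) | (arr == 1), 0.0, out)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(out)
    return out


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, for comparison with printed values
    (Python's round() is banker's rounding)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class CategorizationCurve:
    """p(word | word-likeness) with its complement and entropy.

    ``support`` holds the occupied OLD20 bins (exact-bin estimator) or
    the observed word-likeness values (kde); ``meta`` records the
    estimator, its bin width / bandwidth, class counts and, for
    exact-bin, the per-bin string counts.
    """

    support: np.ndarray
    p_word: np.ndarray
    p_nonword: np.ndarray
    entropy_values: np.ndarray
    meta: dict = field(default_factory=dict)
    _kdes: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.p_word = np.asarray(self.p_word, dtype=float)
        self.p_nonword = np.asarray(self.p_nonword, dtype=float)
        self.entropy_values = np.asarray(self.entropy_values, dtype=float)

    def to_json(self, path=None) -> str:
        payload = {
            "support": self.support.tolist(),
            "p_word": self.p_word.tolist(),
            "p_nonword": self.p_nonword.tolist(),
            "entropy": self.entropy_values.tolist(),
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CategorizationCurve":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    payload = json.load(fh)
        return cls(
            support=np.asarray(payload["support"]),
            p_word=np.asarray(payload["p_word"]),
            p_nonword=np.asarray(payload["p_nonword"]),
            entropy_values=np.asarray(payload["entropy"]),
            meta=payload.get("meta", {}),
        )


def fit_curve(
    table: WordLikenessTable,
    estimator: str = "exact-bin",
    bin_width: float | None = None,
    bandwidth=None,
    measure: str = "old20",
    word_category: str = WORD_CATEGORY,
) -> CategorizationCurve:
    """Estimate p(word | word-likeness) from a word-likeness table.

    exact-bin
        Round each string's word-likeness to the bin grid (default width
        1/20, OLD20's granularity) and set p_word(bin) to the fraction
        of strings in the bin that are words; empty bins are absent from
        the support.
    kde
        Fit separate Gaussian kernel densities f_W and f_NW (Silverman's
        rule unless *bandwidth* given) and set
        p_word(x) = n_W f_W(x) / (n_W f_W(x) + n_NW f_NW(x)),
        i.e. a density ratio with empirical class priors.
    """
    if estimator not in ("exact-bin", "kde"):
        raise ValueError(f"unknown estimator {estimator!r}")
    data = table.data.dropna(subset=[measure])
    if data.empty:
        raise ValueError(f"table has no rows with a {measure!r} value")
    is_word = (data["category"] == word_category).to_numpy()
    if is_word.all() or not is_word.any():
        raise ValueError("curve fitting needs both word and non-word rows")
    x = data[measure].to_numpy(dtype=float)
    if estimator == "exact-bin":
        width = DEFAULT_BIN_WIDTH if bin_width is None else float(bin_width)
        # round-half-away binning keeps .5-multiples stable in float math
        bins = np.round(np.floor(x / width + 0.5) * width, 10)
        frame = pd.DataFrame({"bin": bins, "word": is_word})
        grouped = frame.groupby("bin", sort=True)["word"].agg(["sum", "count"])
        support = grouped.index.to_numpy(dtype=float)
        p_w = grouped["sum"].to_numpy(dtype=float) / grouped["count"].to_numpy()
        meta = {
            "estimator": "exact-bin",
            "bin_width": width,
            "counts": grouped["count"].astype(int).tolist(),
            "word_counts": grouped["sum"].astype(int).tolist(),
            "n_word": int(is_word.sum()),
            "n_nonword": int((~is_word).sum()),
            "measure": measure,
        }
        return CategorizationCurve(support, p_w, 1 - p_w, entropy(p_w), meta)
    # kde estimator
    xw, xn = x[is_word], x[~is_word]
    if len(xw) < 2 or len(xn) < 2:
        raise ValueError("kde estimator needs >= 2 strings per class")
    bw = bandwidth if bandwidth is not None else "silverman"
    kde_w = gaussian_kde(xw, bw_method=bw)
    kde_n = gaussian_kde(xn, bw_method=bw)
    support = np.unique(x)
    n_w, n_n = len(xw), len(xn)
    f_w = kde_w(support) * n_w
    f_n = kde_n(support) * n_n
    p_w = f_w / (f_w + f_n)
    meta = {
        "estimator": "kde",
        "bandwidth": bw if isinstance(bw, str) else float(bw),
        "n_word": n_w,
        "n_nonword": n_n,
        "measure": measure,
    }
    curve = CategorizationCurve(support, p_w, 1 - p_w, entropy(p_w), meta)
    curve._kdes = (kde_w, kde_n, n_w, n_n)
    return curve


def word_probability(curve: CategorizationCurve, x) -> float | np.ndarray:
    """p(word | word-likeness = x) from a fitted curve.

    Exact-bin: the value of the occupied bin containing x; queries in
    empty regions interpolate linearly between the flanking occupied
    bins, and queries beyond the support take the nearest occupied bin's
    value.  Kde: closed-form density-ratio evaluation at x.
    """
    if len(curve.support) == 0:
        raise ValueError("curve has not been fitted (empty support)")
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if curve.meta.get("estimator") == "kde":
        if curve._kdes is not None:
            kde_w, kde_n, n_w, n_n = curve._kdes
            f_w = kde_w(xs) * n_w
            f_n = kde_n(xs) * n_n
            out = f_w / (f_w + f_n)
        else:  # deserialized curve: fall back to interpolation on the grid
            out = np.interp(xs, curve.support, curve.p_word)
    else:
        width = curve.meta.get("bin_width", DEFAULT_BIN_WIDTH)
        snapped = np.round(np.floor(xs / width + 0.5) * width, 10)
        # np.interp handles both the interpolation between occupied bins
        # and the nearest-bin rule beyond the extremes; exact bin hits
        # land on support points and return the bin value itself.
        out = np.interp(snapped, curve.support, curve.p_word)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out[0])
    return out


def nonword_probability(curve: CategorizationCurve, x):
    """Complement query: p(non-word | word-likeness = x)."""
    p = word_probability(curve, x)
    return 1.0 - p


def categorization_uncertainty(curve: CategorizationCurve, x):
    """Entropy of the word/non-word categorization at word-likeness x."""
    return entropy(word_probability(curve, x))


@dataclass
class SimulationResult:
    """Per-item simulated activation for one model, arbitrary units.

    ``data`` columns: string, category, wordlikeness, activation.
    Raw LCM activation is entropy in [0, 1] bits; any rescaling (e.g.
    the 0..6 plotting range) is cosmetic and never enters statistics.
    """

    data: pd.DataFrame
    model: str
    provenance: dict = field(default_factory=dict)

    def activation_by_category(self, agg: str = "median") -> pd.Series:
        return self.data.groupby("category")["activation"].agg(agg)


def simulate_lcm(
    curve: CategorizationCurve,
    items: StimulusSet,
    table: WordLikenessTable,
    measure: str = "old20",
) -> SimulationResult:
    """Simulated lvOT activation: the categorization entropy of every
    item's word-likeness.  Scrambled-letter (SL) items carry no
    orthographic content and are fixed at activation 0."""
    lookup: dict[str, float] = {}
    for row in table.data.itertuples():
        if row.string is not None and not (
            isinstance(row.string, float) and np.isnan(row.string)
        ):
            lookup[row.string] = getattr(row, measure)
    records = []
    for it in items:
        if it.category == "SL":
            records.append((None, "SL", np.nan, 0.0))
            continue
        if it.string not in lookup:
            raise KeyError(f"no word-likeness table row for {it.string!r}")
        wl = lookup[it.string]
        act = entropy(word_probability(curve, wl))
        records.append((it.string, it.category, wl, act))
    data = pd.DataFrame(
        records, columns=["string", "category", "wordlikeness", "activation"]
    )
    return SimulationResult(
        data,
        model="lcm",
        provenance={
            "estimator": curve.meta.get("estimator"),
            "measure": measure,
            "table_reference": table.reference_name,
            **{k: v for k, v in items.provenance.items() if k in ("lexicon", "seed")},
        },
    )
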