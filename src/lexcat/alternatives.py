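"""Ad hoc implementations of competitor models of lvOT function.

Four verbal-descriptive accounts from the word-recognition literature,
each reduced to a transparent single-knob parameterization so that the
qualitative effect directions they predict can be simulated and scored
against the same benchmarks as the lexical categorization model:

lexicon
    Serial frequency-ordered lexicon search — activation grows with
    search depth, so rare words activate more than frequent words and
    every non-word forces an exhaustive (maximal) search.
cd (local combination detector)
    Activation grows linearly with the string's overlap with stored
    representations, operationalized as negated min-max-normalized
    OLD20.
ee (engagement and effort)
    Engagement — a decreasing logistic in OLD20 (word-unlike strings
    fail to engage the word system) — multiplied by effort, 1 minus
    normalized log2 frequency (non-words: maximal effort).
ia (interactive account)
    Predictive-coding reading of the same product: prediction
    eligibility (few top-down predictions form for consonant strings)
    times surprise (rare strings violate predictions).

ee and ia share a functional form under this parameterization and are
kept as separately named models with independent parameter blocks so
that richer forms can be dropped in per model.  All models emit
activations in [0, 1]; scrambled-letter items are 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .model import CategorizationCurve, SimulationResult, word_probability
from .stimuli import StimulusSet
from .wordlikeness import WordLikenessTable


@dataclass
class AltModelParams:
    """Shared knobs of the sigmoid-based competitor models.

    midpoint: OLD20 value of half engagement/eligibility (word-likeness
    units).  slope: logistic steepness per OLD20 unit (> 0).  scale:
    output multiplier applied after the [0,1] mapping, cosmetic only.
    """

    midpoint: float = 1.75
    slope: float = 4.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")


def params_from_curve(curve: CategorizationCurve, slope: float = 4.0) -> AltModelParams:
    """Set the sigmoid midpoint to the word/non-word crossover of a
    fitted categorization curve (the word-likeness where p(word) first
    drops through 0.5)."""
    grid = np.linspace(curve.support.min(), curve.support.max(), 512)
    p = np.asarray([word_probability(curve, g) for g in grid])
    below = np.nonzero(p <= 0.5)[0]
    midpoint = float(grid[below[0]]) if len(below) else float(grid[-1])
    return AltModelParams(midpoint=midpoint, slope=slope)


def params_from_table(
    table: WordLikenessTable, slope: float = 4.0, measure: str = "old20"
) -> AltModelParams:
    """Set the sigmoid midpoint to the orthographic-legality boundary:
    halfway between the median word-likeness of pseudowords (legal) and
    consonant strings (illegal).

    Engagement/eligibility in the E&E and IA accounts separates strings
    that look like possible words from ones that do not — a boundary
    between the legal and illegal non-words, not the word/non-word
    crossover (which sits amid the legal strings).
    """
    data = table.data
    med_pw = data.loc[data["category"] == "PW", measure].median()
    med_cs = data.loc[data["category"] == "CS", measure].median()
    if np.isnan(med_pw) or np.isnan(med_cs):
        raise ValueError("legality midpoint needs both PW and CS rows in the table")
    return AltModelParams(midpoint=float((med_pw + med_cs) / 2.0), slope=slope)


def _wordlikeness_lookup(table: WordLikenessTable, measure: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for row in table.data.itertuples():
        if isinstance(row.string, str):
            out[row.string] = getattr(row, measure)
    return out


def _normalized_log_frequency(items: StimulusSet) -> np.ndarray:
    """log2(1 + per-million frequency), min-max scaled within the set.
    Non-words sit at frequency 0, hence at the scale's bottom."""
    freqs = np.array([it.frequency for it in items], dtype=float)
    logf = np.log2(1.0 + freqs)
    span = logf.max() - logf.min()
    if span == 0:
        return np.zeros_like(logf)
    return (logf - logf.min()) / span


def _frame(items: StimulusSet, wl: list, act: np.ndarray, model: str) -> SimulationResult:
    data = pd.DataFrame(
        {
            "string": [it.string for it in items],
            "category": [it.category for it in items],
            "wordlikeness": wl,
            "activation": act,
        }
    )
    return SimulationResult(data, model=model, provenance=dict(items.provenance))


def simulate_lexicon_model(items: StimulusSet, lexicon: Lexicon) -> SimulationResult:
    """Frequency-ordered serial search: a word's activation is its
    normalized search rank (most frequent word = rank 1 = minimal
    activation); any string not found forces an exhaustive search and
    maximal activation 1.0."""
    order = np.argsort(-lexicon.frequencies, kind="stable")
    rank = {lexicon.words[i]: r + 1 for r, i in enumerate(order)}
    n = len(lexicon)
    acts, wls = [], []
    for it in items:
        wls.append(np.nan)
        if it.category == "SL":
            acts.append(0.0)
        elif it.string in rank:
            acts.append(rank[it.string] / n)
        else:
            acts.append(1.0)
    return _frame(items, wls, np.asarray(acts), "lexicon")


def simulate_cd_model(
    items: StimulusSet, table: WordLikenessTable, measure: str = "old20"
) -> SimulationResult:
    """Local combination detector: activation is linear in word
    similarity, taken as negated min-max-normalized OLD20 (the most
    word-like item in the set maps to 1)."""
    lookup = _wordlikeness_lookup(table, measure)
    wl = np.array(
        [lookup[it.string] if it.category != "SL" else np.nan for it in items]
    )
    finite = wl[~np.isnan(wl)]
    span = finite.max() - finite.min()
    if span == 0:
        raise ValueError("constant word-likeness column: no similarity contrast")
    sim = 1.0 - (wl - finite.min()) / span
    act = np.where(np.isnan(wl), 0.0, sim)
    return _frame(items, list(wl), act, "cd")


def _sigmoid_product(
    items: StimulusSet,
    table: WordLikenessTable,
    params: AltModelParams | None,
    model: str,
    measure: str = "old20",
) -> SimulationResult:
    if params is None:
        try:
            params = params_from_table(table, measure=measure)
        except ValueError:
            params = AltModelParams()
    lookup = _wordlikeness_lookup(table, measure)
    wl = np.array(
        [lookup[it.string] if it.category != "SL" else np.nan for it in items]
    )
    engagement = 1.0 / (1.0 + np.exp(params.slope * (wl - params.midpoint)))
    effort = 1.0 - _normalized_log_frequency(items)
    act = engagement * effort * params.scale
    act = np.where(np.isnan(wl), 0.0, act)
    return _frame(items, list(wl), act, model)


def simulate_ee_model(
    items: StimulusSet,
    table: WordLikenessTable,
    params: AltModelParams | None = None,
    measure: str = "old20",
) -> SimulationResult:
    """Engagement (decreasing logistic in OLD20) times effort (1 minus
    normalized log2 frequency; non-words at maximal effort).  With no
    explicit params the midpoint is placed at the orthographic-legality
    boundary derived from the table (see :func:`params_from_table`)."""
    return _sigmoid_product(items, table, params, "ee", measure)


def simulate_ia_model(
    items: StimulusSet,
    table: WordLikenessTable,
    params: AltModelParams | None = None,
    measure: str = "old20",
) -> SimulationResult:
    """Prediction eligibility (decreasing logistic in OLD20: consonant
    strings attract few top-down predictions) times surprise (1 minus
    normalized log2 frequency: rare strings violate predictions).
    Defaults mirror :func:`simulate_ee_model`."""
    return _sigmoid_product(items, table, params, "ia", measure)


MODELS = ("lcm", "lexicon", "cd", "ee", "ia")
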