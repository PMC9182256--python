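"""End-to-end convenience pipeline for the canonical simulation study.

The canonical conditions: a synthetic five-letter lexicon of 2,000
words, the balanced W/PW/CS stimulus set derived from it, OLD20 against
the full lexicon, an exact-bin categorization curve and the entropy
simulation.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lexicon import Lexicon, synth_lexicon
from .model import CategorizationCurve, SimulationResult, fit_curve, simulate_lcm
from .stimuli import StimulusSet, build_stimulus_set
from .wordlikeness import WordLikenessTable, build_table

CANONICAL_N_WORDS = 2000
CANONICAL_LENGTH = 5


@dataclass
class StudyRun:
    lexicon: Lexicon
    stimuli: StimulusSet
    table: WordLikenessTable
    curve: CategorizationCurve
    simulation: SimulationResult


def run_canonical_study(
    n_words: int = CANONICAL_N_WORDS,
    seed: int = 0,
    length: int = CANONICAL_LENGTH,
    estimator: str = "exact-bin",
    measures: tuple[str, ...] = ("old20",),
    letter_model: str = "ablaut-morph",
) -> StudyRun:
    """Generate lexicon and stimuli, fit the categorization curve, and
    simulate lvOT activation, all from one seed."""
    lexicon = synth_lexicon(n_words, length=length, seed=seed, letter_model=letter_model)
    stimuli = build_stimulus_set(lexicon, np.random.default_rng(seed))
    table = build_table(stimuli, lexicon, measures=measures)
    curve = fit_curve(table, estimator=estimator)
    simulation = simulate_lcm(curve, stimuli, table)
    return StudyRun(lexicon, stimuli, table, curve, simulation)
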