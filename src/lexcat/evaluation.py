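"""Benchmark contrasts, model scoring, and simulation-vs-ROI comparison.

Nine published lvOT activation effects form the benchmark registry: the
categorical contrasts PW>W, W>CS, their conjunction PW>W>CS, PH>W, the
PH=PW null, matched-PW>matched-W, the word-similarity chain
lWS<iWS<hWS=cmW, a negative log-frequency slope over words and
pseudowords, and a positive log-bigram-frequency slope.  Contrasts are
fitted as ordinary linear models over items, Bonferroni-corrected over
the family of nine, and scored qualitatively (correct / incorrect /
null against the literature's direction).

The quantitative model comparison z-transforms simulated activations
and observed percent-signal-change within each dataset and measures,
per condition contrast, |Δsim − Δobs| in units of the standard
deviation of the participant-level observed differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lexicon import Lexicon, truncate_by_frequency
from .model import (
    CategorizationCurve,
    SimulationResult,
    entropy,
    fit_curve,
    simulate_lcm,
    word_probability,
)
from .stimuli import StimulusSet, build_stimulus_set, match_groups
from .wordlikeness import WordLikenessTable, build_table

ALPHA = 0.05
FAMILY_SIZE = 9


def bonferroni(p: float, n: int = FAMILY_SIZE) -> float:
    return float(min(1.0, n * p))


# ---------------------------------------------------------------------------
# contrast registry


@dataclass(frozen=True)
class ContrastSpec:
    """One benchmark effect: what to compare and which direction the
    literature reports."""

    id: str
    kind: str  # greater | equal | conjunction | chain | slope
    description: str
    groups: tuple = ()  # (higher, lower) for greater; (a, b) for equal
    components: tuple = ()  # for conjunction/chain: member contrast ids
    predictor: str | None = None  # for slope contrasts
    slope_categories: tuple = ()
    expected_sign: int = 0  # for slope contrasts
    quadratic: bool = False


DEFAULT_REGISTRY: tuple[ContrastSpec, ...] = (
    ContrastSpec("pw_gt_w", "greater", "pseudowords > words", groups=("PW", "W")),
    ContrastSpec("w_gt_cs", "greater", "words > consonant strings", groups=("W", "CS")),
    ContrastSpec(
        "pw_gt_w_gt_cs",
        "conjunction",
        "pseudowords > words > consonant strings",
        components=("pw_gt_w", "w_gt_cs"),
    ),
    ContrastSpec("ph_gt_w", "greater", "pseudohomophones > words", groups=("PH", "W")),
    ContrastSpec("ph_eq_pw", "equal", "pseudohomophones = pseudowords", groups=("PH", "PW")),
    ContrastSpec(
        "matched_pw_gt_w",
        "greater",
        "matched pseudowords > matched words",
        groups=("mPW", "mW"),
    ),
    ContrastSpec(
        "word_similarity",
        "chain",
        "low < intermediate < high word similarity = matched words",
        components=("ws_i_gt_l", "ws_h_gt_i", "ws_h_eq_w"),
    ),
    ContrastSpec(
        "freq_slope",
        "slope",
        "activation decreases with log word frequency (words + pseudowords)",
        predictor="log_frequency",
        slope_categories=("W", "PW"),
        expected_sign=-1,
    ),
    ContrastSpec(
        "bigram_slope",
        "slope",
        "activation increases with log bigram frequency",
        predictor="log_bigram",
        slope_categories=("W", "PW", "CS"),
        expected_sign=+1,
        quadratic=True,
    ),
)

# sub-contrasts backing the word-similarity chain
_CHAIN_MEMBERS: dict[str, ContrastSpec] = {
    "ws_i_gt_l": ContrastSpec("ws_i_gt_l", "greater", "iWS > lWS", groups=("iWS", "lWS")),
    "ws_h_gt_i": ContrastSpec("ws_h_gt_i", "greater", "hWS > iWS", groups=("hWS", "iWS")),
    "ws_h_eq_w": ContrastSpec("ws_h_eq_w", "equal", "hWS = cmW", groups=("hWS", "cmW")),
}


@dataclass
class ContrastResult:
    id: str
    description: str
    expected: str
    estimated_direction: int  # sign of the estimated effect
    statistic: float
    p_value: float
    p_adjusted: float
    verdict: str  # correct | incorrect | null
    extras: dict = field(default_factory=dict)


def _directional_verdict(direction_ok: bool, p_adj: float) -> str:
    if p_adj < ALPHA:
        return "correct" if direction_ok else "incorrect"
    return "null"


def _effect_stats(model, scale: float) -> tuple[float, float, float, int]:
    """Coefficient, t, p and sign of an OLS effect, treating numerically
    zero effects (float noise on degenerate data) as exact nulls."""
    coef = float(model.params[1])
    tiny = 1e-10 * max(1.0, scale)
    if abs(coef) < tiny or model.bse[1] == 0 or np.isnan(model.bse[1]):
        return 0.0, 0.0, 1.0, 0
    return coef, float(model.tvalues[1]), float(model.pvalues[1]), int(np.sign(coef))


def _two_group(frame: pd.DataFrame, hi: str, lo: str) -> tuple[float, float, float, int]:
    sub = frame[frame["category"].isin([hi, lo])]
    y = sub["activation"].to_numpy(dtype=float)
    x = (sub["category"] == hi).to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    diff, t, p, sign = _effect_stats(model, float(np.abs(y).max(initial=0.0)))
    return diff, t, p, sign


def _evaluate_single(
    spec: ContrastSpec, frame: pd.DataFrame, n_family: int
) -> ContrastResult | None:
    if spec.kind in ("greater", "equal"):
        present = set(frame["category"])
        missing = [g for g in spec.groups if g not in present]
        if missing:
            warnings.warn(f"contrast {spec.id!r} skipped: missing condition(s) {missing}")
            return None
        hi, lo = spec.groups
        diff, t, p_raw, sign = _two_group(frame, hi, lo)
        p_adj = bonferroni(p_raw, n_family)
        if spec.kind == "greater":
            verdict = _directional_verdict(sign > 0, p_adj)
            expected = f"{hi} > {lo}"
        else:
            verdict = "correct" if p_adj >= ALPHA else "incorrect"
            expected = f"{hi} = {lo}"
        return ContrastResult(
            spec.id, spec.description, expected, sign, t, p_raw, p_adj, verdict,
            extras={"mean_difference": diff},
        )
    if spec.kind == "slope":
        if spec.predictor not in frame.columns:
            warnings.warn(
                f"contrast {spec.id!r} skipped: predictor {spec.predictor!r} unavailable"
            )
            return None
        sub = frame[frame["category"].isin(spec.slope_categories)].dropna(
            subset=[spec.predictor, "activation"]
        )
        if sub.empty:
            warnings.warn(f"contrast {spec.id!r} skipped: no usable rows")
            return None
        x = sub[spec.predictor].to_numpy(dtype=float)
        y = sub["activation"].to_numpy(dtype=float)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        slope, t, p, sign = _effect_stats(model, float(np.abs(y).max(initial=0.0)))
        p_adj = bonferroni(p, n_family)
        verdict = _directional_verdict(sign == spec.expected_sign, p_adj)
        extras = {"slope": slope}
        if spec.quadratic:
            X2 = sm.add_constant(np.column_stack([x, x**2]))
            quad = sm.OLS(y, X2).fit()
            extras["quadratic_coef"] = float(quad.params[2])
            extras["quadratic_p"] = float(quad.pvalues[2])
        return ContrastResult(
            spec.id, spec.description,
            f"slope {'<' if spec.expected_sign < 0 else '>'} 0",
            sign, t, p, p_adj, verdict, extras,
        )
    raise ValueError(f"unhandled contrast kind {spec.kind!r}")


def _combine(spec: ContrastSpec, members: list[ContrastResult]) -> ContrastResult:
    verdicts = [m.verdict for m in members]
    if all(v == "correct" for v in verdicts):
        verdict = "correct"
    elif "incorrect" in verdicts:
        verdict = "incorrect"
    else:
        verdict = "null"
    return ContrastResult(
        spec.id, spec.description,
        " & ".join(m.expected for m in members),
        0,
        float("nan"), float("nan"), float("nan"),
        verdict,
        extras={"components": {m.id: m.verdict for m in members}},
    )


def run_benchmark_contrasts(
    sim: SimulationResult,
    registry: tuple[ContrastSpec, ...] = DEFAULT_REGISTRY,
    table: WordLikenessTable | None = None,
    n_family: int | None = None,
) -> list[ContrastResult]:
    """Fit every registry contrast on a simulation.

    Categorical contrasts are linear models of activation on condition;
    slope contrasts regress activation on the log2-transformed
    predictor (``log_frequency`` over words and pseudowords with
    pseudoword frequency at 0, ``log_bigram`` additionally over
    consonant strings, plus a documented quadratic refit).  A contrast
    whose conditions or predictor are absent is skipped with a warning,
    never silently passed.  *n_family* defaults to the registry size
    (nine) for the Bonferroni correction.
    """
    n_family = n_family if n_family is not None else len(registry)
    frame = sim.data.copy()
    if table is not None:
        aux = table.data[["string"]].copy()
        if "frequency" in table.data.columns:
            aux["log_frequency"] = np.log2(1.0 + table.data["frequency"].astype(float))
        if "summated_bigram" in table.data.columns:
            aux["log_bigram"] = np.log2(
                1.0 + table.data["summated_bigram"].astype(float)
            )
        frame = frame.merge(aux.drop_duplicates("string"), on="string", how="left")
    elif "frequency" in frame.columns and "log_frequency" not in frame.columns:
        frame["log_frequency"] = np.log2(1.0 + frame["frequency"].astype(float))

    results: list[ContrastResult] = []
    singles: dict[str, ContrastResult] = {}
    compound = [s for s in registry if s.kind in ("conjunction", "chain")]
    needed_members = {cid for s in compound for cid in s.components}
    for spec in registry:
        if spec.kind in ("conjunction", "chain"):
            continue
        res = _evaluate_single(spec, frame, n_family)
        if res is not None:
            singles[spec.id] = res
            results.append(res)
    for cid in needed_members:
        if cid in singles or cid not in _CHAIN_MEMBERS:
            continue
        res = _evaluate_single(_CHAIN_MEMBERS[cid], frame, n_family)
        if res is not None:
            singles[cid] = res
    for spec in compound:
        members = [singles[c] for c in spec.components if c in singles]
        if len(members) != len(spec.components):
            missing = [c for c in spec.components if c not in singles]
            warnings.warn(f"contrast {spec.id!r} skipped: missing component(s) {missing}")
            continue
        results.append(_combine(spec, members))
    order = {s.id: i for i, s in enumerate(registry)}
    results.sort(key=lambda r: order.get(r.id, len(order)))
    return results


def augment_with_matched_conditions(
    sim: SimulationResult,
    table: WordLikenessTable,
    n_pairs: int | None = None,
    match_features: tuple[str, ...] = (
        "coltheart_n",
        "initial_bigram",
        "final_bigram",
        "summated_bigram",
    ),
    ws_features_high: tuple[str, ...] = ("quadrigram",),
    ws_features_intermediate: tuple[str, ...] = ("summated_bigram",),
) -> SimulationResult:
    """Derive the matched benchmark conditions from a W/PW/CS simulation.

    Appends relabeled copies of items: ``mW``/``mPW`` — words and
    pseudowords paired on the lexical covariates; ``cmW``/``hWS``/
    ``iWS``/``lWS`` — comparison words, non-words matched to them on
    quadrigram frequency (high word similarity), non-words matched on
    bigram frequency (intermediate), and the unmatched consonant strings
    (low).  Items lacking a required feature column abort with an error.
    """
    data = sim.data.merge(
        table.data.drop(columns=["category", "frequency"], errors="ignore"),
        on="string", how="left",
    )
    words = data[data["category"] == "W"]
    pws = data[data["category"] == "PW"]
    css = data[data["category"] == "CS"]
    extra_frames = []

    feats = [f for f in match_features if f in data.columns]
    if not feats:
        raise ValueError("no matching features present in the word-likeness table")
    n = n_pairs or min(len(words), len(pws))
    pairs, _ = match_groups(words, pws, feats, n)
    mw = words.loc[pairs["index_a"]].copy()
    mpw = pws.loc[pairs["index_b"]].copy()
    mw["category"] = "mW"
    mpw["category"] = "mPW"
    extra_frames += [mw, mpw]

    nonwords = pd.concat([pws, css])
    hi_feats = [f for f in ws_features_high if f in data.columns]
    mid_feats = [f for f in ws_features_intermediate if f in data.columns]
    if hi_feats and mid_feats and len(words) and len(nonwords):
        n_ws = min(len(words), len(nonwords))
        hi_pairs, _ = match_groups(words, nonwords, hi_feats, n_ws)
        cmw = words.loc[hi_pairs["index_a"]].copy()
        hws = nonwords.loc[hi_pairs["index_b"]].copy()
        remaining = nonwords.drop(index=hi_pairs["index_b"])
        if len(remaining):
            mid_pairs, _ = match_groups(
                words, remaining, mid_feats, min(len(words), len(remaining))
            )
            iws = remaining.loc[mid_pairs["index_b"]].copy()
        else:
            iws = remaining.copy()
        lws = css[~css.index.isin(hi_pairs["index_b"])].copy()
        cmw["category"] = "cmW"
        hws["category"] = "hWS"
        iws["category"] = "iWS"
        lws["category"] = "lWS"
        extra_frames += [cmw, hws, iws, lws]

    out = pd.concat([sim.data] + [f[sim.data.columns] for f in extra_frames],
                    ignore_index=True)
    return SimulationResult(out, model=sim.model,
                            provenance={**sim.provenance, "matched_conditions": True})


def score_models(results_by_model: dict[str, list[ContrastResult]]) -> pd.DataFrame:
    """Qualitative scores per model: ``score_correct`` counts correct
    verdicts; ``score_penalized`` subtracts incorrect ones (null
    verdicts carry no penalty)."""
    rows = []
    for model, results in results_by_model.items():
        n_correct = sum(r.verdict == "correct" for r in results)
        n_incorrect = sum(r.verdict == "incorrect" for r in results)
        n_null = sum(r.verdict == "null" for r in results)
        rows.append(
            {
                "model": model,
                "score_correct": n_correct,
                "score_penalized": n_correct - n_incorrect,
                "n_incorrect": n_incorrect,
                "n_null": n_null,
                "n_evaluated": len(results),
            }
        )
    return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# observed-data comparison


@dataclass
class ObservedROI:
    """Per-participant, per-condition percent signal change."""

    data: pd.DataFrame  # rows: participants; columns: conditions

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise ValueError("observed ROI data needs >= 2 participants")
        if self.data.columns.duplicated().any():
            raise ValueError("condition labels must be unique")

    @classmethod
    def from_csv(cls, path) -> "ObservedROI":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame)


@dataclass
class ComparisonReport:
    """Per-contrast deviation between simulated and observed condition
    differences, in SDs of the observed participant-level differences."""

    data: pd.DataFrame
    model: str

    @property
    def total_deviation(self) -> float:
        return float(self.data["deviation"].sum())


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-transform constant data")
    return (values - values.mean()) / sd


def compare_to_observed(
    sim: SimulationResult,
    roi: ObservedROI,
    contrasts: list[tuple[str, str]],
    per_participant: bool = False,
) -> ComparisonReport:
    """Standardized deviation between simulated and observed contrasts.

    Simulated activations are z-transformed across items and observed
    values across all participant-by-condition cells (or within each
    participant with ``per_participant=True``), putting both on a common
    scale.  For each (a, b) condition pair the deviation is
    ``|Δsim − Δobs| / SD_obs`` where Δ are the condition-mean
    differences and SD_obs is the standard deviation of the
    participant-level observed difference scores.
    """
    sim_conditions = set(sim.data["category"])
    needed = {c for pair in contrasts for c in pair}
    missing_sim = sorted(needed - sim_conditions)
    missing_obs = sorted(needed - set(roi.data.columns))
    if missing_sim or missing_obs:
        raise ValueError(
            f"condition label mismatch: missing in simulation {missing_sim}, "
            f"missing in observed data {missing_obs}"
        )
    zsim = sim.data.copy()
    zsim["z"] = _zscore(zsim["activation"].to_numpy(dtype=float))
    obs = roi.data.astype(float)
    if per_participant:
        zobs = obs.sub(obs.mean(axis=1), axis=0).div(obs.std(axis=1, ddof=1), axis=0)
    else:
        flat = _zscore(obs.to_numpy().ravel())
        zobs = pd.DataFrame(
            flat.reshape(obs.shape), index=obs.index, columns=obs.columns
        )
    rows = []
    for a, b in contrasts:
        d_sim = (
            zsim.loc[zsim["category"] == a, "z"].mean()
            - zsim.loc[zsim["category"] == b, "z"].mean()
        )
        diffs = zobs[a] - zobs[b]
        d_obs = float(diffs.mean())
        sd_obs = float(diffs.std(ddof=1))
        if sd_obs == 0:
            raise ValueError(f"observed contrast {a}-{b} has zero variance")
        rows.append(
            {
                "contrast": f"{a}-{b}",
                "delta_sim": float(d_sim),
                "delta_obs": d_obs,
                "sd_obs": sd_obs,
                "deviation": abs(d_sim - d_obs) / sd_obs,
            }
        )
    return ComparisonReport(pd.DataFrame(rows), model=sim.model)


def model_correlation_matrix(sims: list[SimulationResult]) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-item activations.  A model
    with zero variance gets NaN in its row/column rather than a silent
    zero."""
    if not sims:
        raise ValueError("need at least one simulation")
    n = len(sims[0].data)
    cols = {}
    for s in sims:
        if len(s.data) != n:
            raise ValueError("all simulations must cover the same item list")
        cols[s.model] = s.data["activation"].to_numpy(dtype=float)
    return pd.DataFrame(cols).corr()


# ---------------------------------------------------------------------------
# robustness


def subset_stability(
    table: WordLikenessTable,
    proportions: list[float],
    n_draws: int = 20,
    seed: int = 0,
    estimator: str = "exact-bin",
    measure: str = "old20",
) -> pd.DataFrame:
    """Internal stability of the categorization curve under item
    subsampling.

    For each proportion, *n_draws* category-stratified random subsets of
    the table are drawn, the curve refitted on the subset, and the
    resulting per-item entropies (for *all* items) correlated with the
    full-set entropies.  Proportion 1.0 reuses every item and yields
    r = 1 exactly.  Draws whose subset cannot support a fit are skipped
    with a warning and reported in ``n_valid``.
    """
    for p in proportions:
        if not (0 < p <= 1):
            raise ValueError("proportions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    data = table.data.dropna(subset=[measure]).reset_index(drop=True)
    full_curve = fit_curve(table, estimator=estimator, measure=measure)
    x_all = data[measure].to_numpy(dtype=float)
    full_entropy = np.array([entropy(word_probability(full_curve, v)) for v in x_all])
    rows = []
    for prop in proportions:
        rs = []
        for _ in range(n_draws):
            if prop == 1.0:
                idx = np.arange(len(data))
            else:
                parts = []
                for _, grp in data.groupby("category"):
                    k = max(1, int(round(prop * len(grp))))
                    parts.append(rng.choice(grp.index.to_numpy(), size=k, replace=False))
                idx = np.concatenate(parts)
            subset = WordLikenessTable(data.loc[idx], table.reference_name)
            try:
                curve = fit_curve(subset, estimator=estimator, measure=measure)
            except ValueError as exc:
                warnings.warn(f"subset draw skipped at proportion {prop}: {exc}")
                continue
            ent = np.array([entropy(word_probability(curve, v)) for v in x_all])
            if np.std(ent) == 0 or np.std(full_entropy) == 0:
                warnings.warn(f"subset draw skipped at proportion {prop}: constant entropy")
                continue
            rs.append(float(np.corrcoef(ent, full_entropy)[0, 1]))
        rows.append(
            {
                "proportion": prop,
                "mean_r": float(np.mean(rs)) if rs else float("nan"),
                "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
                "n_valid": len(rs),
            }
        )
    return pd.DataFrame(rows)


def lexicon_size_sweep(
    full_lexicon: Lexicon,
    sizes: list[int],
    seed: int = 0,
    estimator: str = "exact-bin",
) -> pd.DataFrame:
    """Effect of lexicon size on the simulated category pattern.

    For each size the lexicon is truncated to its most frequent words,
    the stimulus set rebuilt, word-likeness recomputed against the
    truncated reference, the curve refitted and the simulation rerun.
    Reports the median activation per category and whether the
    PW > W > CS ordering holds.  Sizes below 21 cannot support OLD20
    with self-exclusion and are skipped with a warning.
    """
    rows = []
    for size in sizes:
        if size < 21:
            warnings.warn(f"size {size} skipped: OLD20 needs >= 21 reference words")
            continue
        if size > len(full_lexicon):
            warnings.warn(f"size {size} skipped: exceeds lexicon size {len(full_lexicon)}")
            continue
        lex = truncate_by_frequency(full_lexicon, size)
        stim = build_stimulus_set(lex, np.random.default_rng(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_table(stim, lex, measures=("old20",))
        curve = fit_curve(table, estimator=estimator)
        sim = simulate_lcm(curve, stim, table)
        med = sim.activation_by_category("median")
        rows.append(
            {
                "size": size,
                "median_W": float(med.get("W", float("nan"))),
                "median_PW": float(med.get("PW", float("nan"))),
                "median_CS": float(med.get("CS", float("nan"))),
                "ordering_holds": bool(
                    med.get("PW", np.nan) > med.get("W", np.nan) > med.get("CS", np.nan)
                ),
            }
        )
    return pd.DataFrame(rows)
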