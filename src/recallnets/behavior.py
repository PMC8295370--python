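"""Recall-organization scoring: temporal and category clustering factors.

In free recall, the order in which studied items are reported carries
information about the retrieval cue.  The *temporal factor* scores each
recall transition by the percentile rank of its absolute serial-position lag
among the lags to every item that is still available for recall, with
smaller lags ranking higher; the *category factor* applies the same
machinery to a 0/1 same/different-category distance.  Under uniformly random
transitions both factors have expectation 0.5, provided ties share credit
(average rank).

Because the task presents same-category items in consecutive pairs, the list
structure itself biases these scores away from 0.5 for some strategies
(purely serial recall inflates the category factor; within-category recall
deflates the temporal factor).  ``structure_matched_z`` standardizes
observed scores against nulls drawn on the same lists with matched recall
counts, isolating clustering beyond what the structure induces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import fdr_bh

__all__ = [
    "RecallSequence",
    "FactorScores",
    "temporal_factor",
    "category_factor",
    "structure_matched_z",
    "recall_summary",
]


@dataclass
class RecallSequence:
    """Ordered correct recalls for one list.

    study_positions : 1-based serial positions in output order (no repeats).
    vocalization_onsets_ms : onset of each vocal response, strictly
        increasing; optional (None when only order is known).
    """

    study_positions: list[int]
    list_id: int = 0
    vocalization_onsets_ms: list[float] | None = None

    def __post_init__(self) -> None:
        pos = list(self.study_positions)
        if len(set(pos)) != len(pos):
            raise ValueError("recall sequence repeats a study position")
        if any(p < 1 for p in pos):
            raise ValueError("study positions are 1-based")
        if self.vocalization_onsets_ms is not None:
            on = self.vocalization_onsets_ms
            if len(on) != len(pos):
                raise ValueError("one vocalization onset per recall required")
            if any(b <= a for a, b in zip(on, on[1:])):
                raise ValueError("vocalization onsets must strictly increase")


@dataclass
class FactorScores:
    """Clustering factor scores for one subject, optionally standardized."""

    temporal: float
    categorical: float
    temporal_z: float = field(default=np.nan)
    categorical_z: float = field(default=np.nan)


def _percentile_rank_mean(distances_per_transition) -> float:
    """Mean percentile rank over transitions; NaN if none is scorable.

    Each element is ``(actual_distance, candidate_distances)`` where the
    candidate pool includes the recalled item itself.  Rank credit:
    (n_farther + 0.5 * n_tied_others) / (n_candidates - 1), so a uniformly
    random choice scores 0.5 in expectation and ties share credit.
    """
    scores = []
    for actual, cands in distances_per_transition:
        cands = np.asarray(cands, dtype=float)
        n = cands.size
        if n < 2:
            continue  # percentile rank undefined with a single candidate
        farther = int(np.sum(cands > actual))
        tied_others = int(np.sum(cands == actual)) - 1
        scores.append((farther + 0.5 * tied_others) / (n - 1))
    return float(np.mean(scores)) if scores else np.nan


def _transition_distances(sequence: RecallSequence, list_length: int,
                          distance) -> list:
    """Collect (actual, candidates) distance pools for each transition.

    Candidates at a transition are every serial position not yet recalled
    (the just-recalled item included in none of the pools)."""
    recalled: set[int] = set()
    out = []
    pos = sequence.study_positions
    for cur, nxt in zip(pos, pos[1:]):
        recalled.add(cur)
        candidates = [p for p in range(1, list_length + 1)
                      if p not in recalled]
        out.append((distance(cur, nxt), [distance(cur, k) for k in candidates]))
    return out


def temporal_factor(list_length: int, sequence: RecallSequence) -> float:
    """Temporal clustering factor of one recall sequence (NaN if undefined).

    Per transition i -> j, the actual |lag| = |pos_j - pos_i| is ranked
    against the |lag| to every not-yet-recalled position; smaller lags rank
    higher, ties receive average rank.  The factor is the mean rank over
    transitions mapped to [0, 1]; 0.5 is chance.
    """
    _check(list_length, sequence)
    trans = _transition_distances(sequence, list_length,
                                  lambda a, b: abs(a - b))
    return _percentile_rank_mean(trans)


def category_factor(categories_by_position, sequence: RecallSequence) -> float:
    """Category clustering factor: same machinery with 0/1 category distance.

    categories_by_position : sequence of category labels indexed 0..L-1 for
        serial positions 1..L.
    """
    cats = list(categories_by_position)
    _check(len(cats), sequence)

    def dist(a: int, b: int) -> float:
        return 0.0 if cats[a - 1] == cats[b - 1] else 1.0

    trans = _transition_distances(sequence, len(cats), dist)
    return _percentile_rank_mean(trans)


def _check(list_length: int, sequence: RecallSequence) -> None:
    if any(p > list_length for p in sequence.study_positions):
        raise ValueError("study position exceeds list length")


def _mean_factors(sequences, structures) -> tuple[float, float]:
    t = [temporal_factor(len(s.categories), r) for r, s in zip(sequences, structures)]
    c = [category_factor(s.categories, r) for r, s in zip(sequences, structures)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(t)), float(np.nanmean(c))


def structure_matched_z(
    sequences,
    structures,
    n_null: int = 1000,
    seed: int | None = None,
) -> FactorScores:
    """Standardize factor scores against structure-matched random recalls.

    For each list the null draws a uniform random no-repeat sequence of the
    same length as the observed recall, on the same list structure; the null
    statistic is the across-list mean factor.  z = (observed - null mean) /
    null sd, computed for both factors over ``n_null`` replicates.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    rng = np.random.default_rng(seed)
    obs_t, obs_c = _mean_factors(sequences, structures)

    null_t = np.empty(n_null)
    null_c = np.empty(n_null)
    lengths = [len(r.study_positions) for r in sequences]
    for i in range(n_null):
        null_seqs = [
            RecallSequence(list(rng.choice(len(s.categories), size=k, replace=False) + 1))
            for k, s in zip(lengths, structures)
        ]
        null_t[i], null_c[i] = _mean_factors(null_seqs, structures)

    def z(obs: float, null: np.ndarray) -> float:
        sd = null.std(ddof=1)
        if sd == 0:
            warnings.warn("zero null variance; z undefined", stacklevel=2)
            return np.nan
        return (obs - null.mean()) / sd

    return FactorScores(
        temporal=obs_t, categorical=obs_c,
        temporal_z=z(obs_t, null_t), categorical_z=z(obs_c, null_c),
    )


def recall_summary(events: pd.DataFrame, q: float = 0.05) -> dict:
    """Group recall-probability summaries with per-position/category tests.

    ``events`` must contain columns subject, list, position, category,
    recalled (bool) with one row per studied item.  Returns per-position and
    per-category recall probabilities (group mean ± SEM), plus two-sided
    one-sample t-tests of each subject-level probability against that
    subject's overall recall rate, BH-FDR corrected.
    """
    required = {"subject", "list", "position", "category", "recalled"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")

    overall = events.groupby("subject")["recalled"].mean()

    def table(by: str) -> pd.DataFrame:
        per_subj = (
            events.groupby(["subject", by])["recalled"].mean().unstack(by)
        )
        diffs = per_subj.sub(overall, axis=0)
        rows = []
        for level in per_subj.columns:
            d = diffs[level].dropna().to_numpy()
            if d.size >= 2 and np.ptp(d) > 0:
                t, p = sps.ttest_1samp(d, 0.0)
            else:
                t, p = np.nan, 1.0
            rows.append({
                by: level,
                "probability": per_subj[level].mean(),
                "sem": per_subj[level].sem(),
                "t": t,
                "p": p,
            })
        out = pd.DataFrame(rows)
        out["significant"] = fdr_bh(out["p"].to_numpy(), q=q)
        return out

    return {
        "overall_recall": float(overall.mean()),
        "by_position": table("position"),
        "by_category": table("category"),
    }
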