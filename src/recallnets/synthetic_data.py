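"""Generative model of the categorized free-recall experiment.

Produces, with known ground truth, every input the analysis pipeline
consumes: a word pool with category-structured embeddings, study lists built
from 3 categories x 4 items presented in same-category pairs, recall
sequences with tunable temporal/semantic clustering, and spectral-power
tensors in which semantic-category signal is carried by anterior temporal
(AT) electrodes and serial-position signal by posterior medial (PM)
electrodes, on top of network-shared trial-to-trial fluctuations and
independent Gaussian noise.  Pre-recall epochs reinstate a scaled copy of
the recalled item's encoding pattern, which is the effect the reinstatement
analysis is built to detect.

The generative model is deliberately linear in the same stimulus attributes
the ridge encoding models regress on, so parameter recovery is exact in the
zero-noise limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import RecallSequence

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ListStructure",
    "generate_word_pool",
    "generate_list_structure",
    "simulate_recall",
    "make_ground_truth",
    "simulate_power",
    "simulate_subject",
    "write_events_tsv",
    "write_electrodes_tsv",
    "write_embeddings_tsv",
]

WORD_MS = 1600          # stimulus duration
ISI_MS = 875            # mean inter-stimulus interval
RECALL_GAP_MS = 2500    # default spacing between vocalization onsets
N_RETRIEVAL_SAMPLES = 40  # -900..-100 ms at 20 ms steps


@dataclass
class SimulationConfig:
    """Study-design and signal parameters for one simulated experiment.

    Defaults mirror the task: 25-list sessions of 12-item lists drawn from a
    25-category pool, 3 categories x 4 items per list with same-category
    items in consecutive pairs, 300-dimensional word embeddings.  Effect
    sizes are unitless gains on z-scored power; ``reinstatement_gain`` in
    [0, 1] scales how much of the encoding pattern reappears pre-recall.
    """

    n_subjects: int = 1
    n_sessions: int = 1
    n_lists: int = 25
    list_length: int = 12
    n_categories_pool: int = 25
    categories_per_list: int = 3
    items_per_category: int = 4
    words_per_category: int = 12
    embedding_dim: int = 300
    n_electrodes_pm: int = 5
    n_electrodes_at: int = 5
    n_electrodes_other: int = 0
    n_frequencies: int = 8
    effect_size_category: float = 1.0
    effect_size_position: float = 1.0
    network_shared_sd: float = 0.5
    noise_sd: float = 1.0
    reinstatement_gain: float = 0.5
    clustering_temporal: float = 1.0
    clustering_semantic: float = 1.0
    stop_prob: float = 0.15
    embedding_within_sd: float = 0.3
    allow_adjacent_pairs: bool = False
    min_vocalization_gap_ms: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.categories_per_list * self.items_per_category != self.list_length:
            raise ValueError(
                "categories_per_list * items_per_category must equal list_length"
            )
        if self.items_per_category % 2 != 0:
            raise ValueError("items_per_category must be even (paired presentation)")
        for name in ("effect_size_category", "effect_size_position",
                     "network_shared_sd", "noise_sd", "clustering_temporal",
                     "clustering_semantic", "embedding_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.stop_prob <= 1.0:
            raise ValueError("stop_prob must lie in [0, 1]")
        if not 0.0 <= self.reinstatement_gain <= 1.0:
            raise ValueError("reinstatement_gain must lie in [0, 1]")
        if min(self.n_subjects, self.n_sessions, self.n_lists,
               self.embedding_dim, self.n_frequencies) < 1:
            raise ValueError("counts must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.n_electrodes_pm + self.n_electrodes_at + self.n_electrodes_other

    @property
    def network_labels(self) -> np.ndarray:
        return np.array(
            ["PM"] * self.n_electrodes_pm
            + ["AT"] * self.n_electrodes_at
            + ["none"] * self.n_electrodes_other
        )


@dataclass
class ListStructure:
    """Study order of one list: items and categories per serial position."""

    items: list[int]          # word ids, one per position
    categories: list[int]     # category ids, one per position
    list_id: int = 0

    def __post_init__(self) -> None:
        if len(self.items) != len(self.categories):
            raise ValueError("items and categories must align")
        if len(set(self.items)) != len(self.items):
            raise ValueError("items repeat within a list")


@dataclass
class GroundTruth:
    """Generative parameters the analysis should be able to recover.

    category_loadings : (electrodes, frequencies) gain of the semantic
        signal per neural feature; nonzero only on AT rows when the config
        requests network-specific effects.
    position_loadings : (positions, electrodes, frequencies) pattern evoked
        by each serial position; nonzero only on PM rows.
    embedding_projection : (frequencies, embedding_dim) fixed random rows
        mapping a word vector to a per-frequency scalar drive.
    """

    category_loadings: np.ndarray
    position_loadings: np.ndarray
    embedding_projection: np.ndarray
    network_labels: np.ndarray
    true_embeddings: np.ndarray
    word_categories: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload))


def generate_word_pool(
    n_categories: int,
    words_per_category: int,
    dim: int = 300,
    within_sd: float = 0.3,
    seed: int | np.random.Generator | None = None,
):
    """Category-structured word embeddings: centroid + isotropic jitter.

    Returns ``(embeddings, categories)`` with embeddings of shape
    (n_categories * words_per_category, dim) and integer category labels.
    Words of one category share a Gaussian centroid (unit scale) and differ
    by isotropic noise of scale ``within_sd``; with ``within_sd=0`` all
    words in a category collapse onto the centroid.
    """
    if n_categories < 2 or dim < 2 or words_per_category < 1:
        raise ValueError("need n_categories >= 2, dim >= 2, words_per_category >= 1")
    if within_sd < 0:
        raise ValueError("within_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_categories, dim))
    categories = np.repeat(np.arange(n_categories), words_per_category)
    jitter = rng.standard_normal((categories.size, dim)) * within_sd
    embeddings = centroids[categories] + jitter
    return embeddings, categories


def _pair_category_order(
    categories: np.ndarray,
    rng: np.random.Generator,
    allow_adjacent: bool,
) -> np.ndarray:
    """Order the 6 same-category pairs; two pairs of a category are never
    adjacent unless ``allow_adjacent`` (rejection sampling)."""
    pair_cats = np.repeat(categories, 2)  # each category contributes 2 pairs
    while True:
        order = rng.permutation(pair_cats)
        if allow_adjacent or not np.any(order[:-1] == order[1:]):
            return order


def generate_list_structure(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    word_categories: np.ndarray | None = None,
) -> list[ListStructure]:
    """Build one session of study lists with paired-category structure.

    Each list draws ``categories_per_list`` categories with enough unused
    words left in the pool, splits each category's 4 items into 2 pairs,
    and arranges the 6 pairs so that positions (1,2), (3,4), ... are
    same-category; words never repeat within the session.
    """
    rng = np.random.default_rng(seed)
    if word_categories is None:
        word_categories = np.repeat(
            np.arange(config.n_categories_pool), config.words_per_category
        )
    pool: dict[int, list[int]] = {}
    for c in range(config.n_categories_pool):
        pool[c] = list(np.flatnonzero(word_categories == c))
    # each category supports floor(words / items_per_list) list appearances;
    # scheduling the categories with the most remaining uses first (random
    # tie-break) keeps the exactly-sized default pool feasible
    uses = {c: len(w) // config.items_per_category for c, w in pool.items()}
    if sum(uses.values()) < config.n_lists * config.categories_per_list:
        raise ValueError("word pool too small for the requested session")

    lists = []
    for li in range(config.n_lists):
        eligible = [c for c in pool if uses[c] >= 1]
        if len(eligible) < config.categories_per_list:
            raise ValueError("word pool too small for the requested session")
        rng.shuffle(eligible)
        eligible.sort(key=lambda c: -uses[c])
        cats = np.array(eligible[: config.categories_per_list])
        for c in cats:
            uses[c] -= 1
        # draw 4 unused words per category, split into two pairs
        pairs: dict[int, list[list[int]]] = {}
        for c in cats:
            take = rng.choice(pool[c], size=config.items_per_category, replace=False)
            for w in take:
                pool[c].remove(w)
            half = config.items_per_category // 2
            pairs[c] = [list(take[:half]), list(take[half:])]
        order = _pair_category_order(cats, rng, config.allow_adjacent_pairs)
        items: list[int] = []
        categories: list[int] = []
        for c in order:
            pair = pairs[c].pop(0)
            rng.shuffle(pair)
            items.extend(int(w) for w in pair)
            categories.extend([int(c)] * 2)
        lists.append(ListStructure(items=items, categories=categories, list_id=li))
    return lists


def simulate_recall(
    structure: ListStructure,
    clustering_temporal: float = 0.0,
    clustering_semantic: float = 0.0,
    stop_prob: float = 0.15,
    seed: int | np.random.Generator | None = None,
    min_gap_ms: float = 2000.0,
) -> RecallSequence:
    """Sample one recall sequence with exponential-in-distance transitions.

    The first recall is uniform over the list.  Each subsequent recall is
    drawn over not-yet-recalled positions with weight
    exp(-theta_T * |lag|) * exp(-theta_S * d_cat), where d_cat is 0 for the
    same category as the just-recalled item and 1 otherwise.  After every
    recall the process stops with probability ``stop_prob`` (so
    ``stop_prob=1`` yields exactly one recall).  Vocalization onsets are
    spaced ``>= min_gap_ms`` apart so the epochs pass the pre-recall
    screening; pass a smaller gap to generate violations deliberately.
    """
    if clustering_temporal < 0 or clustering_semantic < 0:
        raise ValueError("clustering parameters must be nonnegative")
    if not 0.0 <= stop_prob <= 1.0:
        raise ValueError("stop_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(structure.items)
    positions = np.arange(1, L + 1)
    cats = np.asarray(structure.categories)

    recalled = [int(rng.integers(1, L + 1))]
    while len(recalled) < L:
        if rng.random() < stop_prob:
            break
        cur = recalled[-1]
        avail = np.array([p for p in positions if p not in recalled])
        lag = np.abs(avail - cur)
        dcat = (cats[avail - 1] != cats[cur - 1]).astype(float)
        w = np.exp(-clustering_temporal * lag) * np.exp(-clustering_semantic * dcat)
        w /= w.sum()
        recalled.append(int(rng.choice(avail, p=w)))

    onsets = list(np.arange(len(recalled)) * max(RECALL_GAP_MS, min_gap_ms)
                  + rng.uniform(500, 1500))
    if min_gap_ms < 2000.0:  # deliberately violate the screening gap
        onsets = list(np.arange(len(recalled)) * min_gap_ms + 500.0)
    return RecallSequence(
        study_positions=recalled,
        list_id=structure.list_id,
        vocalization_onsets_ms=[float(o) for o in onsets],
    )


def make_ground_truth(
    config: SimulationConfig,
    embeddings: np.ndarray,
    word_categories: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> GroundTruth:
    """Draw the fixed generative parameters for one simulated subject.

    Category loadings are standard-normal on AT electrodes and zero
    elsewhere; per-position patterns are standard-normal on PM electrodes
    and zero elsewhere.  The embedding projection is a fixed random matrix
    with unit-norm rows, one per frequency, through which a word vector
    drives the AT features.
    """
    rng = np.random.default_rng(seed)
    E, F, L = config.n_electrodes, config.n_frequencies, config.list_length
    labels = config.network_labels

    cat_load = np.zeros((E, F))
    at = labels == "AT"
    cat_load[at] = rng.standard_normal((at.sum(), F))

    pos_load = np.zeros((L, E, F))
    pm = labels == "PM"
    pos_load[:, pm, :] = rng.standard_normal((L, pm.sum(), F))

    proj = rng.standard_normal((F, config.embedding_dim))
    proj /= np.linalg.norm(proj, axis=1, keepdims=True)

    return GroundTruth(
        category_loadings=cat_load,
        position_loadings=pos_load,
        embedding_projection=proj,
        network_labels=labels,
        true_embeddings=embeddings,
        word_categories=word_categories,
    )


def encoding_signal(
    structure: ListStructure,
    truth: GroundTruth,
    config: SimulationConfig,
) -> np.ndarray:
    """Noise-free encoding pattern per event: (list_length, E, F).

    value[e, f] = gain_cat * category_loadings[e, f] * (proj_f . x_word)
                + gain_pos * position_loadings[pos, e, f]
    with x_word the item's true embedding (the category signal is therefore
    linear in the same features the content model regresses on).
    """
    drives = truth.true_embeddings[structure.items] @ truth.embedding_projection.T
    cat_part = (config.effect_size_category
                * truth.category_loadings[None, :, :]
                * drives[:, None, :])
    pos_part = config.effect_size_position * truth.position_loadings
    return cat_part + pos_part


def _network_noise(
    rng: np.random.Generator,
    labels: np.ndarray,
    n_events: int,
    shared_sd: float,
    noise_sd: float,
    n_freq: int,
    extra_shape: tuple = (),
) -> np.ndarray:
    """Shared per-network fluctuation (one draw per event per network,
    added to every feature of that network) plus independent noise."""
    E = labels.size
    shape = (n_events, E, n_freq) + extra_shape
    out = rng.standard_normal(shape) * noise_sd
    if shared_sd > 0:
        for net in np.unique(labels):
            mask = labels == net
            shared = rng.standard_normal((n_events,) + extra_shape) * shared_sd
            out[:, mask, :] += shared[:, None, None] if not extra_shape \
                else shared[:, None, None, :]
    return out


def simulate_power(
    structures: list[ListStructure],
    recalls: list[RecallSequence],
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    retrieval_gain_profile: np.ndarray | None = None,
):
    """Generate encoding and retrieval power tensors for one session.

    Returns ``(encoding, retrieval, retrieval_events)``:

    encoding : (n_events, E, F) z-scale power per studied item.
    retrieval : (n_recalls, E, F, 40) pre-vocalization samples; each time
        sample carries ``reinstatement_gain`` times the recalled item's
        *noise-free* encoding pattern plus fresh shared and independent
        noise.  ``retrieval_gain_profile`` (length 40) optionally modulates
        the gain across the window, e.g. a ramp.
    retrieval_events : DataFrame (list, output_position, study_position,
        item, category, onset_ms) aligned with the retrieval tensor rows.
    """
    if truth.category_loadings.shape != (config.n_electrodes, config.n_frequencies):
        raise ValueError("ground-truth loadings do not match config dimensions")
    rng = np.random.default_rng(seed)
    labels = truth.network_labels

    signals = [encoding_signal(s, truth, config) for s in structures]
    enc_signal = np.concatenate(signals, axis=0)
    n_enc = enc_signal.shape[0]
    encoding = enc_signal + _network_noise(
        rng, labels, n_enc, config.network_shared_sd, config.noise_sd,
        config.n_frequencies,
    )

    if retrieval_gain_profile is None:
        gain = np.full(N_RETRIEVAL_SAMPLES, config.reinstatement_gain)
    else:
        gain = np.asarray(retrieval_gain_profile, dtype=float)
        if gain.shape != (N_RETRIEVAL_SAMPLES,):
            raise ValueError("retrieval_gain_profile must have length 40")

    rows = []
    patterns = []
    for s, r, sig in zip(structures, recalls, signals):
        onsets = r.vocalization_onsets_ms or [np.nan] * len(r.study_positions)
        for out_i, (p, on) in enumerate(zip(r.study_positions, onsets)):
            rows.append({
                "list": s.list_id, "output_position": out_i,
                "study_position": p, "item": s.items[p - 1],
                "category": s.categories[p - 1], "onset_ms": on,
            })
            patterns.append(sig[p - 1])
    retrieval_events = pd.DataFrame(
        rows, columns=["list", "output_position", "study_position",
                       "item", "category", "onset_ms"])
    n_rec = len(patterns)
    base = np.stack(patterns) if n_rec else np.zeros(
        (0, config.n_electrodes, config.n_frequencies))
    retrieval = base[:, :, :, None] * gain[None, None, None, :]
    retrieval += _network_noise(
        rng, labels, n_rec, config.network_shared_sd, config.noise_sd,
        config.n_frequencies, extra_shape=(N_RETRIEVAL_SAMPLES,),
    )
    return encoding, retrieval, retrieval_events


@dataclass
class SimulatedSubject:
    """Everything the pipeline needs for one simulated subject."""

    config: SimulationConfig
    truth: GroundTruth
    structures: list[ListStructure]        # across sessions, list_id unique
    recalls: list[RecallSequence]
    sessions: np.ndarray                   # session id per list
    encoding: np.ndarray                   # (events, E, F)
    retrieval: np.ndarray                  # (recalls, E, F, 40)
    events: pd.DataFrame                   # encoding events table
    retrieval_events: pd.DataFrame
    electrodes: pd.DataFrame

    @property
    def encoding_labels(self) -> pd.DataFrame:
        return self.events


def _electrode_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Electrode coordinates for the distance-matched connectivity bootstrap.

    Each network is multi-regional (posterior medial: retrosplenial,
    parahippocampal, posterior parietal; anterior temporal: temporal pole,
    perirhinal, inferior frontal), so within- and between-network pair
    distances overlap as they do in real coverage, which is what makes
    distance matching feasible."""
    subcenters = {
        # retrosplenial/posterior cingulate, parahippocampal, posterior parietal
        "PM": np.array([[-5.0, -55.0, 25.0],
                        [-25.0, -40.0, -15.0],
                        [-40.0, -65.0, 40.0]]),
        # temporal pole, perirhinal (abuts parahippocampal), inferior angular
        # gyrus (abuts posterior parietal) -- the cross-network adjacencies
        # that make distance matching both necessary and feasible
        "AT": np.array([[-35.0, 10.0, -30.0],
                        [-25.0, -25.0, -20.0],
                        [-45.0, -60.0, 30.0]]),
        "none": np.array([[30.0, -20.0, 50.0]]),
    }
    rows = []
    for i, net in enumerate(config.network_labels):
        centers = subcenters[net]
        xyz = centers[rng.integers(len(centers))] + rng.standard_normal(3) * 8.0
        rows.append({"id": f"E{i:03d}", "x_mm": xyz[0], "y_mm": xyz[1],
                     "z_mm": xyz[2], "network": net})
    return pd.DataFrame(rows)


def simulate_subject(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> SimulatedSubject:
    """End-to-end generation for one subject (all sessions).

    Deterministic given ``seed`` (falls back to ``config.seed``); sessions
    share the word pool and ground truth but draw fresh lists, recalls and
    noise.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    # electrodes drawn first: geometry is identical across signal/noise
    # settings at a matched seed, enabling clean parameter contrasts
    electrodes = _electrode_table(config, rng)

    embeddings, word_categories = generate_word_pool(
        config.n_categories_pool, config.words_per_category,
        config.embedding_dim, config.embedding_within_sd, rng,
    )
    truth = make_ground_truth(config, embeddings, word_categories, rng)

    structures: list[ListStructure] = []
    recalls: list[RecallSequence] = []
    sessions = []
    enc_parts, ret_parts, ret_ev_parts = [], [], []
    ev_rows = []
    for sess in range(config.n_sessions):
        sess_lists = generate_list_structure(config, rng, word_categories)
        for s in sess_lists:
            s.list_id += sess * config.n_lists
        sess_recalls = [
            simulate_recall(
                s, config.clustering_temporal, config.clustering_semantic,
                config.stop_prob, rng, config.min_vocalization_gap_ms,
            )
            for s in sess_lists
        ]
        enc, ret, ret_ev = simulate_power(sess_lists, sess_recalls, truth, config, rng)
        ret_ev.insert(0, "session", sess)
        enc_parts.append(enc)
        ret_parts.append(ret)
        ret_ev_parts.append(ret_ev)
        for s, r in zip(sess_lists, sess_recalls):
            recalled = set(r.study_positions)
            for pos in range(1, config.list_length + 1):
                onset = (pos - 1) * (WORD_MS + ISI_MS)
                ev_rows.append({
                    "session": sess, "list": s.list_id, "position": pos,
                    "item": s.items[pos - 1], "category": s.categories[pos - 1],
                    "onset_ms": onset, "recalled": pos in recalled,
                })
        structures.extend(sess_lists)
        recalls.extend(sess_recalls)
        sessions.extend([sess] * len(sess_lists))

    events = pd.DataFrame(ev_rows)
    return SimulatedSubject(
        config=config, truth=truth, structures=structures, recalls=recalls,
        sessions=np.asarray(sessions),
        encoding=np.concatenate(enc_parts, axis=0),
        retrieval=np.concatenate(ret_parts, axis=0),
        events=events,
        retrieval_events=pd.concat(ret_ev_parts, ignore_index=True),
        electrodes=electrodes,
    )


def simulate_timeseries(
    n_channels: int,
    duration_s: float,
    fs: float,
    oscillations: tuple[tuple[float, float], ...] = ((10.0, 1.0),),
    noise_sd: float = 1.0,
    line_noise_amp: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Oscillation-plus-noise multichannel voltage series.

    A minimal raw-signal mode meant solely to exercise the spectral chain
    (bipolar referencing, notch filtering, wavelet power): each channel is a
    sum of the requested (frequency Hz, amplitude) sinusoids with random
    phases, optional 60 Hz line noise, and white Gaussian noise.  Returns
    (n_channels, samples).
    """
    if noise_sd < 0 or duration_s <= 0 or fs <= 0:
        raise ValueError("invalid time-series parameters")
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration_s, 1 / fs)
    out = rng.standard_normal((n_channels, t.size)) * noise_sd
    for freq, amp in oscillations:
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        out += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    if line_noise_amp:
        out += line_noise_amp * np.sin(2 * np.pi * 60.0 * t)[None, :]
    return out


def write_events_tsv(subject: SimulatedSubject, path: str | Path,
                     subject_id: str = "S000") -> None:
    """Events table: WORD rows for study events, REC_WORD rows for recalls."""
    enc = subject.events.copy()
    enc.insert(0, "subject", subject_id)
    enc["type"] = "WORD"
    rec = subject.retrieval_events.copy()
    rec = rec.rename(columns={"study_position": "position"})
    rec.insert(0, "subject", subject_id)
    rec["type"] = "REC_WORD"
    cols = ["subject", "session", "list", "position", "item", "category",
            "onset_ms", "type"]
    pd.concat([enc[cols], rec[cols]]).to_csv(path, sep="\t", index=False)


def write_electrodes_tsv(subject: SimulatedSubject, path: str | Path) -> None:
    subject.electrodes.to_csv(path, sep="\t", index=False)


def write_embeddings_tsv(embeddings: np.ndarray, categories: np.ndarray,
                         path: str | Path) -> None:
    df = pd.DataFrame(embeddings)
    df.insert(0, "category", categories)
    df.insert(0, "word", [f"w{i:03d}" for i in range(len(categories))])
    df.to_csv(path, sep="\t", index=False)
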