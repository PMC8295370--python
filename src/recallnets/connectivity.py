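"""Within- vs. between-network coupling of trial-to-trial spectral power.

Connectivity is the Pearson correlation, across encoding events, of two
electrodes' time-averaged power at one frequency.  Because electrodes of
one network sit closer together than electrodes of different networks, and
proximity alone inflates power correlations, the within-minus-between
contrast is estimated with a distance-matched bootstrap: each replicate
samples between-network pairs, then greedily picks for each a within-network
pair of the closest unused inter-centroid distance, and averages the
correlations within each class.  Subjects whose coverage cannot support
matched samples are excluded with a logged flag.  Group inference on the
per-frequency contrast uses the sign-flip max-|t| permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import PermutationResult, sign_flip_max_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "ElectrodePair",
    "ConnectivityEstimate",
    "build_pairs",
    "trial_power_correlation",
    "distance_matched_bootstrap",
    "network_contrast_test",
]


@dataclass(frozen=True)
class ElectrodePair:
    """Unordered electrode pair with inter-centroid distance and class."""

    a: int
    b: int
    distance_mm: float
    pair_class: str   # within-PM | within-AT | between

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValueError("pair distance must be positive")
        if self.pair_class not in {"within-PM", "within-AT", "between"}:
            raise ValueError(f"unknown pair class {self.pair_class!r}")


@dataclass
class ConnectivityEstimate:
    """Distance-matched within/between correlations per frequency."""

    frequencies: np.ndarray
    within_r: dict[str, np.ndarray]     # network -> mean r per frequency
    between_r: np.ndarray
    contrast: dict[str, np.ndarray]     # network -> within - between
    n_boot: int
    n_skipped: int = 0
    excluded: bool = False


def build_pairs(electrodes: pd.DataFrame) -> list[ElectrodePair]:
    """All PM/AT electrode pairs with distances from the coordinates table.

    ``electrodes`` needs x_mm/y_mm/z_mm and network columns; rows labeled
    neither PM nor AT are ignored.
    """
    labeled = electrodes.reset_index(drop=True)
    keep = labeled["network"].isin(["PM", "AT"])
    idx = np.flatnonzero(keep.to_numpy())
    xyz = labeled[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    nets = labeled["network"].to_numpy()
    pairs = []
    for i, j in combinations(idx, 2):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if nets[i] == nets[j]:
            cls = f"within-{nets[i]}"
        else:
            cls = "between"
        pairs.append(ElectrodePair(int(i), int(j), d, cls))
    return pairs


def trial_power_correlation(
    power: np.ndarray,
    pairs: list[ElectrodePair],
    frequency_index: int,
) -> np.ndarray:
    """Pearson r across events for each pair at one frequency.

    ``power`` is (events, electrodes, frequencies) time-averaged normalized
    log power.  Pairs whose series is constant are returned as NaN and
    logged (they are dropped from matching downstream).
    """
    P = np.asarray(power, dtype=float)
    if P.shape[0] < 10:
        raise ValueError("need at least 10 encoding events")
    x = P[:, :, frequency_index]
    sd = x.std(axis=0)
    xc = (x - x.mean(axis=0))
    out = np.empty(len(pairs))
    for k, pr in enumerate(pairs):
        if sd[pr.a] == 0 or sd[pr.b] == 0:
            logger.info("constant power series for pair (%d,%d); dropped",
                        pr.a, pr.b)
            out[k] = np.nan
            continue
        out[k] = (xc[:, pr.a] @ xc[:, pr.b]) / (P.shape[0] * sd[pr.a] * sd[pr.b])
    return out


def _greedy_match(between_d: np.ndarray, within_d: np.ndarray) -> np.ndarray:
    """For each sampled between-pair distance (largest first), pick the
    unused within-pair with minimal |distance difference|; returns indices
    into within_d, one per between distance."""
    order = np.argsort(between_d)[::-1]
    available = np.ones(within_d.size, dtype=bool)
    chosen = np.empty(between_d.size, dtype=int)
    for i in order:
        cand = np.flatnonzero(available)
        j = cand[np.argmin(np.abs(within_d[cand] - between_d[i]))]
        chosen[i] = j
        available[j] = False
    return chosen


def distance_matched_bootstrap(
    power: np.ndarray,
    pairs: list[ElectrodePair],
    frequencies: np.ndarray | None = None,
    n_boot: int = 1000,
    n_sample: int | None = None,
    seed=None,
    max_mismatch_mm: float = 20.0,
) -> ConnectivityEstimate:
    """Distance-matched within-vs-between connectivity per frequency.

    Each replicate samples ``n_sample`` between-network pairs with
    replacement and matches, per network, an equal number of within-network
    pairs without replacement by greedy nearest-distance selection.  A
    replicate whose mean |distance mismatch| exceeds ``max_mismatch_mm`` for
    some network is skipped; if more than half the replicates skip, the
    subject is flagged excluded (insufficient coverage for matching).
    """
    rng = np.random.default_rng(seed)
    P = np.asarray(power, dtype=float)
    n_freq = P.shape[2]
    freqs = np.arange(n_freq) if frequencies is None else np.asarray(frequencies)

    r_by_freq = np.stack(
        [trial_power_correlation(P, pairs, f) for f in range(n_freq)])  # (F, n_pairs)
    valid = ~np.isnan(r_by_freq).any(axis=0)

    dist = np.array([p.distance_mm for p in pairs])
    cls = np.array([p.pair_class for p in pairs])
    between = np.flatnonzero((cls == "between") & valid)
    within = {net: np.flatnonzero((cls == f"within-{net}") & valid)
              for net in ("PM", "AT")}
    nets = [n for n, idx in within.items() if idx.size > 0]
    if between.size == 0 or not nets:
        raise ValueError("need both between- and within-network pairs")
    if n_sample is None:
        # half the smallest pool: leaves the greedy matcher freedom to pick
        # within-network pairs that actually resemble the sampled between
        # distances instead of being forced to use every pair
        n_sample = max(3, min(between.size,
                              *(within[n].size for n in nets)) // 2)

    sums_w = {n: np.zeros(n_freq) for n in nets}
    sums_b = np.zeros(n_freq)
    n_used = 0
    n_skipped = 0
    for _ in range(n_boot):
        bs = rng.choice(between, size=n_sample, replace=True)
        ok = True
        matched = {}
        for net in nets:
            if within[net].size < n_sample:
                ok = False
                break
            sel = _greedy_match(dist[bs], dist[within[net]])
            mismatch = np.abs(dist[within[net]][sel] - dist[bs]).mean()
            if mismatch > max_mismatch_mm:
                ok = False
                break
            matched[net] = within[net][sel]
        if not ok:
            n_skipped += 1
            continue
        sums_b += r_by_freq[:, bs].mean(axis=1)
        for net in nets:
            sums_w[net] += r_by_freq[:, matched[net]].mean(axis=1)
        n_used += 1

    excluded = n_used < n_boot / 2
    if excluded:
        logger.warning("subject excluded: %d/%d replicates failed distance "
                       "matching", n_skipped, n_boot)
    denom = max(n_used, 1)
    within_r = {n: sums_w[n] / denom for n in nets}
    between_r = sums_b / denom
    return ConnectivityEstimate(
        frequencies=freqs,
        within_r=within_r,
        between_r=between_r,
        contrast={n: within_r[n] - between_r for n in nets},
        n_boot=n_used,
        n_skipped=n_skipped,
        excluded=excluded,
    )


def network_contrast_test(
    contrasts_by_subject: np.ndarray,
    n_perm: int = 2000,
    seed=None,
) -> PermutationResult:
    """Group test of within-minus-between contrasts across frequencies.

    One-sample t per frequency with sign-flip max-|t| FWER correction
    (two-tailed); ``contrasts_by_subject`` is subjects x frequencies.
    """
    C = np.asarray(contrasts_by_subject, dtype=float)
    if C.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    return sign_flip_max_t_test(C, n_perm=n_perm, seed=seed)
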