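"""Permutation inference machinery: TFCE, sign-flip max-statistic tests, FDR.

Threshold-free cluster enhancement (TFCE) integrates, over an increasing
ladder of cluster-forming thresholds, the height of each threshold raised to
``H`` times the extent of the contiguous supra-threshold run raised to ``E``.
It rewards contiguous stretches of elevated statistics in a time series
without committing to a single cluster-forming threshold.  Family-wise error
is controlled by permutation: under the null the subject-level effects are
symmetric around zero, so randomly sign-flipping them and recording the
maximum statistic across positions builds a valid null distribution for the
maximum, and comparing each observed position against that distribution
yields FWER-corrected p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TFCEParams",
    "PermutationResult",
    "tfce",
    "tfce_permutation_test",
    "sign_flip_max_t_test",
    "fdr_bh",
]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE exponents and threshold ladder.

    H : height exponent (default 2).
    E : extent exponent (default 0.5).
    dh : threshold step; the ladder runs h0=dh, 2*dh, ... up to the series
        maximum.
    """

    H: float = 2.0
    E: float = 0.5
    dh: float = 0.01

    def __post_init__(self) -> None:
        if self.H <= 0 or self.E <= 0:
            raise ValueError("TFCE exponents H and E must be positive")
        if self.dh <= 0:
            raise ValueError("TFCE threshold step dh must be positive")


@dataclass
class PermutationResult:
    """Observed statistics with FWER-corrected permutation p-values."""

    observed: np.ndarray          # statistic per position (t series)
    enhanced: np.ndarray          # TFCE-enhanced statistic (signed) per position
    p_corrected: np.ndarray       # FWER-corrected p per position
    null_max: np.ndarray          # permutation distribution of the max statistic
    n_perm: int
    seed: int | None = None
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_corrected < 0.05


def _tfce_positive(series: np.ndarray, params: TFCEParams) -> np.ndarray:
    """Enhance the positive part of a 1-D series.

    Vectorized over the threshold ladder: builds the supra-threshold boolean
    matrix (thresholds x time), labels contiguous runs per row with a cumsum
    of run starts, and accumulates h^H * extent^E * dh via one bincount.
    """
    x = np.asarray(series, dtype=float)
    hmax = x.max(initial=0.0)
    if hmax < params.dh:
        return np.zeros_like(x)
    heights = np.arange(params.dh, hmax + params.dh / 2, params.dh)
    supra = x[None, :] >= heights[:, None]                       # (K, T)
    starts = supra.copy()
    starts[:, 1:] &= ~supra[:, :-1]
    # unique run id per (row, run); id 0 reserved for sub-threshold samples
    run_id = np.cumsum(starts.ravel()) * supra.ravel()
    lengths = np.bincount(run_id)
    extent = lengths[run_id].reshape(supra.shape)                # 0 where sub-threshold
    weights = heights ** params.H * params.dh
    enhanced = (np.where(supra, extent, 0.0) ** params.E * weights[:, None]).sum(axis=0)
    return enhanced


def tfce(series: np.ndarray, params: TFCEParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 1-D statistic series.

    Positive and negative excursions are enhanced separately (the negative
    part on the negated series) and recombined with sign, supporting
    two-sided inference.  Samples whose magnitude never exceeds the first
    threshold receive 0.

    Parameters
    ----------
    series : 1-D array of statistics (e.g. a group t series).
    params : TFCEParams, defaults H=2, E=0.5, dh=0.01.
    """
    params = params or TFCEParams()
    x = np.atleast_1d(np.asarray(series, dtype=float))
    if x.ndim != 1:
        raise ValueError("tfce expects a 1-D series")
    pos = _tfce_positive(x, params)
    neg = _tfce_positive(-x, params)
    return pos - neg


def tfce_permutation_test(
    series_by_subject: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    chance: float = 0.0,
    two_sided: bool = True,
) -> PermutationResult:
    """Group-level TFCE test of a per-subject statistic series against chance.

    The observed statistic is the TFCE-enhanced one-sample t series of
    ``series_by_subject - chance`` (subjects x time).  The null flips the
    sign of each subject's deviation series, re-enhances, and records the
    maximum |enhanced| value across positions; corrected p-values compare
    each observed position to that max distribution.

    Corrected p-values are bounded below by 1/(n_perm + 1).
    """
    params = params or TFCEParams()
    data = np.asarray(series_by_subject, dtype=float) - chance
    if data.ndim != 2:
        raise ValueError("series_by_subject must be subjects x positions")
    n_subj = data.shape[0]
    if n_subj < 2:
        raise ValueError("at least 2 subjects required")
    rng = np.random.default_rng(seed)

    def t_series(d: np.ndarray) -> np.ndarray:
        sd = d.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return d.mean(axis=0) / (sd / np.sqrt(n_subj))

    observed_t = t_series(data)
    enhanced = tfce(observed_t, params)
    stat = np.abs(enhanced) if two_sided else enhanced

    null_max = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        null_t = t_series(data * flips[:, None])
        null_e = tfce(null_t, params)
        null_max[i] = np.abs(null_e).max() if two_sided else null_e.max()

    exceed = (null_max[None, :] >= stat[:, None]).sum(axis=1)
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed=observed_t, enhanced=enhanced, p_corrected=p,
        null_max=null_max, n_perm=n_perm, seed=seed,
    )


def sign_flip_max_t_test(
    effects: np.ndarray,
    n_perm: int = 2000,
    seed: int | None = None,
) -> PermutationResult:
    """Sign-flip max-|t| permutation test over a family of positions.

    ``effects`` is subjects x positions (e.g. connectivity contrasts per
    frequency).  A one-sample t is computed per position; the null flips the
    sign of each subject's whole effect vector and records max |t| across
    positions; two-tailed FWER-corrected p per position follows.
    """
    data = np.asarray(effects, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n_subj = data.shape[0]
    if n_subj < 2:
        raise ValueError("at least 2 subjects required")
    rng = np.random.default_rng(seed)

    def t_stat(d: np.ndarray) -> np.ndarray:
        sd = d.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return d.mean(axis=0) / (sd / np.sqrt(n_subj))

    observed = t_stat(data)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    # vectorized: null t for all permutations at once
    flipped_mean = flips @ data / n_subj                          # (n_perm, P)
    sq = (data ** 2).sum(axis=0)                                  # flip-invariant
    var = (sq[None, :] - n_subj * flipped_mean ** 2) / (n_subj - 1)
    var = np.where(var <= 0, np.inf, var)
    null_t = flipped_mean / np.sqrt(var / n_subj)
    null_max = np.abs(null_t).max(axis=1)

    exceed = (null_max[None, :] >= np.abs(observed)[:, None]).sum(axis=1)
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed=observed, enhanced=observed.copy(), p_corrected=p,
        null_max=null_max, n_perm=n_perm, seed=seed,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
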