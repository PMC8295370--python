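"""Forward encoding models: nested-CV ridge fits and inverted decoding.

Two design matrices describe each studied word: a *content* design (the
300-dimensional embedding centroid of the word's semantic category) and a
*context* design (one-hot serial position within the list, one-hot list,
and one-hot session, the session block omitted for single-session
subjects).  Ridge regression maps the design to every neural feature
(electrode x frequency z-scored log power), with the penalty chosen per
neural feature by 10-fold cross-validation inside each of 5 outer folds
split over words.  Decoding inverts the fit: the model predicts a power
pattern for every class (25 categories or 12 serial positions), the
observed pattern is Pearson-correlated with each prediction, and a softmax
over the correlations yields class probabilities scored by macro
one-vs-rest AUC.

The multi-penalty ridge path is computed from a single SVD of each training
split (weights for all 50 grid penalties come from rescaling the singular
spectrum), which keeps the electrode bootstrap affordable; tests verify it
against the closed-form normal-equations solution and scikit-learn's Ridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "default_lambda_grid",
    "DesignMatrix",
    "EncodingModelFit",
    "DecodingResult",
    "build_content_design",
    "build_context_design",
    "fit_ridge_nested_cv",
    "predict_class_patterns",
    "decode",
    "auc_score",
    "decode_events",
    "bootstrap_electrode_auc",
]


def default_lambda_grid(n: int = 50) -> np.ndarray:
    """50 ridge penalties log-spaced from 1e-2 to 1e10."""
    return np.logspace(-2, 10, n)


@dataclass
class DesignMatrix:
    """Stimulus-attribute regressors for the encoding events.

    X : (events, features); kind in {"content", "context"}.
    class_features : (classes, features) the per-class feature vectors used
        to generate predicted patterns (category centroids, or one-hot
        position with list/session blocks at zero).
    class_labels : per-event integer class index aligned with
        ``class_features`` rows.
    """

    X: np.ndarray
    kind: str
    class_features: np.ndarray
    class_labels: np.ndarray
    class_ids: np.ndarray
    word_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.class_labels.shape[0]:
            raise ValueError("row count must equal event count")


@dataclass
class EncodingModelFit:
    """Per-fold ridge weights with per-neural-feature selected penalties."""

    weights: list[np.ndarray]            # per outer fold: (features, n_neural)
    selected_lambda: list[np.ndarray]    # per outer fold: (n_neural,)
    x_mean: list[np.ndarray]
    x_scale: list[np.ndarray]
    y_mean: list[np.ndarray]
    fold_of_event: np.ndarray            # outer-fold id per event
    lambda_grid: np.ndarray
    design: DesignMatrix

    @property
    def n_folds(self) -> int:
        return len(self.weights)

    def predict(self, fold: int, features: np.ndarray) -> np.ndarray:
        """Predicted neural pattern(s) for raw design-feature row(s)."""
        Z = (np.atleast_2d(features) - self.x_mean[fold]) / self.x_scale[fold]
        return Z @ self.weights[fold] + self.y_mean[fold]


@dataclass
class DecodingResult:
    """Held-out class probabilities with macro one-vs-rest AUC."""

    probabilities: np.ndarray    # (events, classes)
    labels: np.ndarray           # true class index per event
    class_ids: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = auc_score(self)


def build_content_design(events: pd.DataFrame, embeddings: np.ndarray,
                         word_categories: np.ndarray) -> DesignMatrix:
    """Category-centroid design: each event row is the mean embedding of the
    words presented from that event's category.

    ``events`` needs ``item`` and ``category`` columns; centroids average
    the embeddings of the presented words of each category.
    """
    presented = events.drop_duplicates("item")
    centroids: dict[int, np.ndarray] = {}
    for cat, grp in presented.groupby("category"):
        items = grp["item"].to_numpy()
        if np.any(items >= len(embeddings)):
            bad = items[items >= len(embeddings)][0]
            raise KeyError(f"no embedding for word id {bad}")
        centroids[cat] = embeddings[items].mean(axis=0)
    class_ids = np.array(sorted(centroids))
    lookup = {c: i for i, c in enumerate(class_ids)}
    class_features = np.stack([centroids[c] for c in class_ids])
    labels = events["category"].map(lookup).to_numpy()
    X = class_features[labels]
    return DesignMatrix(X=X, kind="content", class_features=class_features,
                        class_labels=labels, class_ids=class_ids,
                        word_ids=events["item"].to_numpy())


def build_context_design(events: pd.DataFrame,
                         list_length: int = 12) -> DesignMatrix:
    """One-hot position + list + session design (session block omitted for
    single-session subjects).  Class features are position indicators with
    the list/session blocks at zero, the reference against which per-position
    patterns are predicted."""
    pos = events["position"].to_numpy()
    if np.any((pos < 1) | (pos > list_length)):
        raise ValueError(f"serial positions must lie in [1, {list_length}]")
    lists = np.unique(events["list"])
    sessions = np.unique(events["session"]) if "session" in events else [0]
    n = len(events)

    blocks = [np.eye(list_length)[pos - 1]]
    list_block = np.zeros((n, lists.size))
    list_block[np.arange(n), np.searchsorted(lists, events["list"])] = 1.0
    blocks.append(list_block)
    if len(sessions) > 1:
        sess_block = np.zeros((n, len(sessions)))
        sess_block[np.arange(n),
                   np.searchsorted(sessions, events["session"])] = 1.0
        blocks.append(sess_block)
    X = np.hstack(blocks)

    class_features = np.zeros((list_length, X.shape[1]))
    class_features[:, :list_length] = np.eye(list_length)
    return DesignMatrix(X=X, kind="context", class_features=class_features,
                        class_labels=pos - 1,
                        class_ids=np.arange(1, list_length + 1),
                        word_ids=events["item"].to_numpy())


def _word_folds(word_ids: np.ndarray, n_folds: int,
                rng: np.random.Generator) -> np.ndarray:
    """Partition events into folds by word, so repeated presentations of one
    word never straddle a train/test boundary."""
    words = np.unique(word_ids)
    order = rng.permutation(words)
    fold_of_word = {w: i % n_folds for i, w in enumerate(order)}
    return np.array([fold_of_word[w] for w in word_ids])


def _svd_factors(X: np.ndarray, Y: np.ndarray):
    """SVD factors from which the whole ridge path is cheap to evaluate."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return s, Vt, U.T @ Y


def _ridge_weights(s: np.ndarray, Vt: np.ndarray, UtY: np.ndarray,
                   lam: float) -> np.ndarray:
    """Closed-form ridge weights (p, q) for one penalty from SVD factors:
    W = V diag(s / (s^2 + lam)) U'Y, the minimizer of ||Y - XW||^2 + lam||W||^2."""
    d = s / (s ** 2 + lam)
    return (Vt.T * d) @ UtY


def _ridge_path_sse(X_val: np.ndarray, Y_val: np.ndarray, s: np.ndarray,
                    Vt: np.ndarray, UtY: np.ndarray,
                    lambdas: np.ndarray) -> np.ndarray:
    """Held-out squared error per (penalty, response column) for the whole
    penalty grid, without materializing any weight matrix."""
    A = X_val @ Vt.T                                        # (v, r)
    D = s[None, :] / (s[None, :] ** 2 + lambdas[:, None])   # (k, r)
    pred = np.einsum("vr,kr,rq->kvq", A, D, UtY, optimize=True)
    resid = pred - Y_val[None]
    return (resid ** 2).sum(axis=1)                         # (k, q)


def _standardize(X: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (X - mean) / scale


def fit_ridge_nested_cv(
    design: DesignMatrix,
    Y: np.ndarray,
    outer_folds: int = 5,
    inner_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> EncodingModelFit:
    """Nested cross-validated ridge fit of neural features on the design.

    Outer 5-fold split over words; within each outer training set an inner
    10-fold CV evaluates every grid penalty and, per neural feature, the
    penalty with the smallest mean squared held-out error is refit in
    closed form on the full outer training split.  Design columns are
    standardized (and Y centered) on the training split only.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    X, Y = design.X, np.asarray(Y, dtype=float)
    n = X.shape[0]
    if Y.ndim == 1:
        Y = Y[:, None]
    if n != Y.shape[0]:
        raise ValueError("X and Y disagree on event count")
    if n < outer_folds:
        raise ValueError("fewer events than outer folds")
    rng = np.random.default_rng(seed)
    fold_of_event = _word_folds(design.word_ids, outer_folds, rng)

    weights, sel_lambda, xm_l, xs_l, ym_l = [], [], [], [], []
    for fold in range(outer_folds):
        train = fold_of_event != fold
        Xt, Yt = X[train], Y[train]
        xm = Xt.mean(axis=0)
        xs = Xt.std(axis=0)
        xs = np.where(xs == 0, 1.0, xs)              # all-zero-column guard
        ym = Yt.mean(axis=0)
        Zt = _standardize(Xt, xm, xs)
        Yc = Yt - ym

        # inner CV over words of the training split
        inner_words = design.word_ids[train]
        k_inner = min(inner_folds, np.unique(inner_words).size)
        inner_fold = _word_folds(inner_words, k_inner, rng)
        sse = np.zeros((lambda_grid.size, Y.shape[1]))
        for j in range(k_inner):
            tr, va = inner_fold != j, inner_fold == j
            if not va.any() or not tr.any():
                continue
            s, Vt, UtY = _svd_factors(Zt[tr], Yc[tr])
            sse += _ridge_path_sse(Zt[va], Yc[va], s, Vt, UtY, lambda_grid)
        best = sse.argmin(axis=0)                    # per neural feature

        W_full = np.empty((X.shape[1], Y.shape[1]))
        s, Vt, UtY = _svd_factors(Zt, Yc)
        for k in np.unique(best):
            cols = best == k
            W_full[:, cols] = _ridge_weights(s, Vt, UtY[:, cols],
                                             lambda_grid[k])
        weights.append(W_full)
        sel_lambda.append(lambda_grid[best])
        xm_l.append(xm)
        xs_l.append(xs)
        ym_l.append(ym)

    return EncodingModelFit(
        weights=weights, selected_lambda=sel_lambda, x_mean=xm_l,
        x_scale=xs_l, y_mean=ym_l, fold_of_event=fold_of_event,
        lambda_grid=lambda_grid, design=design,
    )


def predict_class_patterns(fit: EncodingModelFit, fold: int,
                           class_features: np.ndarray | None = None) -> np.ndarray:
    """Predicted neural pattern per class from one outer fold's weights.

    Content classes use category-centroid features; context classes use the
    position indicator with list/session blocks at zero.  Features pass
    through the fold's standardization before the linear map.
    """
    if class_features is None:
        class_features = fit.design.class_features
    class_features = np.asarray(class_features, dtype=float)
    if class_features.shape[1] != fit.design.X.shape[1]:
        raise ValueError("class feature dimension does not match design")
    return fit.predict(fold, class_features)


def decode(observed: np.ndarray, class_patterns: np.ndarray) -> np.ndarray:
    """Class probabilities for one observed pattern.

    Evidence per class is the Pearson correlation between the observed
    neural pattern and the class's predicted pattern; probabilities are the
    unit-temperature softmax of the evidence vector.  A zero-variance
    observation (or pattern) yields zero evidence for the affected classes,
    with a warning for the former.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    P = np.atleast_2d(class_patterns)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 classes to decode")
    if obs.size < 3 or P.shape[1] != obs.size:
        raise ValueError("pattern length must be >= 3 and match classes")
    o = obs - obs.mean()
    so = np.sqrt((o ** 2).sum())
    C = P - P.mean(axis=1, keepdims=True)
    sc = np.sqrt((C ** 2).sum(axis=1))
    if so == 0:
        warnings.warn("zero-variance observed pattern; uniform probabilities")
        evidence = np.zeros(P.shape[0])
    else:
        denom = np.where(sc == 0, np.inf, so * sc)
        evidence = (C @ o) / denom
    e = np.exp(evidence - evidence.max())
    return e / e.sum()


def auc_score(result: "DecodingResult | tuple") -> float:
    """Macro one-vs-rest AUC over the classes present among the labels.

    Per class, the rank-based AUC of that class's probability for positive
    vs. all other events (ties credited 0.5); classes lacking positives or
    negatives are skipped.  Returns NaN with a warning if fewer than two
    classes appear.
    """
    if isinstance(result, tuple):
        probs, labels = result
    else:
        probs, labels = result.probabilities, result.labels
    labels = np.asarray(labels)
    present = np.unique(labels)
    if present.size < 2:
        warnings.warn("single-class labels; AUC undefined")
        return np.nan
    aucs = []
    for c in present:
        y = (labels == c).astype(int)
        aucs.append(roc_auc_score(y, probs[:, c]))
    return float(np.mean(aucs))


def decode_events(fit: EncodingModelFit, Y: np.ndarray) -> DecodingResult:
    """Decode every event from its held-out fold's class patterns."""
    Y = np.asarray(Y, dtype=float)
    probs = np.empty((Y.shape[0], fit.design.class_features.shape[0]))
    patterns = [predict_class_patterns(fit, f) for f in range(fit.n_folds)]
    for i in range(Y.shape[0]):
        probs[i] = decode(Y[i], patterns[fit.fold_of_event[i]])
    return DecodingResult(probabilities=probs, labels=fit.design.class_labels,
                          class_ids=fit.design.class_ids)


def bootstrap_electrode_auc(
    power: np.ndarray,
    design: DesignMatrix,
    network_labels: np.ndarray,
    networks: tuple[str, ...] = ("PM", "AT"),
    k: int = 5,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    outer_folds: int = 5,
    inner_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
) -> dict[str, dict]:
    """Decoding AUC per network from repeated k-electrode subsamples.

    Each replicate draws ``k`` electrodes of the network without
    replacement, flattens their (electrode, frequency) features, runs the
    full nested-CV fit and held-out decoding, and records the macro AUC;
    the summary is the mean over replicates.  Networks with fewer than
    ``k`` electrodes are skipped with a log entry.  Controls for unequal
    electrode coverage across networks.
    """
    import logging

    logger = logging.getLogger(__name__)
    power = np.asarray(power, dtype=float)        # (events, electrodes, freq)
    network_labels = np.asarray(network_labels)
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for net in networks:
        idx = np.flatnonzero(network_labels == net)
        if idx.size < k:
            logger.info("network %s has %d < %d electrodes; skipped",
                        net, idx.size, k)
            continue
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            chosen = rng.choice(idx, size=k, replace=False)
            Y = power[:, chosen, :].reshape(power.shape[0], -1)
            fit = fit_ridge_nested_cv(design, Y, outer_folds, inner_folds,
                                      lambda_grid, rng)
            aucs[b] = decode_events(fit, Y).auc
        out[net] = {"auc": aucs, "mean": float(aucs.mean()),
                    "median": float(np.median(aucs))}
    return out
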