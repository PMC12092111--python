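"""Three-stage reduction of (variable, PC) features to a final main set.

Stage 1, *parallel analysis* (Horn): per variable, keep only PCs whose
eigenvalues exceed the mean eigenvalues of weighted-correlation PCAs of
matched random (standard normal) data -- same trial count, 101 samples and
the same trial weights as the real estimator.

Stage 2, *independent-feature screening* (Weiss-Indurkhya): per feature,
Welch's t on trial-mean scores between the symptomatic and control groups;
keep |t| >= 2.0 (about alpha = 0.05 two-sided).

Stage 3, *sequential forward selection*: greedy addition of features that
strictly decrease the 10-fold cross-validated misclassification rate of a
Gaussian naive Bayes classifier, repeated over many random fold draws; the
features most frequently present in the per-iteration final sets form the
main feature set (at most 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .datasets import GROUPS, InvalidInputError, N_SAMPLES
from .pca import ScoreTable, weighted_correlation_matrix

logger = logging.getLogger(__name__)

SCREENING_THRESHOLD = 2.0


class FeatureId(NamedTuple):
    """A (variable, PC) feature, e.g. ``FeatureId('theta_HIPFLEX', 1)``.

    Read as 'the first principal component of hip flexion angle'.  Being a
    tuple, it indexes :class:`~wavefeat.pca.ScoreTable` columns directly,
    and sorts lexicographically by (variable, pc).
    """

    variable: str
    pc: int

    @property
    def label(self) -> str:
        return f"{self.variable} PC{self.pc}"

    @classmethod
    def from_label(cls, label: str) -> "FeatureId":
        variable, pc = label.rsplit(" PC", 1)
        return cls(variable, int(pc))


@dataclass
class SelectionResult:
    """Outcome of the three-stage reduction for one reference limb."""

    retained_after_parallel: list[FeatureId]
    screened: pd.DataFrame  # columns: variable, pc, t; sorted by |t| desc
    selection_frequency: dict[FeatureId, int]
    main_features: list[FeatureId]
    seed: int | None
    n_iterations: int

    def screened_features(self) -> list[FeatureId]:
        return [FeatureId(v, int(p))
                for v, p in zip(self.screened["variable"], self.screened["pc"])]

    def validate_containment(self) -> None:
        main = set(self.main_features)
        screened = set(self.screened_features())
        parallel = set(self.retained_after_parallel)
        if not (main <= screened <= parallel):
            raise InvalidInputError(
                "selection stages violate main <= screened <= parallel containment")


# ---------------------------------------------------------------------------
# Stage 1: parallel analysis
# ---------------------------------------------------------------------------

def parallel_reference(n_trials: int, w: np.ndarray, n_reps: int = 100,
                       seed=None) -> np.ndarray:
    """Mean eigenvalue spectrum of weighted-correlation PCAs of random data.

    Simulates ``n_reps`` matrices of independent standard normals with the
    given trial count and weights, fits the same weighted-correlation
    estimator used on real data, and averages the descending eigenvalue
    spectra.  This is the Horn null reference; it depends only on the trial
    count and the weights, so one reference serves every variable of a
    dataset.
    """
    if n_trials < 2:
        raise InvalidInputError("parallel analysis needs >= 2 trials")
    if n_reps < 10:
        raise InvalidInputError("n_reps must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.asarray(w, dtype=float)
    acc = np.zeros(N_SAMPLES)
    for _ in range(int(n_reps)):
        X = rng.normal(size=(n_trials, N_SAMPLES))
        R = weighted_correlation_matrix(X, w)
        lam = np.linalg.eigvalsh(R)[::-1]
        acc += np.clip(lam, 0.0, None)
    return acc / n_reps


def parallel_analysis(eigenvalues: np.ndarray, n_trials: int, w: np.ndarray,
                      n_reps: int = 100, seed=None,
                      reference: np.ndarray | None = None) -> list[int]:
    """Retained 1-based PC indices for one variable under Horn's criterion.

    PC k is retained iff its observed eigenvalue is *strictly* larger than
    the mean k-th eigenvalue of the random reference.  Pass a precomputed
    ``reference`` (from :func:`parallel_reference`) to reuse one null
    spectrum across variables.
    """
    if reference is None:
        reference = parallel_reference(n_trials, w, n_reps=n_reps, seed=seed)
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    n = min(len(eigenvalues), len(reference))
    return [k + 1 for k in range(n) if eigenvalues[k] > reference[k]]


# ---------------------------------------------------------------------------
# Stage 2: Welch-t screening
# ---------------------------------------------------------------------------

def welch_t_statistics(X: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Vectorized Welch t statistic (group a minus group b) per column.

    Degenerate columns (both group variances zero) give ``+/-inf`` for
    unequal means and ``0`` for equal means.
    """
    a, b = X[is_a], X[~is_a]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InvalidInputError("both groups need >= 2 trials")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    fallback = np.where(diff == 0, 0.0,
                        np.where(diff > 0, np.inf, -np.inf))
    return np.atleast_1d(np.where(se == 0, fallback, t))


def screen_features(score_table: ScoreTable,
                    threshold: float = SCREENING_THRESHOLD) -> pd.DataFrame:
    """Welch-t screening of trial-mean scores, trial as unit of analysis.

    Returns a DataFrame (variable, pc, t, abs_t, retained) sorted by
    descending |t|; features with |t| >= ``threshold`` are retained.
    Zero-variance degeneracies yield infinite |t| and are retained with a
    logged warning.
    """
    is_sym = score_table.groups == GROUPS[0]
    X = score_table.matrix()
    keys = score_table.feature_keys()
    if X.shape[1] == 0:
        return pd.DataFrame(columns=["variable", "pc", "t", "abs_t", "retained"])
    t = welch_t_statistics(X, is_sym)
    if np.any(np.isinf(t)):
        logger.warning("degenerate zero-variance features screened with |t|=inf")
    out = pd.DataFrame({
        "variable": [k[0] for k in keys],
        "pc": [int(k[1]) for k in keys],
        "t": t,
        "abs_t": np.abs(t),
    })
    out["retained"] = out["abs_t"] >= threshold
    out = out.sort_values(["abs_t", "variable", "pc"],
                          ascending=[False, True, True], kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stage 3: naive Bayes CV and sequential forward selection
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Random stratified fold assignment (0..n_folds-1) per trial."""
    y = np.asarray(y)
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise InvalidInputError(
                f"class {cls!r} has {len(idx)} trials; need >= {n_folds} "
                "for stratified folding")
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _gnb_fold_tables(X: np.ndarray, y01: np.ndarray, fold: np.ndarray,
                     n_folds: int):
    """Per-trial Gaussian naive Bayes ingredients under held-out folds.

    Returns ``(L, logprior, majority)`` where ``L[j, f, c]`` is the
    class-c log density of trial j's feature f under the training fold
    excluding trial j's fold, ``logprior[j, c]`` the training-fold log class
    frequency, and ``majority[j]`` the training-fold majority class.
    Training-fold class variances of zero are floored at 1e-9 times the
    pooled (class-ignoring) training variance of that feature, with a
    logged warning; features constant across the whole training fold are
    treated as uninformative (unit variance).
    """
    n, d = X.shape
    L = np.empty((n, d, 2))
    logprior = np.empty((n, 2))
    majority = np.empty(n, dtype=int)
    floored = False
    for k in range(n_folds):
        test = fold == k
        train = ~test
        Xt, yt = X[train], y01[train]
        counts = np.array([(yt == 0).sum(), (yt == 1).sum()], dtype=float)
        logprior[test] = np.log(counts / counts.sum())
        majority[test] = 0 if counts[0] >= counts[1] else 1
        if d == 0:
            continue
        pooled = Xt.var(axis=0)
        means = np.empty((2, d))
        variances = np.empty((2, d))
        for c in (0, 1):
            Xc = Xt[yt == c]
            means[c] = Xc.mean(axis=0)
            variances[c] = Xc.var(axis=0)
        floor = 1e-9 * pooled
        zero = variances <= 0
        if zero.any():
            floored = True
            variances = np.maximum(variances, floor)
            variances[variances <= 0] = 1.0  # feature constant in training fold
        dx = X[test][:, None, :] - means[None, :, :]          # (m, 2, d)
        ll = -0.5 * (np.log(2 * np.pi * variances)[None]
                     + dx ** 2 / variances[None])
        L[test] = np.transpose(ll, (0, 2, 1))
    if floored:
        logger.warning(
            "zero within-class variance in a training fold; variance floored")
    return L, logprior, majority


def _encode_labels(groups: np.ndarray) -> np.ndarray:
    y01 = np.empty(len(groups), dtype=int)
    for c, g in enumerate(GROUPS):
        y01[np.asarray(groups) == g] = c
    return y01


def naive_bayes_cv_error(X: np.ndarray, groups: np.ndarray, n_folds: int = 10,
                         seed=None, fold: np.ndarray | None = None) -> float:
    """Pooled 10-fold cross-validated misclassification rate of Gaussian
    naive Bayes on the given feature columns.

    Class-conditional means/variances and class priors come from the
    training folds; folds are stratified by group.  An empty feature set
    predicts the training-fold majority class, so its error is the pooled
    minority-class fraction.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y01 = _encode_labels(np.asarray(groups))
    if fold is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        fold = stratified_folds(y01, n_folds, rng)
    L, logprior, majority = _gnb_fold_tables(X, y01, fold, n_folds)
    if X.shape[1] == 0:
        pred = majority
    else:
        pred = np.argmax(L.sum(axis=1) + logprior, axis=1)
    return float(np.mean(pred != y01))


def _greedy_path(L: np.ndarray, logprior: np.ndarray, majority: np.ndarray,
                 y01: np.ndarray, max_features: int) -> list[int]:
    """Greedy forward selection for one fixed fold assignment.

    Candidates are column indices of ``L`` (already ordered by screening
    |t| then FeatureId, so ``argmin`` tie-breaks follow that order); each
    step adds the candidate minimizing CV error, stopping when no candidate
    strictly decreases it.
    """
    n, d, _ = L.shape
    selected: list[int] = []
    available = np.ones(d, dtype=bool)
    base = logprior.copy()
    current = float(np.mean(majority != y01))
    while len(selected) < max_features and available.any():
        cand = np.flatnonzero(available)
        ll = base[:, None, :] + L[:, cand, :]          # (n, m, 2)
        pred = np.argmax(ll, axis=2)
        errors = np.mean(pred != y01[:, None], axis=0)
        j = int(np.argmin(errors))
        if errors[j] < current:
            pick = int(cand[j])
            selected.append(pick)
            available[pick] = False
            base = base + L[:, pick, :]
            current = float(errors[j])
        else:
            break
    return selected


def sequential_selection(
    score_table: ScoreTable,
    screened: pd.DataFrame,
    *,
    retained_after_parallel: Sequence[FeatureId] | None = None,
    max_features: int = 10,
    n_iterations: int = 1000,
    n_folds: int = 10,
    seed=None,
) -> SelectionResult:
    """Repeated greedy forward selection over random stratified fold draws.

    Each iteration draws fresh folds, runs greedy selection to a final set,
    and increments the selection counter of every feature in that set.
    The main features are the ``max_features`` highest-count features
    (count > 0), ties broken by larger screening |t| then lexicographic
    FeatureId.  Deterministic given ``seed``.
    """
    scr = screened
    if "retained" in getattr(screened, "columns", ()):
        scr = screened.loc[screened["retained"].astype(bool)]
    if len(scr) == 0:
        raise InvalidInputError("no screened features to select from")
    scr = scr.sort_values(["abs_t", "variable", "pc"],
                          ascending=[False, True, True], kind="mergesort")
    features = [FeatureId(v, int(p))
                for v, p in zip(scr["variable"], scr["pc"])]
    abs_t = {f: float(a) for f, a in zip(features, scr["abs_t"])}
    X = score_table.matrix(features)
    y01 = _encode_labels(score_table.groups)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts: dict[FeatureId, int] = {f: 0 for f in features}
    for _ in range(int(n_iterations)):
        fold = stratified_folds(y01, n_folds, rng)
        L, logprior, majority = _gnb_fold_tables(X, y01, fold, n_folds)
        for j in _greedy_path(L, logprior, majority, y01, max_features):
            counts[features[j]] += 1

    ranked = sorted(
        (f for f in features if counts[f] > 0),
        key=lambda f: (-counts[f], -abs_t[f], f))
    main = ranked[:max_features]
    result = SelectionResult(
        retained_after_parallel=list(retained_after_parallel)
        if retained_after_parallel is not None else list(features),
        screened=scr.reset_index(drop=True),
        selection_frequency=counts,
        main_features=main,
        seed=seed if isinstance(seed, (int, type(None))) else None,
        n_iterations=int(n_iterations),
    )
    result.validate_containment()
    return result
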