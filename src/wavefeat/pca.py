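"""Per-variable weighted-correlation PCA over trials x time.

Each biomechanical variable is analysed independently as an
(n_trials x 101) matrix.  Trials are standardized sample-wise with
*weighted* means and SDs, and the principal components are the unit
eigenvectors of the weighted correlation matrix

    R(t, t') = sum_j w_j z_j(t) z_j(t'),    z_j(t) = (x_j(t) - mu(t)) / sigma(t),

with weights summing to one.  A PC's *score* for a trial is stored as the
time-average of the per-sample products z_j(t) c_k(t), i.e. the classical
orthogonal projection divided by 101; the weighted mean of trial scores is
exactly zero for every PC.  Eigenvector signs follow a fixed convention
(largest-magnitude coefficient positive, earliest sample on ties) so output
is deterministic across linear-algebra backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import InvalidInputError, VARIABLES, WaveformDataset


class DegenerateVariableError(InvalidInputError):
    """A time sample with zero weighted variance: correlations are undefined."""


class UndefinedCurveError(InvalidInputError):
    """Squared-correlation curve requested for a zero-variance PC."""


def weighted_moments(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean and SD curves of a trials x time matrix.

    ``mu(t) = sum_j w_j x_j(t)`` and ``sigma(t)^2 = sum_j w_j (x_j(t) - mu(t))^2``
    (weights-sum-to-one variance; the normalization constant cancels in the
    correlation matrix).  Raises :class:`DegenerateVariableError` naming the
    first offending sample if any sigma(t) is zero.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("need a 2-D matrix with >= 2 trials")
    if w.shape != (X.shape[0],):
        raise InvalidInputError("weights must align with trials")
    if abs(w.sum() - 1.0) > 1e-9:
        raise InvalidInputError("weights must sum to 1")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("non-finite values in data matrix")
    mu = w @ X
    var = w @ (X - mu) ** 2
    if np.any(var <= 0):
        t_bad = int(np.argmax(var <= 0))
        raise DegenerateVariableError(
            f"zero weighted variance at time sample {t_bad}")
    return mu, np.sqrt(var)


def _fix_signs(coefficients: np.ndarray) -> np.ndarray:
    """Flip eigenvectors so the largest-|coefficient| entry is positive.

    ``np.argmax`` returns the earliest index on exact ties, which is the
    tie-break rule.
    """
    C = coefficients.copy()
    for k in range(C.shape[1]):
        j = int(np.argmax(np.abs(C[:, k])))
        if C[j, k] < 0:
            C[:, k] = -C[:, k]
    return C


@dataclass
class VariablePCModel:
    """Weighted-correlation PCA result for one biomechanical variable.

    ``coefficients[:, k]`` is the unit eigenvector c_{k+1}(t); eigenvalues
    are sorted descending and sum to 101 (the trace of a correlation
    matrix).  ``explained_fraction[k] = eigenvalue[k] / 101``.
    """

    variable: str
    mu: np.ndarray
    sigma: np.ndarray
    eigenvalues: np.ndarray
    coefficients: np.ndarray  # (101, n_pcs), column k = c_{k+1}
    n_trials: int
    weights_digest: str = ""

    @property
    def n_pcs(self) -> int:
        return self.coefficients.shape[1]

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mu.shape[0]:
            raise InvalidInputError("data length does not match the model")
        return (X - self.mu) / self.sigma

    def coefficient(self, pc: int) -> np.ndarray:
        """Coefficient vector c_k(t) for 1-based PC index ``pc``."""
        if not (1 <= pc <= self.n_pcs):
            raise InvalidInputError(f"PC index {pc} out of range")
        return self.coefficients[:, pc - 1]

    def squared_correlation(self, pc: int) -> np.ndarray:
        """Closed-form squared-correlation curve r^2_k(t) = lambda_k c_k(t)^2.

        The squared weighted Pearson correlation between the original data
        at sample t and the PC-k trial scores; values clipped into [0, 1]
        against floating-point excess.
        """
        lam = self.eigenvalues[pc - 1]
        if lam <= 0:
            raise UndefinedCurveError(
                f"PC {pc} has zero eigenvalue; its curve is undefined")
        return np.clip(lam * self.coefficient(pc) ** 2, 0.0, 1.0)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "variable": self.variable,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "coefficients": self.coefficients.tolist(),
            "n_trials": self.n_trials,
            "weights_digest": self.weights_digest,
            "sign_convention": "largest-|coefficient| positive, earliest sample on ties",
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "VariablePCModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            variable=payload["variable"],
            mu=np.asarray(payload["mu"]),
            sigma=np.asarray(payload["sigma"]),
            eigenvalues=np.asarray(payload["eigenvalues"]),
            coefficients=np.asarray(payload["coefficients"]),
            n_trials=int(payload["n_trials"]),
            weights_digest=payload.get("weights_digest", ""),
        )


def weighted_correlation_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    mu, sigma = weighted_moments(X, w)
    Z = (X - mu) / sigma
    R = (Z * w[:, None]).T @ Z
    return 0.5 * (R + R.T)  # enforce exact symmetry for eigh


def fit_variable_pca(X: np.ndarray, w: np.ndarray, *,
                     variable: str = "", weights_digest: str = "") -> VariablePCModel:
    """Fit the weighted-correlation PCA of one variable's trials x time matrix."""
    mu, sigma = weighted_moments(X, w)
    R = weighted_correlation_matrix(X, w)
    lam, vecs = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vecs = _fix_signs(vecs[:, order])
    return VariablePCModel(
        variable=variable, mu=mu, sigma=sigma, eigenvalues=lam,
        coefficients=vecs, n_trials=X.shape[0], weights_digest=weights_digest)


def score_trials(X: np.ndarray, model: VariablePCModel) -> np.ndarray:
    """Trial-mean PC scores: row j, column k is (1/101) z_j . c_{k+1}.

    The per-sample score of trial j for PC k at time t is
    z_j(t) c_k(t); averaging over the 101 samples gives the standard
    orthogonal projection scaled by 1/101.  The weighted mean over trials
    is zero for every PC.
    """
    Z = model.standardize(X)
    return Z @ model.coefficients / Z.shape[1]


def squared_correlation_curve(model: VariablePCModel, pc: int,
                              X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Empirical squared weighted Pearson correlation between each time
    sample of the original data and the PC-``pc`` trial scores.

    Agrees with the closed form ``lambda_k c_k(t)^2`` (see
    :meth:`VariablePCModel.squared_correlation`); provided separately so the
    identity can be verified on data.
    """
    if model.eigenvalues[pc - 1] <= 0:
        raise UndefinedCurveError(f"PC {pc} has zero eigenvalue")
    w = np.asarray(w, dtype=float)
    u = score_trials(X, model)[:, pc - 1]
    u_mean = w @ u
    du = u - u_mean
    var_u = w @ du ** 2
    mu = w @ X
    dX = X - mu
    cov = (w * du) @ dX           # per-sample weighted covariance
    var_x = w @ dX ** 2
    r2 = cov ** 2 / (var_x * var_u)
    return np.clip(r2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Per-trial mean PC scores for every retained (variable, PC) feature.

    ``meta`` has one row per trial (participant, trial, group, weight);
    ``scores`` is a DataFrame aligned with ``meta`` whose columns are a
    (variable, pc) MultiIndex with 1-based PC indices.  This table is the
    substrate of all screening, selection and inference.
    """

    meta: pd.DataFrame
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.scores):
            raise InvalidInputError("meta and scores must align")

    @property
    def n_trials(self) -> int:
        return len(self.meta)

    @property
    def groups(self) -> np.ndarray:
        return self.meta["group"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.meta["weight"].to_numpy()

    def feature_keys(self) -> list[tuple[str, int]]:
        return list(self.scores.columns)

    def feature(self, key: tuple[str, int]) -> np.ndarray:
        """Score vector of one (variable, pc) feature across all trials."""
        return self.scores[tuple(key)].to_numpy()

    def matrix(self, keys: Sequence[tuple[str, int]] | None = None) -> np.ndarray:
        if keys is None:
            return self.scores.to_numpy()
        return self.scores[[tuple(k) for k in keys]].to_numpy()

    def restrict(self, keys: Sequence[tuple[str, int]]) -> "ScoreTable":
        return ScoreTable(self.meta, self.scores[[tuple(k) for k in keys]])


def build_score_table(
    dataset: WaveformDataset,
    models: Mapping[str, VariablePCModel],
    retained: Mapping[str, Sequence[int]] | None = None,
) -> ScoreTable:
    """Score every trial on every (retained) PC of every fitted variable."""
    meta = dataset.meta[["participant", "trial", "group"]].copy()
    meta["weight"] = dataset.weights
    columns, blocks = [], []
    for v in VARIABLES:
        if v not in models:
            continue
        model = models[v]
        S = score_trials(dataset.variable_matrix(v), model)
        pcs = list(retained[v]) if retained is not None else list(
            range(1, model.n_pcs + 1))
        for pc in pcs:
            columns.append((v, int(pc)))
            blocks.append(S[:, pc - 1])
    scores = pd.DataFrame(
        np.column_stack(blocks) if blocks else np.empty((len(meta), 0)),
        columns=pd.MultiIndex.from_tuples(columns, names=["variable", "pc"])
        if columns else pd.MultiIndex.from_arrays([[], []], names=["variable", "pc"]),
    )
    return ScoreTable(meta.reset_index(drop=True), scores)
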