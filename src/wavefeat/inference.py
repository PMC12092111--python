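"""Final-feature inference, associated features, and the descriptive
pointwise waveform comparison.

Inference on the main features uses Welch's t-test on trial-mean PC scores
at alpha = 0.001 with Hedges' g effect sizes (pooled-SD standardized mean
difference with the small-sample correction J = 1 - 3/(4N - 9)).  The
*trial* is the default unit of analysis, mirroring the pooled 193/107
trial design; participant-level aggregation is available because trial
pooling pseudo-replicates within participants.

*Associated features* are post-parallel-analysis PCs correlating moderately
(0.5 <= |rho| < 0.7) or strongly (|rho| >= 0.7) with a main feature at
alpha = 0.05; they are flagged significant when their own group |t| >= 2.

The pointwise waveform comparison is a deliberately simple per-sample
two-sample t-test at a Bonferroni-corrected alpha (0.05/16 = 0.003125).
It is a *pointwise surrogate* for random-field-theory SPM: it shares the
descriptive role but performs no cluster-level inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GROUPS, InvalidInputError, VARIABLES, WaveformDataset
from .pca import ScoreTable
from .selection import SCREENING_THRESHOLD, FeatureId, welch_t_statistics

logger = logging.getLogger(__name__)

FINAL_ALPHA = 0.001
BONFERRONI_ALPHA = 0.05 / 16  # 0.003125, sixteen non-independent variables
ASSOCIATION_MODERATE = 0.5
ASSOCIATION_STRONG = 0.7


class UndefinedEffectError(InvalidInputError):
    """Hedges g requested with both group SDs zero."""


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float


def welch_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int,
                       ci: float = 0.95) -> WelchResult:
    """Welch's t-test from group summary statistics.

    Welch-Satterthwaite degrees of freedom; two-sided p; the confidence
    interval is ``diff +/- t_crit(df) * SE`` with
    ``SE = sqrt(s_a^2/n_a + s_b^2/n_b)``.
    """
    if n_a < 2 or n_b < 2:
        raise InvalidInputError("each sample needs >= 2 values")
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    se = np.sqrt(va + vb)
    diff = mean_a - mean_b
    if se == 0:
        t = 0.0 if diff == 0 else np.sign(diff) * np.inf
        p = 1.0 if diff == 0 else 0.0
        return WelchResult(float(t), float("nan"), p, diff, diff, diff)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    t = diff / se
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.5 + ci / 2, df))
    return WelchResult(float(t), float(df), p, float(diff),
                       float(diff - tcrit * se), float(diff + tcrit * se))


def welch_test(a: Sequence[float], b: Sequence[float],
               ci: float = 0.95) -> WelchResult:
    """Welch's t-test between two samples (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each sample needs >= 2 values")
    return welch_from_summary(a.mean(), a.std(ddof=1), a.size,
                              b.mean(), b.std(ddof=1), b.size, ci=ci)


def hedges_g(mean_a: float, sd_a: float, n_a: int,
             mean_b: float, sd_b: float, n_b: int) -> float:
    """Hedges' g: bias-corrected pooled-SD standardized mean difference.

    ``g = J * (mean_a - mean_b) / s_pooled`` with
    ``s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2))``
    and ``J = 1 - 3 / (4 (n_a + n_b) - 9)``.
    """
    if n_a < 2 or n_b < 2:
        raise InvalidInputError("each sample needs >= 2 values")
    if sd_a < 0 or sd_b < 0:
        raise InvalidInputError("SDs must be >= 0")
    if sd_a == 0 and sd_b == 0:
        raise UndefinedEffectError("both group SDs are zero; g is undefined")
    s_pooled = np.sqrt(((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2)
                       / (n_a + n_b - 2))
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return float(j * (mean_a - mean_b) / s_pooled)


def _per_participant_scores(score_table: ScoreTable,
                            values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a trial-level score vector to participant means."""
    df = pd.DataFrame({
        "participant": score_table.meta["participant"],
        "group": score_table.meta["group"],
        "value": values,
    })
    agg = df.groupby(["participant", "group"], sort=False)["value"].mean()
    groups = np.array([g for _, g in agg.index])
    return agg.to_numpy(), groups


def final_feature_table(score_table: ScoreTable,
                        main_features: Sequence[FeatureId],
                        alpha: float = FINAL_ALPHA,
                        unit: str = "trial") -> pd.DataFrame:
    """Group inference for each main feature, one row per feature.

    Columns: group means/SDs/counts of trial-mean scores, mean difference
    (symptomatic minus control) with 95% CI, Welch t/df/p, Hedges g, and a
    significance flag at ``alpha``.  Ordered by variable then PC.  ``unit``
    selects the unit of analysis: ``"trial"`` (default, pooled trials) or
    ``"participant"`` (participant-mean scores).
    """
    if unit not in ("trial", "participant"):
        raise InvalidInputError(f"unknown unit {unit!r}")
    order = {v: i for i, v in enumerate(VARIABLES)}
    feats = sorted(set(main_features), key=lambda f: (order[f.variable], f.pc))
    rows = []
    for fid in feats:
        values = score_table.feature(fid)
        groups = score_table.groups
        if unit == "participant":
            values, groups = _per_participant_scores(score_table, values)
        a = values[groups == GROUPS[0]]
        b = values[groups == GROUPS[1]]
        res = welch_test(a, b)
        g = hedges_g(a.mean(), a.std(ddof=1), a.size,
                     b.mean(), b.std(ddof=1), b.size)
        rows.append({
            "variable": fid.variable, "pc": fid.pc, "feature": fid.label,
            "mean_sym": a.mean(), "sd_sym": a.std(ddof=1), "n_sym": a.size,
            "mean_con": b.mean(), "sd_con": b.std(ddof=1), "n_con": b.size,
            "mean_diff": res.mean_diff, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "t": res.t, "df": res.df, "p": res.p,
            "g": g, "significant": res.p < alpha,
        })
    return pd.DataFrame(rows, columns=[
        "variable", "pc", "feature", "mean_sym", "sd_sym", "n_sym",
        "mean_con", "sd_con", "n_con", "mean_diff", "ci_low", "ci_high",
        "t", "df", "p", "g", "significant"])


def correlation_band(rho: float) -> str | None:
    """Hinkle-style band: moderate for 0.5 <= |rho| < 0.7, strong for >= 0.7."""
    if abs(rho) >= ASSOCIATION_STRONG:
        return "strong"
    if abs(rho) >= ASSOCIATION_MODERATE:
        return "moderate"
    return None


def associated_features(
    main_features: Sequence[FeatureId],
    post_parallel: Sequence[FeatureId],
    score_table: ScoreTable,
    alpha: float = 0.05,
    group_t_threshold: float = 2.0,
) -> pd.DataFrame:
    """Post-parallel PCs that correlate at least moderately with a main feature.

    For each main feature, Pearson correlations with every *other*
    post-parallel feature's trial-mean scores across all pooled trials;
    keep |rho| >= 0.5 with correlation-significance p < ``alpha`` (t
    transform of r with n-2 df).  ``significant_associated`` marks
    associated features whose own group |t| >= ``group_t_threshold``.
    """
    post = [FeatureId(*f) for f in post_parallel]
    mains = [FeatureId(*f) for f in main_features]
    cols = ["main_feature", "associated_feature", "rho", "band", "p_corr",
            "group_t", "significant_associated"]
    if not post or not mains:
        return pd.DataFrame(columns=cols)
    X = score_table.matrix(post)
    n = X.shape[0]
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.all():
        for f, ok in zip(post, usable):
            if not ok:
                logger.warning("feature %s has zero score variance; skipped",
                               f.label)
    t_group = welch_t_statistics(X, score_table.groups == GROUPS[0])
    Z = np.where(usable, 1.0, np.nan) * (X - X.mean(axis=0)) / np.where(
        usable, sd, 1.0)
    corr = Z.T @ Z / n
    index = {f: i for i, f in enumerate(post)}
    rows = []
    for m in mains:
        if m not in index or not usable[index[m]]:
            continue
        i = index[m]
        for f in post:
            j = index[f]
            if f == m or not usable[j]:
                continue
            rho = float(corr[i, j])
            band = correlation_band(rho)
            if band is None:
                continue
            r2 = min(rho ** 2, 1.0 - 1e-15)
            t_corr = abs(rho) * np.sqrt((n - 2) / (1.0 - r2))
            p_corr = float(2 * stats.t.sf(t_corr, n - 2))
            if p_corr >= alpha:
                continue
            rows.append({
                "main_feature": m.label, "associated_feature": f.label,
                "rho": rho, "band": band, "p_corr": p_corr,
                "group_t": float(t_group[j]),
                "significant_associated": abs(t_group[j]) >= group_t_threshold,
            })
    return pd.DataFrame(rows, columns=cols)


@dataclass
class PointwiseComparison:
    """Per-sample two-group t curve for one variable (pointwise surrogate).

    NOT random-field-theory SPM: each of the 101 samples is tested
    marginally at the corrected alpha with no cluster-level correction.
    """

    variable: str
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float


def pointwise_group_comparison(dataset: WaveformDataset,
                               alpha: float = BONFERRONI_ALPHA
                               ) -> dict[str, PointwiseComparison]:
    """Descriptive per-sample group comparison of the original waveforms.

    Trials are first averaged per participant (control participants' left
    and right limbs together), then a pooled-variance two-sample t-test is
    run at every time sample of every variable, masked at the
    Bonferroni-corrected ``alpha``.  A labelled pointwise surrogate for
    SPM; no random-field correction is applied.
    """
    parts = dataset.meta["participant"].to_numpy()
    uniq = list(dict.fromkeys(parts))
    means = np.stack([dataset.values[parts == p].mean(axis=0) for p in uniq])
    groups = np.array([
        dataset.meta.loc[parts == p, "group"].iloc[0] for p in uniq])
    is_sym = groups == GROUPS[0]
    if is_sym.all() or not is_sym.any():
        raise InvalidInputError("both groups must be present")
    out = {}
    for j, v in enumerate(VARIABLES):
        a = means[is_sym, j, :]
        b = means[~is_sym, j, :]
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
        out[v] = PointwiseComparison(v, np.asarray(t), np.asarray(p),
                                     np.asarray(p) < alpha, alpha)
    return out


# ---------------------------------------------------------------------------
# Permutation calibration
# ---------------------------------------------------------------------------

def permutation_calibration(
    score_table: ScoreTable,
    main_features: Sequence[FeatureId],
    post_parallel: Sequence[FeatureId],
    n_permutations: int = 200,
    alpha: float = FINAL_ALPHA,
    screening_threshold: float = SCREENING_THRESHOLD,
    seed=None,
) -> dict:
    """Null calibration by permuting trial group labels.

    Keeps the main-feature set fixed and, per permutation, (a) recomputes
    the Welch tests on the main features, recording whether any reaches
    ``alpha``; (b) recomputes screening over all post-parallel features,
    recording the retained fraction at |t| >= ``screening_threshold``.
    Under exchangeable labels the main-feature tests should essentially
    never reach alpha = 0.001, and screening should retain about 5% of
    features.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X_main = score_table.matrix([FeatureId(*f) for f in main_features])
    X_all = score_table.matrix([FeatureId(*f) for f in post_parallel])
    is_sym = score_table.groups == GROUPS[0]
    n_sym = int(is_sym.sum())
    n = len(is_sym)
    any_significant = 0
    retention = np.empty(n_permutations)
    for i in range(int(n_permutations)):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_sym]] = True
        p_main = _welch_p_values(X_main, mask)
        if np.any(p_main < alpha):
            any_significant += 1
        t_all = welch_t_statistics(X_all, mask)
        retention[i] = np.mean(np.abs(t_all) >= screening_threshold)
    return {
        "n_permutations": int(n_permutations),
        "frac_with_significant_feature": any_significant / n_permutations,
        "frac_without_significant_feature": 1.0 - any_significant / n_permutations,
        "mean_screening_retention": float(retention.mean()),
    }


def _welch_p_values(X: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch p-values per column."""
    a, b = X[is_a], X[~is_a]
    na, nb = len(a), len(b)
    va, vb = a.var(axis=0, ddof=1) / na, b.var(axis=0, ddof=1) / nb
    se2 = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(se2)
        df = se2 ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = 2 * stats.t.sf(np.abs(t), df)
    return np.where(np.isfinite(p), p, 1.0)
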