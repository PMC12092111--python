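"""Interpretive artifacts for main features.

A principal component of a waveform variable is abstract; these helpers
turn it into things a movement scientist can read:

* *quartile waveforms* -- the original-variable curves corresponding to the
  upper and lower quartiles of pooled trial-mean PC scores, either as the
  observed trials nearest each quartile or as model reconstructions
  ``mu(t) + 101 q sigma(t) c_k(t)``;
* *group-to-quartile assignment* -- which quartile each group's mean score
  points to (the two groups necessarily point opposite ways, since the
  weighted pooled mean score is zero);
* *influence windows* -- maximal time windows where both the coefficient
  magnitude and the squared-correlation curve are large, labelled with the
  task phases they overlap;
* *mode-of-variation labels* -- a quantitative fit of the upper quartile
  curve as ``A * lower(t - C) + B`` inside an influence window, classifying
  the feature's action as scaling, translation, temporal shift, or mixed.
  This classification is an added quantitative operationalization of an
  otherwise qualitative reading of the curves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .datasets import InvalidInputError, N_SAMPLES, WaveformDataset
from .pca import ScoreTable, VariablePCModel
from .selection import FeatureId

logger = logging.getLogger(__name__)

PHASE_NAMES = ("step_down", "pivot", "step_forward")
DEFAULT_PHASE_BOUNDARIES = (33, 66)


@dataclass
class QuartileWaveforms:
    """Upper/lower-quartile curves of the original variable for one feature."""

    feature: FeatureId
    upper: np.ndarray
    lower: np.ndarray
    mode: str  # "representative_trial" or "reconstruction"
    q_upper: float
    q_lower: float
    upper_trial: tuple[str, int] | None = None
    lower_trial: tuple[str, int] | None = None


@dataclass
class InfluenceWindow:
    start: int
    end: int
    phases: tuple[str, ...]


@dataclass
class ModeLabel:
    """Fitted mode of variation ``upper(t) ~= A * lower(t - C) + B``."""

    feature: FeatureId
    window: tuple[int, int]
    A: float
    B: float
    C: float
    dominant_mode: str  # scaling | translation | temporal_shift | mixed
    residual: float


def quartile_waveforms(
    model: VariablePCModel,
    score_table: ScoreTable,
    feature: FeatureId,
    dataset: WaveformDataset | None = None,
    mode: str = "representative_trial",
) -> QuartileWaveforms:
    """Curves of the original variable at the upper/lower score quartiles.

    ``representative_trial`` returns the observed trial whose trial-mean
    score is nearest each quartile (earliest trial on ties) and needs the
    ``dataset``; ``reconstruction`` returns
    ``mu(t) + 101 * q * sigma(t) * c_k(t)`` (the factor 101 undoes the
    trial-mean score scaling).
    """
    feature = FeatureId(*feature)
    scores = score_table.feature(feature)
    if scores.size < 4:
        raise InvalidInputError("need >= 4 scored trials for quartiles")
    q_upper = float(np.percentile(scores, 75))
    q_lower = float(np.percentile(scores, 25))
    c = model.coefficient(feature.pc)
    if mode == "reconstruction":
        upper = model.mu + N_SAMPLES * q_upper * model.sigma * c
        lower = model.mu + N_SAMPLES * q_lower * model.sigma * c
        return QuartileWaveforms(feature, upper, lower, mode, q_upper, q_lower)
    if mode != "representative_trial":
        raise InvalidInputError(f"unknown quartile mode {mode!r}")
    if dataset is None:
        raise InvalidInputError("representative_trial mode needs the dataset")
    X = dataset.variable_matrix(feature.variable)
    keys = dataset.trial_keys()
    i_up = int(np.argmin(np.abs(scores - q_upper)))
    i_lo = int(np.argmin(np.abs(scores - q_lower)))
    return QuartileWaveforms(
        feature, X[i_up].copy(), X[i_lo].copy(), mode, q_upper, q_lower,
        upper_trial=keys[i_up], lower_trial=keys[i_lo])


def assign_group_quartile(mean_scores: Mapping[str, float]) -> dict[str, str]:
    """Map each group to the quartile its mean PC score points to.

    Positive mean score -> upper quartile, negative -> lower.  With
    weighted group means the two groups necessarily receive opposite
    labels, because the weighted pooled mean score is zero.  An exactly
    zero mean yields ``"undetermined"`` with a warning.
    """
    out = {}
    for group, m in mean_scores.items():
        if m > 0:
            out[group] = "upper"
        elif m < 0:
            out[group] = "lower"
        else:
            logger.warning("group %r has exactly zero mean score", group)
            out[group] = "undetermined"
    labels = [v for v in out.values() if v != "undetermined"]
    if len(labels) == 2 and labels[0] == labels[1]:
        logger.warning("both groups map to the same quartile; check whether "
                       "unweighted means were passed")
    return out


def _phase_labels(start: int, end: int,
                  boundaries: tuple[int, int]) -> tuple[str, ...]:
    b0, b1 = boundaries
    spans = ((0, b0), (b0, b1), (b1, N_SAMPLES - 1))
    return tuple(name for name, (s, e) in zip(PHASE_NAMES, spans)
                 if start <= e and end >= s)


def influence_windows(
    model: VariablePCModel,
    pc: int,
    fraction: float = 0.5,
    phase_boundaries: tuple[int, int] = DEFAULT_PHASE_BOUNDARIES,
) -> list[InfluenceWindow]:
    """Time windows where a PC has its greatest influence on the waveform.

    Maximal runs of samples where both ``|c_k(t)| >= fraction * max|c_k|``
    and ``r^2_k(t) >= fraction * max r^2_k`` hold, labelled with the task
    phases each window overlaps.
    """
    c = np.abs(model.coefficient(pc))
    r2 = model.squared_correlation(pc)
    mask = (c >= fraction * c.max()) & (r2 >= fraction * r2.max())
    windows = []
    t = 0
    while t < N_SAMPLES:
        if mask[t]:
            start = t
            while t + 1 < N_SAMPLES and mask[t + 1]:
                t += 1
            windows.append(InfluenceWindow(
                start, t, _phase_labels(start, t, phase_boundaries)))
        t += 1
    return windows


def fit_variation_mode(
    upper: np.ndarray,
    lower: np.ndarray,
    window: tuple[int, int],
    feature: FeatureId | None = None,
    mixed_tolerance: float = 0.2,
) -> ModeLabel:
    """Classify how the upper quartile curve differs from the lower one.

    Grid search over integer temporal shifts C in [-L/2, +L/2] (L = window
    length, small |C| preferred on ties); for each C a least-squares fit of
    scaling A and offset B mapping ``lower(t - C)`` to ``upper(t)`` inside
    the window.  The dominant mode is the largest of the normalized
    deviations |A - 1|, |B| / range(lower), |C| / L; when the top two are
    within ``mixed_tolerance`` (20%) of each other the label is ``mixed``.
    A constant lower curve leaves A unidentifiable and falls back to a
    translation-only fit with a warning.
    """
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    s, e = int(window[0]), int(window[1])
    length = e - s
    if length < 5:
        raise InvalidInputError("window must span >= 5 samples")
    t_win = np.arange(s, e + 1, dtype=float)
    t_all = np.arange(len(lower), dtype=float)
    u = upper[s:e + 1]
    lower_range = float(np.ptp(lower[s:e + 1]))
    fid = FeatureId(*feature) if feature is not None else FeatureId("", 0)

    if lower_range < 1e-12:
        logger.warning("constant lower curve in window; translation-only fit")
        b = float(np.mean(u - lower[s:e + 1]))
        resid = float(np.sqrt(np.mean((u - lower[s:e + 1] - b) ** 2)))
        return ModeLabel(fid, (s, e), 1.0, b, 0.0, "translation", resid)

    shifts = sorted(range(-(length // 2), length // 2 + 1),
                    key=lambda c: (abs(c), c))
    best = None
    for c_shift in shifts:
        shifted = np.interp(t_win - c_shift, t_all, lower)
        design = np.column_stack([shifted, np.ones_like(shifted)])
        coef, *_ = np.linalg.lstsq(design, u, rcond=None)
        resid = float(np.sqrt(np.mean((u - design @ coef) ** 2)))
        if best is None or resid < best[0] - 1e-12:
            best = (resid, float(coef[0]), float(coef[1]), float(c_shift))
    resid, a, b, c_shift = best

    deviations = {
        "scaling": abs(a - 1.0),
        "translation": abs(b) / lower_range,
        "temporal_shift": abs(c_shift) / length,
    }
    ranked = sorted(deviations.items(), key=lambda kv: -kv[1])
    (top_mode, d1), (_, d2) = ranked[0], ranked[1]
    if d1 <= 0 or abs(d1 - d2) <= mixed_tolerance * max(d1, d2):
        dominant = "mixed"
    else:
        dominant = top_mode
    return ModeLabel(fid, (s, e), a, b, c_shift, dominant, resid)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _slug(label: str) -> str:
    return label.replace(" ", "_")


def render_report(results: Mapping, outdir) -> dict:
    """Render tables and one figure per main feature from a results bundle.

    ``results`` is the machine-readable bundle produced by the pipeline
    (its ``curves`` section carries every curve needed, so nothing is
    recomputed here).  Writes the final-feature, association and
    stage-count tables as delimited files, one PNG per main feature (quartile
    curves annotated with the group-to-quartile arrows on top; coefficient
    and squared-correlation curves below), and an ``index.json`` of all
    artifacts.  File names are deterministic.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    index = {"tables": [], "figures": []}
    for name in ("final_features", "associations", "stage_counts",
                 "interpretation", "screening", "selection"):
        rows = results.get(name)
        if rows is None:
            continue
        path = outdir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        index["tables"].append(path.name)

    curves = results.get("curves", {})
    boundaries = results.get("phase_boundaries", DEFAULT_PHASE_BOUNDARIES)
    quartiles = {r["feature"]: r for r in results.get("interpretation", [])}
    for label, payload in sorted(curves.get("features", {}).items()):
        fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
        x = np.arange(N_SAMPLES)
        interp = quartiles.get(label, {})
        axes[0].plot(x, payload["upper"], color="tab:orange",
                     label=f"upper quartile (q={interp.get('q_upper', 0):.3g})")
        axes[0].plot(x, payload["lower"], color="tab:green", ls="--",
                     label=f"lower quartile (q={interp.get('q_lower', 0):.3g})")
        if "mu" in payload:
            axes[0].plot(x, payload["mu"], color="0.6", lw=0.8, label="mean")
        for group, quart in interp.get("group_quartile", {}).items():
            if quart not in ("upper", "lower"):
                continue
            curve = payload[quart]
            color = "tab:red" if group == "symptomatic" else "tab:blue"
            i = int(np.argmax(np.abs(np.asarray(curve)
                                     - np.asarray(payload.get("mu", 0.0)))))
            axes[0].annotate(group, xy=(i, curve[i]),
                             xytext=(i, curve[i]), color=color, fontsize=8)
        axes[0].set_ylabel(label.split(" ")[0])
        axes[0].legend(fontsize=7)
        axes[0].set_title(label)
        axes[1].plot(x, payload["coefficient"], color="k",
                     label="PC coefficient")
        axes[1].plot(x, payload["r2"], color="k", ls="--",
                     label="explained variance $r^2(t)$")
        axes[1].set_xlabel("% task time")
        axes[1].legend(fontsize=7)
        for ax in axes:
            for b in boundaries:
                ax.axvline(b, color="0.8", lw=0.8)
        for lbl, idx in results.get("events", []):
            axes[1].annotate(lbl, xy=(idx, axes[1].get_ylim()[0]),
                             fontsize=7, color="0.4")
        fname = f"feature_{_slug(label)}.png"
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=110)
        plt.close(fig)
        index["figures"].append(fname)

    with open(outdir / "index.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    return index
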