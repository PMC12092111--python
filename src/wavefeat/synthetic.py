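"""Synthetic step-down-and-pivot cohorts with planted group effects.

The generator emulates the statistical structure the selection pipeline
assumes: two unbalanced groups (symptomatic participants contributing one
limb, controls contributing both), a variable number of trials per
participant, 16 smooth waveform variables per trial, participant-level
random offsets, and trial-level smooth (band-limited) noise.  Group
differences are planted as the three elementary modes of variation of a
windowed curve segment,

    y = A * f(t - C) + B,

i.e. scaling (A), translation (B) and temporal shift (C), applied inside a
cosine-tapered time window so that the injected difference is as smooth as
the low-pass-filtered signals it imitates.  Each generated cohort comes
with a machine-readable truth table of the planted effects, so that every
downstream stage can be tested for recovery without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    ANGLE_VARIABLES,
    ConfigError,
    GROUPS,
    LIMB_ROLES,
    N_SAMPLES,
    VARIABLES,
    WaveformDataset,
)

logger = logging.getLogger(__name__)

# Smooth per-variable template curves f(t): truncated Fourier series on
# t in [0, 1], (a0, ((a1, b1), (a2, b2), (a3, b3))) with
# f(t) = a0 + sum_m a_m cos(2 pi m t) + b_m sin(2 pi m t).
# Shapes are free choices qualitatively resembling step-down-and-pivot
# curves (e.g. hip flexion high at step-down, descending through the
# pivot); only the statistical structure matters downstream.  Angles are in
# degrees, moments in %BW.HT.
TEMPLATE_COEFFS: dict[str, tuple[float, tuple[tuple[float, float], ...]]] = {
    "theta_HIPFLEX": (35.0, ((22.0, 6.0), (5.0, -4.0), (1.5, 2.0))),
    "theta_HIPADD": (2.0, ((4.0, 3.0), (2.0, -2.0), (1.0, 1.0))),
    "theta_HIPROT": (-3.0, ((5.0, -2.0), (2.0, 2.0), (1.0, -1.0))),
    "theta_KNEEEXT": (-30.0, ((18.0, -10.0), (6.0, 5.0), (2.0, -2.0))),
    "theta_ANKLEDF": (8.0, ((10.0, -6.0), (4.0, 3.0), (2.0, -1.0))),
    "theta_LUMBAREXT": (-10.0, ((4.0, 2.0), (1.5, -1.0), (0.5, 0.5))),
    "theta_LUMBARBEND": (1.0, ((3.0, -2.0), (1.5, 1.0), (0.5, -0.5))),
    "theta_LUMBARROT": (-5.0, ((6.0, 4.0), (2.0, -1.0), (1.0, 0.5))),
    "M_HIPFLEX": (1.5, ((2.5, 1.2), (1.0, -0.8), (0.4, 0.3))),
    "M_HIPADD": (-1.0, ((1.8, -0.9), (0.7, 0.5), (0.3, -0.2))),
    "M_HIPROT": (0.3, ((0.8, 0.5), (0.4, -0.3), (0.15, 0.1))),
    "M_KNEEEXT": (2.0, ((2.2, -1.0), (0.8, 0.6), (0.3, -0.2))),
    "M_ANKLEDF": (-4.0, ((3.0, 1.5), (1.2, -0.8), (0.5, 0.3))),
    "M_LUMBAREXT": (-1.2, ((1.0, 0.6), (0.5, -0.3), (0.2, 0.1))),
    "M_LUMBARBEND": (0.4, ((0.9, -0.5), (0.3, 0.2), (0.1, -0.1))),
    "M_LUMBARROT": (0.2, ((0.6, 0.3), (0.25, -0.2), (0.1, 0.1))),
}


def variable_template(variable: str) -> np.ndarray:
    """The noise-free template curve f(t) for one variable, 101 samples."""
    a0, harmonics = TEMPLATE_COEFFS[variable]
    t = np.arange(N_SAMPLES) / (N_SAMPLES - 1)
    f = np.full(N_SAMPLES, a0)
    for m, (a, b) in enumerate(harmonics, start=1):
        f += a * np.cos(2 * np.pi * m * t) + b * np.sin(2 * np.pi * m * t)
    return f


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect: ``y = A f(t - C) + B`` inside a time window.

    ``A`` is a dimensionless scaling factor (1 = none), ``B`` a translation
    offset in the variable's units (0 = none) and ``C`` a temporal shift in
    samples (0 = none, positive = delayed).  The effect is applied to all
    trials of ``applied_to`` within ``window`` with cosine-tapered edges.
    """

    variable: str
    window: tuple[int, int]
    A: float = 1.0
    B: float = 0.0
    C: float = 0.0
    applied_to: str = "symptomatic"

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ConfigError(f"unknown variable {self.variable!r}")
        s, e = self.window
        if not (0 <= s < e <= N_SAMPLES - 1):
            raise ConfigError(f"effect window {self.window} outside [0, 100]")
        if self.A <= 0:
            raise ConfigError("scaling factor A must be positive")
        if abs(self.C) >= e - s:
            raise ConfigError("|C| must be smaller than the window length")
        if self.applied_to not in GROUPS:
            raise ConfigError(f"unknown group {self.applied_to!r}")

    @property
    def mode(self) -> str:
        """Which elementary mode dominates this effect's parameters."""
        kinds = []
        if self.A != 1.0:
            kinds.append("scaling")
        if self.B != 0.0:
            kinds.append("translation")
        if self.C != 0.0:
            kinds.append("temporal_shift")
        return "+".join(kinds) if kinds else "none"


def default_effects() -> tuple[EffectSpec, ...]:
    """The default planted-effect scenario: one of each elementary mode.

    Magnitudes are at least 1.5x the trial noise SD of the affected
    variable, comfortably recoverable at the default cohort size.
    """
    return (
        EffectSpec("theta_HIPFLEX", (15, 45), B=4.5),
        EffectSpec("M_ANKLEDF", (35, 65), A=1.15),
        EffectSpec("theta_KNEEEXT", (55, 90), C=3.0),
    )


def _scale_map(value) -> dict[str, float]:
    """Expand a noise-scale spec into a per-variable map.

    Accepts a scalar (applied to all variables), a {"angle": x, "moment": y}
    map, or a full per-variable map.
    """
    if isinstance(value, Mapping):
        if set(value) <= {"angle", "moment"}:
            out = {}
            for v in VARIABLES:
                kind = "angle" if v in ANGLE_VARIABLES else "moment"
                out[v] = float(value.get(kind, 0.0))
            return out
        unknown = set(value) - set(VARIABLES)
        if unknown:
            raise ConfigError(f"unknown variables in scale map: {sorted(unknown)}")
        return {v: float(value.get(v, 0.0)) for v in VARIABLES}
    return {v: float(value) for v in VARIABLES}


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic step-down-and-pivot cohort.

    Defaults mirror the study conditions the pipeline targets: 36
    symptomatic participants contributing one limb and 11 controls
    contributing both limbs, 3-7 trials per limb, 16 variables x 101
    samples, smooth trial noise, and three planted effects (one per
    elementary mode of variation).
    """

    n_symptomatic: int = 36
    n_control: int = 11
    trials_per_participant: tuple[int, int] = (3, 7)
    participant_sd: object = field(
        default_factory=lambda: {"angle": 3.0, "moment": 0.75})
    trial_noise_sd: object = field(
        default_factory=lambda: {"angle": 1.5, "moment": 0.4})
    noise_smoothness: float = 8.0
    effects: tuple[EffectSpec, ...] = field(default_factory=default_effects)
    seed: int = 20240908
    phase_boundaries: tuple[int, int] = (33, 66)
    reference_limb: str = "pivot"

    def __post_init__(self) -> None:
        if self.n_symptomatic < 1 or self.n_control < 1:
            raise ConfigError("participant counts must be >= 1")
        lo, hi = self.trials_per_participant
        if not (1 <= lo <= hi):
            raise ConfigError("invalid trials_per_participant range")
        if self.noise_smoothness < 0:
            raise ConfigError("noise_smoothness must be >= 0")
        b0, b1 = self.phase_boundaries
        if not (0 < b0 < b1 < N_SAMPLES - 1):
            raise ConfigError(
                "phase boundaries must be strictly increasing within (0, 100)")
        if self.reference_limb not in LIMB_ROLES:
            raise ConfigError(f"unknown reference limb {self.reference_limb!r}")
        self.effects = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(**e)
            for e in self.effects)
        psd = _scale_map(self.participant_sd)
        tsd = _scale_map(self.trial_noise_sd)
        if min(psd.values()) < 0 or min(tsd.values()) < 0:
            raise ConfigError("noise scales must be >= 0")
        self._participant_sd_map = psd
        self._trial_noise_map = tsd

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = [asdict(e) for e in self.effects]
        d.pop("_participant_sd_map", None)
        d.pop("_trial_noise_map", None)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "effects" in d:
            d["effects"] = tuple(
                EffectSpec(**{**e, "window": tuple(e["window"])})
                if isinstance(e, Mapping) else e
                for e in d["effects"])
        for k in ("trials_per_participant", "phase_boundaries"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def apply_effect(curve: np.ndarray, effect: EffectSpec,
                 taper_fraction: float = 0.15) -> np.ndarray:
    """Apply ``y = A f(t - C) + B`` to a curve inside a cosine-tapered window.

    The taper ramps over ``taper_fraction`` of the window length at each
    edge (at least two samples), so the modified curve joins the original
    continuously, as a 10 Hz low-pass-filtered signal must.
    """
    t = np.arange(N_SAMPLES, dtype=float)
    shifted = np.interp(t - effect.C, t, curve)
    target = effect.A * shifted + effect.B
    s, e = effect.window
    length = e - s
    ramp = max(2, int(round(taper_fraction * length)))
    w = np.zeros(N_SAMPLES)
    w[s:e + 1] = 1.0
    for k in range(ramp):
        frac = 0.5 * (1.0 - np.cos(np.pi * (k + 1) / (ramp + 1)))
        w[s + k] = min(w[s + k], frac)
        w[e - k] = min(w[e - k], frac)
    return curve + w * (target - curve)


def smooth_noise(rng: np.random.Generator, n: int, sd: float,
                 smoothness: float, size: int = 1) -> np.ndarray:
    """Stationary smooth Gaussian noise: white noise convolved with a
    Gaussian kernel of the given correlation length (samples), normalized
    so each output sample has standard deviation ``sd`` exactly.
    """
    if sd == 0:
        return np.zeros((size, n)) if size > 1 else np.zeros(n)
    if smoothness <= 0:
        out = rng.normal(0.0, sd, size=(size, n))
        return out if size > 1 else out[0]
    half = int(np.ceil(4 * smoothness))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / smoothness) ** 2)
    k /= k.sum()
    gain = np.linalg.norm(k)
    white = rng.normal(0.0, sd / gain, size=(size, n + 2 * half))
    out = np.empty((size, n))
    for i in range(size):
        out[i] = np.convolve(white[i], k, mode="valid")
    return out if size > 1 else out[0]


def generate_cohort(config: CohortConfig) -> tuple[WaveformDataset, tuple[EffectSpec, ...]]:
    """Generate a synthetic cohort and return it with its planted-effect truth table.

    Fully reproducible from ``config.seed``.  Symptomatic participants
    contribute one limb each (sides alternating); controls contribute
    trials from both limbs, all serving the configured reference-limb
    analysis.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    templates = {v: variable_template(v) for v in VARIABLES}
    group_templates = {g: {v: templates[v].copy() for v in VARIABLES}
                       for g in GROUPS}
    for eff in config.effects:
        tpl = group_templates[eff.applied_to][eff.variable]
        group_templates[eff.applied_to][eff.variable] = apply_effect(tpl, eff)

    b0, b1 = config.phase_boundaries
    events = (("PFS1", int(b0)), ("NFS2", int(b1)), ("PFO3", N_SAMPLES - 1))

    # (participant, group, side, n_trials) blocks; controls get one block
    # per side so both limbs contribute.
    lo, hi = config.trials_per_participant
    blocks: list[tuple[str, str, str]] = []
    for i in range(config.n_symptomatic):
        blocks.append((f"S{i + 1:02d}", "symptomatic",
                       "left" if i % 2 == 0 else "right"))
    for i in range(config.n_control):
        blocks.append((f"C{i + 1:02d}", "control", "left"))
        blocks.append((f"C{i + 1:02d}", "control", "right"))
    n_trials_per_block = rng.integers(lo, hi + 1, size=len(blocks))

    psd = config._participant_sd_map
    tsd = config._trial_noise_map
    participant_ids = list(dict.fromkeys(pid for pid, _, _ in blocks))
    offsets = {
        pid: {v: rng.normal(0.0, psd[v]) for v in VARIABLES}
        for pid in participant_ids
    }

    meta_rows, values, trial_events = [], [], []
    trial_counter: dict[str, int] = {}
    for (pid, group, side), n_t in zip(blocks, n_trials_per_block):
        tpl = group_templates[group]
        for _ in range(int(n_t)):
            trial_counter[pid] = trial_counter.get(pid, 0) + 1
            block = np.empty((len(VARIABLES), N_SAMPLES))
            for j, v in enumerate(VARIABLES):
                noise = smooth_noise(rng, N_SAMPLES, tsd[v],
                                     config.noise_smoothness)
                block[j] = tpl[v] + offsets[pid][v] + noise
            meta_rows.append((pid, trial_counter[pid], group,
                              config.reference_limb, side))
            values.append(block)
            trial_events.append(events)

    meta = pd.DataFrame(
        meta_rows,
        columns=["participant", "trial", "group", "limb_role", "limb_side"])
    dataset = WaveformDataset(
        meta, np.stack(values), events=trial_events,
        reference_limb=config.reference_limb)
    return dataset, tuple(config.effects)


def write_truth_table(effects: Sequence[EffectSpec], path, sep: str = ",") -> None:
    """Write the planted-effect truth table as a delimited file."""
    rows = [{
        "variable": e.variable, "window_start": e.window[0],
        "window_end": e.window[1], "A": e.A, "B": e.B, "C": e.C,
        "applied_to": e.applied_to, "mode": e.mode,
    } for e in effects]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_truth_table(path, sep: str = ",") -> tuple[EffectSpec, ...]:
    df = pd.read_csv(path, sep=sep)
    return tuple(
        EffectSpec(variable=r["variable"],
                   window=(int(r["window_start"]), int(r["window_end"])),
                   A=float(r["A"]), B=float(r["B"]), C=float(r["C"]),
                   applied_to=r["applied_to"])
        for _, r in df.iterrows())


def planted_feature_check(selection_result, truth: Sequence[EffectSpec],
                          models: Mapping[str, object],
                          influence_fraction: float = 0.5) -> list[dict]:
    """Audit whether each planted effect was recovered by the pipeline.

    A planted effect counts as a *hit* when at least one final main feature
    belongs to the effect's variable and has the peak of its
    squared-correlation curve inside the planted window.  The report also
    records whether any influence window (joint coefficient / squared-
    correlation support at ``influence_fraction`` of their maxima) overlaps
    the planted window.  Effects on variables absent from the fitted models
    are reported as untestable.
    """
    from .interpret import influence_windows

    report = []
    for eff in truth:
        s, e = eff.window
        entry = {
            "variable": eff.variable, "window": (s, e), "mode": eff.mode,
            "criterion": ("hit iff a main feature on the effect's variable has "
                          "its squared-correlation peak inside the planted window"),
            "matching_features": [], "peak_samples": [],
            "window_overlap": False, "status": "miss",
        }
        if eff.variable not in models:
            entry["status"] = "untestable"
            report.append(entry)
            continue
        model = models[eff.variable]
        hit = False
        for fid in selection_result.main_features:
            if fid.variable != eff.variable:
                continue
            r2 = model.squared_correlation(fid.pc)
            peak = int(np.argmax(r2))
            entry["matching_features"].append(fid.label)
            entry["peak_samples"].append(peak)
            if s <= peak <= e:
                hit = True
            for win in influence_windows(model, fid.pc,
                                         fraction=influence_fraction):
                if win.start <= e and win.end >= s:
                    entry["window_overlap"] = True
        entry["status"] = "hit" if hit else "miss"
        report.append(entry)
    return report
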