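"""Data model, IO and preprocessing for time-normalized trial waveforms.

A *trial* is one execution of the step-down-and-pivot task by one
participant.  Each trial carries 16 biomechanical variables -- eight joint
angles (degrees) and eight joint moments (% body weight x height) -- every
one of them resampled onto a common 101-sample axis representing 0-100% of
task time.  Trials are pooled across participants and groups
(symptomatic vs. control) into a :class:`WaveformDataset`, with a
per-trial weight that equalizes each participant's influence regardless of
how many trials they contributed.

The on-disk format is a long delimited table, one row per
(participant, trial, variable, sample); see :func:`read_dataset` and
:func:`write_dataset`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_SAMPLES = 101
#: Standard gravitational acceleration, m/s^2, used for moment normalization.
STANDARD_GRAVITY = 9.81

COORDINATES = (
    "HIPFLEX", "HIPADD", "HIPROT", "KNEEEXT",
    "ANKLEDF", "LUMBAREXT", "LUMBARBEND", "LUMBARROT",
)
ANGLE_VARIABLES = tuple(f"theta_{c}" for c in COORDINATES)
MOMENT_VARIABLES = tuple(f"M_{c}" for c in COORDINATES)
#: The 16 in-scope biomechanical variables, in canonical order.
VARIABLES = ANGLE_VARIABLES + MOMENT_VARIABLES

GROUPS = ("symptomatic", "control")
LIMB_ROLES = ("pivot", "swing")
LIMB_SIDES = ("left", "right")


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its domain."""


class SchemaError(ValueError):
    """Raised when a dataset file violates the long-table schema."""


class ConfigError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialWaveform:
    """One trial's time-normalized curve for a single biomechanical variable.

    ``events`` are task events stored as (label, sample-index) pairs, with
    labels of the form [Limb][EventType][Sequence], e.g. ``PFO3`` = third
    event on the pivot limb, a foot-off.
    """

    participant_id: str
    group: str
    limb_role: str
    limb_side: str
    trial_index: int
    variable: str
    values: np.ndarray
    events: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.limb_role not in LIMB_ROLES:
            raise InvalidInputError(f"unknown limb role {self.limb_role!r}")
        if self.limb_side not in LIMB_SIDES:
            raise InvalidInputError(f"unknown limb side {self.limb_side!r}")
        if self.variable not in VARIABLES:
            raise InvalidInputError(f"unknown variable {self.variable!r}")
        if int(self.trial_index) < 1:
            raise InvalidInputError("trial_index must be >= 1")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SAMPLES,):
            raise InvalidInputError(
                f"values must have exactly {N_SAMPLES} samples, "
                f"got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("values must be finite")
        idx = [int(i) for _, i in self.events]
        if any(i < 0 or i > N_SAMPLES - 1 for i in idx):
            raise InvalidInputError("event sample-indices must lie in [0, 100]")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InvalidInputError("event sample-indices must be strictly increasing")


class WaveformDataset:
    """Pooled collection of trials across participants, groups and variables.

    Internally values are a dense ``(n_trials, 16, 101)`` array with trial
    metadata in a DataFrame; each (participant, trial_index) pair carries
    all 16 variables.  ``weights`` sum to one over trials; by default each
    participant's trials share ``1/P`` of the total weight (P = number of
    participants), so that prolific participants do not dominate the
    pooled analysis.
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        values: np.ndarray,
        *,
        events: Sequence[tuple[tuple[str, int], ...]] | None = None,
        weights: np.ndarray | Mapping[tuple[str, int], float] | None = None,
        reference_limb: str = "pivot",
        weighting: str | Callable[[Mapping[str, int]], Mapping[str, float]] = "equal_participant",
    ) -> None:
        meta = meta.reset_index(drop=True)
        required = {"participant", "trial", "group", "limb_role", "limb_side"}
        missing = required - set(meta.columns)
        if missing:
            raise InvalidInputError(f"meta missing columns: {sorted(missing)}")
        values = np.asarray(values, dtype=float)
        n = len(meta)
        if n == 0:
            raise InvalidInputError("empty dataset")
        if values.shape != (n, len(VARIABLES), N_SAMPLES):
            raise InvalidInputError(
                f"values must have shape ({n}, {len(VARIABLES)}, {N_SAMPLES})")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("waveform values must be finite")
        if reference_limb not in LIMB_ROLES:
            raise InvalidInputError(f"unknown reference limb {reference_limb!r}")
        keys = list(zip(meta["participant"], meta["trial"]))
        if len(set(keys)) != n:
            raise InvalidInputError("duplicate (participant, trial) pairs in meta")
        by_part = meta.groupby("participant", sort=False)["group"].nunique()
        if (by_part > 1).any():
            bad = by_part[by_part > 1].index[0]
            raise InvalidInputError(
                f"participant {bad!r} appears under more than one group")

        self.meta = meta
        self.values = values
        self.events = tuple(tuple(e) for e in events) if events is not None else tuple(
            () for _ in range(n))
        if len(self.events) != n:
            raise InvalidInputError("events must align with trials")
        self.reference_limb = reference_limb
        self.weighting = weighting

        if weights is None:
            w = compute_trial_weights(self, strategy=weighting)
            self.weights = np.array([w[k] for k in keys], dtype=float)
        elif isinstance(weights, Mapping):
            if set(weights) != set(keys):
                raise InvalidInputError(
                    "weights must reference exactly the dataset's trials")
            self.weights = np.array([weights[k] for k in keys], dtype=float)
        else:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != (n,):
                raise InvalidInputError("weights must align with trials")
        if np.any(self.weights <= 0):
            raise InvalidInputError("weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise InvalidInputError("weights must sum to 1 within 1e-12")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_trials(
        cls,
        trials: Iterable[TrialWaveform],
        *,
        weights: Mapping[tuple[str, int], float] | None = None,
        reference_limb: str = "pivot",
        weighting: str | Callable = "equal_participant",
    ) -> "WaveformDataset":
        """Assemble a dataset from per-variable :class:`TrialWaveform` records."""
        var_pos = {v: i for i, v in enumerate(VARIABLES)}
        rows: dict[tuple[str, int], dict] = {}
        for tw in trials:
            key = (tw.participant_id, int(tw.trial_index))
            rec = rows.setdefault(key, {
                "meta": (tw.group, tw.limb_role, tw.limb_side),
                "events": tw.events,
                "curves": {},
            })
            if rec["meta"] != (tw.group, tw.limb_role, tw.limb_side):
                raise InvalidInputError(
                    f"inconsistent metadata across variables for trial {key}")
            if tw.variable in rec["curves"]:
                raise InvalidInputError(
                    f"duplicate variable {tw.variable} for trial {key}")
            rec["curves"][tw.variable] = tw.values
        if not rows:
            raise InvalidInputError("empty dataset")
        meta_rows, events, values = [], [], []
        for key, rec in rows.items():
            missing = set(VARIABLES) - set(rec["curves"])
            if missing:
                raise SchemaError(
                    f"trial {key} is missing variables {sorted(missing)}")
            g, role, side = rec["meta"]
            meta_rows.append((key[0], key[1], g, role, side))
            events.append(tuple(rec["events"]))
            block = np.empty((len(VARIABLES), N_SAMPLES))
            for v, curve in rec["curves"].items():
                block[var_pos[v]] = curve
            values.append(block)
        meta = pd.DataFrame(
            meta_rows,
            columns=["participant", "trial", "group", "limb_role", "limb_side"])
        return cls(meta, np.stack(values), events=events, weights=weights,
                   reference_limb=reference_limb, weighting=weighting)

    # -- accessors ----------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.meta)

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.meta["participant"]))

    @property
    def groups(self) -> np.ndarray:
        return self.meta["group"].to_numpy()

    def trial_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.meta["participant"], self.meta["trial"]))

    def variable_matrix(self, variable: str) -> np.ndarray:
        """Return the (n_trials, 101) matrix of one variable's waveforms."""
        if variable not in VARIABLES:
            raise InvalidInputError(f"unknown variable {variable!r}")
        return self.values[:, VARIABLES.index(variable), :]

    def iter_waveforms(self) -> Iterator[TrialWaveform]:
        for i, row in self.meta.iterrows():
            for j, v in enumerate(VARIABLES):
                yield TrialWaveform(
                    participant_id=row["participant"], group=row["group"],
                    limb_role=row["limb_role"], limb_side=row["limb_side"],
                    trial_index=int(row["trial"]), variable=v,
                    values=self.values[i, j], events=self.events[i])

    def weights_digest(self) -> str:
        """Stable hash of the weight vector, for model provenance."""
        return hashlib.sha256(
            np.ascontiguousarray(self.weights).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def resample_waveform(values: Sequence[float], n_out: int = N_SAMPLES) -> np.ndarray:
    """Resample a waveform onto ``n_out`` uniform phase samples.

    Piecewise-linear interpolation on a uniform 0-100% phase axis: monotone,
    overshoot-free, and exact at shared nodes (in particular the first and
    last samples are preserved, and an input already of length ``n_out`` is
    returned unchanged).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidInputError("resampling needs a 1-D sequence of >= 2 samples")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("cannot resample non-finite values")
    if n_out < 2:
        raise InvalidInputError("n_out must be >= 2")
    x_in = np.linspace(0.0, 1.0, arr.size)
    x_out = np.linspace(0.0, 1.0, int(n_out))
    return np.interp(x_out, x_in, arr)


def normalize_moment(moment, mass: float, height: float,
                     g: float = STANDARD_GRAVITY):
    """Convert a joint moment from N.m to % body weight x height (%BW.HT).

    Returns ``100 * moment / (mass * g * height)``; linear in the moment,
    sign-preserving.  Accepts scalars or arrays.
    """
    if not (mass > 0):
        raise InvalidInputError("mass must be positive")
    if not (height > 0):
        raise InvalidInputError("height must be positive")
    return 100.0 * np.asarray(moment, dtype=float) / (mass * g * height)


def participant_trial_weights(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-trial weight 1/(P * n_i) for participant i with n_i trials."""
    if not counts:
        raise InvalidInputError("empty dataset: no participants")
    p = len(counts)
    return {pid: 1.0 / (p * n) for pid, n in counts.items()}


def compute_trial_weights(
    dataset: "WaveformDataset",
    strategy: str | Callable[[Mapping[str, int]], Mapping[str, float]] = "equal_participant",
) -> dict[tuple[str, int], float]:
    """Normalized per-trial weights for the pooled analysis.

    ``equal_participant`` (default): trial j of participant i gets
    ``1/(P * n_i)`` so every participant carries the same total weight
    ``1/P``.  ``equal_trial``: every trial gets ``1/N``.  A callable
    receives the {participant: trial count} mapping and must return a
    {participant: per-trial weight} mapping.
    """
    counts = dataset.meta.groupby("participant", sort=False)["trial"].size()
    counts_map = {str(k): int(v) for k, v in counts.items()}
    if callable(strategy):
        per_trial = dict(strategy(counts_map))
    elif strategy == "equal_participant":
        per_trial = participant_trial_weights(counts_map)
    elif strategy == "equal_trial":
        n_total = sum(counts_map.values())
        per_trial = {pid: 1.0 / n_total for pid in counts_map}
    else:
        raise ConfigError(f"unknown weighting strategy {strategy!r}")
    return {
        (pid, int(t)): per_trial[pid]
        for pid, t in zip(dataset.meta["participant"], dataset.meta["trial"])
    }


def average_control_limbs(
    dataset: "WaveformDataset",
    participants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-participant mean waveforms over all left- and right-limb control trials.

    Descriptive output only: the selection pipeline keeps control trials
    unaveraged.  Returns a DataFrame indexed by (participant, variable) with
    101 sample columns.  Requested participants with no control trials are
    excluded with a logged warning.
    """
    is_control = dataset.groups == "control"
    control_parts = list(dict.fromkeys(dataset.meta.loc[is_control, "participant"]))
    if participants is None:
        participants = control_parts
    rows, index = [], []
    for pid in participants:
        mask = is_control & (dataset.meta["participant"] == pid).to_numpy()
        if not mask.any():
            logger.warning("participant %r has no control trials; excluded", pid)
            continue
        mean_block = dataset.values[mask].mean(axis=0)  # (16, 101)
        for j, v in enumerate(VARIABLES):
            rows.append(mean_block[j])
            index.append((pid, v))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["participant", "variable"]),
        columns=range(N_SAMPLES))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "participant": "participant",
    "group": "group",
    "limb_role": "limb_role",
    "limb_side": "limb_side",
    "trial": "trial",
    "variable": "variable",
    "sample": "sample",
    "value": "value",
}


def _load_schema_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, Mapping):
        return dict(config)
    text = open(config).read()
    if str(config).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_dataset(dataset: WaveformDataset, path, *, events_path=None,
                  sep: str = ",") -> None:
    """Write a dataset as a long delimited table with a header row.

    Values are written with 17 significant digits so that a read/write
    round trip is bit-exact.
    """
    n, nv = dataset.n_trials, len(VARIABLES)
    meta = dataset.meta
    frame = pd.DataFrame({
        "participant": np.repeat(meta["participant"].to_numpy(), nv * N_SAMPLES),
        "group": np.repeat(meta["group"].to_numpy(), nv * N_SAMPLES),
        "limb_role": np.repeat(meta["limb_role"].to_numpy(), nv * N_SAMPLES),
        "limb_side": np.repeat(meta["limb_side"].to_numpy(), nv * N_SAMPLES),
        "trial": np.repeat(meta["trial"].to_numpy(), nv * N_SAMPLES),
        "variable": np.tile(np.repeat(np.array(VARIABLES), N_SAMPLES), n),
        "sample": np.tile(np.arange(N_SAMPLES), n * nv),
        "value": dataset.values.reshape(-1),
    })
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    if events_path is not None:
        rows = []
        for (pid, t), evts in zip(dataset.trial_keys(), dataset.events):
            for label, idx in evts:
                rows.append((pid, t, label, idx))
        pd.DataFrame(rows, columns=["participant", "trial", "label", "sample"]) \
            .to_csv(events_path, sep=sep, index=False)


def read_dataset(path, config=None, *, events_path=None) -> WaveformDataset:
    """Read a long-format delimited waveform table into a :class:`WaveformDataset`.

    ``config`` (mapping or YAML/JSON path) may override column names
    (``columns``), the delimiter (``sep``), the moment unit
    (``moment_unit``: ``"pct_bw_ht"`` (default) or ``"Nm"``, the latter
    requiring per-participant ``mass``/``height`` columns in the file), the
    reference limb and the weighting strategy.
    """
    cfg = _load_schema_config(config)
    cols = {**DEFAULT_COLUMNS, **cfg.get("columns", {})}
    sep = cfg.get("sep", ",")
    moment_unit = cfg.get("moment_unit", "pct_bw_ht")
    if moment_unit not in ("pct_bw_ht", "Nm"):
        raise ConfigError(f"unknown moment unit {moment_unit!r}")

    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    needed = [cols[k] for k in DEFAULT_COLUMNS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})

    unknown = set(df["variable"].unique()) - set(VARIABLES)
    if unknown:
        raise SchemaError(f"{path}: unknown variable names {sorted(unknown)}")

    key_cols = ["participant", "trial", "variable", "sample"]
    if df.duplicated(key_cols).any():
        bad = df.loc[df.duplicated(key_cols), key_cols].iloc[0]
        raise SchemaError(
            f"{path}: duplicate record for (participant={bad['participant']}, "
            f"trial={bad['trial']}, variable={bad['variable']}, "
            f"sample={bad['sample']})")

    if moment_unit == "Nm":
        for c in ("mass", "height"):
            if c not in df.columns:
                raise SchemaError(
                    f"{path}: moment_unit 'Nm' requires a {c!r} column")
        is_moment = df["variable"].isin(MOMENT_VARIABLES)
        sub = df.loc[is_moment]
        df.loc[is_moment, "value"] = (
            100.0 * sub["value"]
            / (sub["mass"] * STANDARD_GRAVITY * sub["height"]))

    df = df.sort_values(["participant", "trial", "variable", "sample"],
                        kind="mergesort")
    grouped = df.groupby(["participant", "trial", "variable"], sort=False)
    sizes = grouped["sample"].agg(["size", "min", "max"])
    bad = sizes[(sizes["size"] != N_SAMPLES) | (sizes["min"] != 0)
                | (sizes["max"] != N_SAMPLES - 1)]
    if len(bad):
        key = bad.index[0]
        raise SchemaError(
            f"{path}: non-contiguous or incomplete samples for "
            f"(participant={key[0]}, trial={key[1]}, variable={key[2]}): "
            f"expected samples 0..{N_SAMPLES - 1}")

    events_map: dict[tuple[str, int], tuple] = {}
    if events_path is not None:
        ev = pd.read_csv(events_path, sep=sep)
        for c in ("participant", "trial", "label", "sample"):
            if c not in ev.columns:
                raise SchemaError(f"{events_path}: missing column {c!r}")
        for (pid, t), sub in ev.groupby(["participant", "trial"], sort=False):
            events_map[(pid, int(t))] = tuple(
                (str(l), int(s)) for l, s in zip(sub["label"], sub["sample"]))

    trials = []
    for (pid, t, v), sub in grouped:
        row0 = sub.iloc[0]
        trials.append(TrialWaveform(
            participant_id=str(pid), group=str(row0["group"]),
            limb_role=str(row0["limb_role"]), limb_side=str(row0["limb_side"]),
            trial_index=int(t), variable=str(v),
            values=sub["value"].to_numpy(),
            events=events_map.get((str(pid), int(t)), ())))
    return WaveformDataset.from_trials(
        trials,
        reference_limb=cfg.get("reference_limb", "pivot"),
        weighting=cfg.get("weighting", "equal_participant"))
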