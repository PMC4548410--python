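"""Domain containers for voltage-clamp sweep data and their on-disk formats.

Conventions enforced package-wide: membrane current in pA with outward
current positive (IPSCs recorded at depolarized holding potentials appear
as positive deflections), times in ms, potentials in mV, distances in µm.

A recording is stored as one HDF5 file with three groups:

* ``/traces`` — trial × sample float dataset of current (pA)
* ``/protocol`` — attributes ``step_onset_ms``, ``step_duration_ms``,
  ``v_hold_pre_mV``, ``v_step_mV``, ``v_hold_post_mV``, ``artifact_blank_ms``,
  plus ``sampling_rate_Hz``
* ``/meta`` — free-form string/scalar attributes (genotype, age group,
  ground-truth annotations from the simulators, ...)
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import h5py
import numpy as np
import pandas as pd

GENOTYPES = ("Pcdhg22", "Pcdhg0", "Pcdhg1")
AGE_GROUPS = ("juvenile", "adult")

#: applied when a legacy container lacks an artifact blanking window (ms)
DEFAULT_ARTIFACT_BLANK_MS = 1.0


class SweepSetFormatError(ValueError):
    """Raised when an on-disk container is missing fields or malformed."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Voltage-step protocol timing and command potentials.

    ``artifact_blank_ms`` is the window excluded from peak searches after
    each step transition, covering capacitive/stimulus artifacts.
    """

    step_onset_ms: float
    step_duration_ms: float
    v_hold_pre_mV: float
    v_step_mV: float
    v_hold_post_mV: float
    artifact_blank_ms: float = DEFAULT_ARTIFACT_BLANK_MS

    def __post_init__(self) -> None:
        if self.step_onset_ms < 0:
            raise ValueError("step_onset_ms must be >= 0")
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration_ms must be > 0")
        if self.artifact_blank_ms < 0:
            raise ValueError("artifact_blank_ms must be >= 0")

    @classmethod
    def paired(cls, step_onset_ms: float = 60.0) -> "StimulusProtocol":
        """Paired-recording protocol: 200 ms step from −70 to +20 mV,
        postsynaptic cell held at +30 mV."""
        return cls(
            step_onset_ms=step_onset_ms,
            step_duration_ms=200.0,
            v_hold_pre_mV=-70.0,
            v_step_mV=20.0,
            v_hold_post_mV=30.0,
        )

    @classmethod
    def autaptic(
        cls, step_onset_ms: float = 60.0, step_duration_ms: float = 2.0
    ) -> "StimulusProtocol":
        """Autapse protocol: brief (2–4 ms) step from −70 to +60 mV followed
        by a return to −20 mV, at which the current is measured."""
        if not 2.0 <= step_duration_ms <= 4.0:
            raise ValueError("autaptic step duration must be in [2, 4] ms")
        return cls(
            step_onset_ms=step_onset_ms,
            step_duration_ms=step_duration_ms,
            v_hold_pre_mV=-70.0,
            v_step_mV=60.0,
            v_hold_post_mV=-20.0,
        )


@dataclass
class SweepSet:
    """Trial × sample matrix of membrane current (pA, outward positive)."""

    traces: np.ndarray
    sampling_rate_Hz: float
    protocol: StimulusProtocol
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D trial × sample matrix")
        if self.traces.shape[0] < 1:
            raise ValueError("need at least one trial")
        if self.sampling_rate_Hz <= 0:
            raise ValueError("sampling_rate_Hz must be > 0")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_Hz

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def time_ms(self) -> np.ndarray:
        """Sample times in ms from sweep start."""
        return np.arange(self.n_samples) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` (rounded to the nearest sample)."""
        return int(round(t_ms / self.dt_ms))


@dataclass
class PairRecording:
    """One directed paired test: presynaptic step, postsynaptic sweeps."""

    pre_cell_id: str
    post_cell_id: str
    distance_um: float
    genotype: str
    age_group: str
    sweeps: SweepSet

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ValueError("distance_um must be >= 0")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")


@dataclass
class DetectionResult:
    """Outcome of the three-criterion connection (or autapse) classifier."""

    verdict: bool
    peak_pA: float | None
    latency_ms: float | None
    rise_10_90_ms: float | None
    trial_fraction: float | None
    criteria: dict[str, bool]
    baseline_sd_pA: float
    baseline_mean_pA: float = 0.0
    anomaly: bool = False
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if self.trial_fraction is not None and not 0.0 <= self.trial_fraction <= 1.0:
            raise ValueError("trial_fraction must be in [0, 1]")
        if self.verdict and not all(self.criteria.values()):
            raise ValueError("verdict cannot be true with a failing criterion")


@dataclass
class IVResult:
    """Peak current vs holding potential and the interpolated reversal."""

    holding_potentials_mV: np.ndarray
    peak_currents_pA: np.ndarray
    reversal_mV: float
    extrapolated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.holding_potentials_mV, dtype=float)
        i = np.asarray(self.peak_currents_pA, dtype=float)
        if v.size != i.size or v.size < 2:
            raise ValueError("need matched lists of >= 2 potentials and currents")
        if not np.all(np.diff(v) > 0):
            raise ValueError("holding potentials must be strictly increasing")
        self.holding_potentials_mV = v
        self.peak_currents_pA = i


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_PROTOCOL_FIELDS = (
    "step_onset_ms",
    "step_duration_ms",
    "v_hold_pre_mV",
    "v_step_mV",
    "v_hold_post_mV",
)


def write_sweepset(sweeps: SweepSet, path: str | Path) -> None:
    """Write a :class:`SweepSet` to the documented HDF5 layout.

    Traces are stored in their native dtype so the round trip is bit-exact.
    Metadata values that are not scalars or strings are stored as JSON.
    """
    if not np.all(np.isfinite(sweeps.traces)):
        raise ValueError("refusing to write non-finite trace values")
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=sweeps.traces)
        g = f.create_group("protocol")
        for name in _PROTOCOL_FIELDS:
            g.attrs[name] = getattr(sweeps.protocol, name)
        g.attrs["artifact_blank_ms"] = sweeps.protocol.artifact_blank_ms
        g.attrs["sampling_rate_Hz"] = sweeps.sampling_rate_Hz
        m = f.create_group("meta")
        for key, value in sweeps.meta.items():
            if isinstance(value, (str, int, float, bool, np.integer, np.floating)):
                m.attrs[key] = value
            else:
                m.attrs[key] = "json:" + json.dumps(value, default=_jsonify)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def read_sweepset(path: str | Path) -> SweepSet:
    """Read a :class:`SweepSet`, validating the container layout.

    A legacy container lacking ``artifact_blank_ms`` gets the documented
    default of 1.0 ms and ``meta['artifact_blank_defaulted'] = True``.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SweepSetFormatError(f"cannot open container {path}: {exc}") from exc
    with f:
        if "traces" not in f or "protocol" not in f:
            raise SweepSetFormatError(
                f"{path}: container must hold /traces and /protocol"
            )
        traces = f["traces"][()]
        pattrs = dict(f["protocol"].attrs)
        if "sampling_rate_Hz" not in pattrs:
            raise SweepSetFormatError(f"{path}: missing field 'sampling_rate_Hz'")
        for name in _PROTOCOL_FIELDS:
            if name not in pattrs:
                raise SweepSetFormatError(f"{path}: missing field '{name}'")
        meta: dict[str, Any] = {}
        if "meta" in f:
            for key, value in f["meta"].attrs.items():
                if isinstance(value, str) and value.startswith("json:"):
                    meta[key] = json.loads(value[5:])
                elif isinstance(value, bytes):
                    meta[key] = value.decode()
                elif isinstance(value, (np.integer, np.floating, np.bool_)):
                    meta[key] = value.item()
                else:
                    meta[key] = value
        defaulted = "artifact_blank_ms" not in pattrs
        protocol = StimulusProtocol(
            step_onset_ms=float(pattrs["step_onset_ms"]),
            step_duration_ms=float(pattrs["step_duration_ms"]),
            v_hold_pre_mV=float(pattrs["v_hold_pre_mV"]),
            v_step_mV=float(pattrs["v_step_mV"]),
            v_hold_post_mV=float(pattrs["v_hold_post_mV"]),
            artifact_blank_ms=float(
                pattrs.get("artifact_blank_ms", DEFAULT_ARTIFACT_BLANK_MS)
            ),
        )
        if defaulted:
            meta["artifact_blank_defaulted"] = True
        try:
            return SweepSet(
                traces=traces,
                sampling_rate_Hz=float(pattrs["sampling_rate_Hz"]),
                protocol=protocol,
                meta=meta,
            )
        except ValueError as exc:
            raise SweepSetFormatError(f"{path}: {exc}") from exc


def write_pair_recording(rec: PairRecording, path: str | Path) -> None:
    """Write a :class:`PairRecording` (sweeps + pair metadata) to HDF5."""
    sweeps = SweepSet(
        traces=rec.sweeps.traces,
        sampling_rate_Hz=rec.sweeps.sampling_rate_Hz,
        protocol=rec.sweeps.protocol,
        meta={
            **rec.sweeps.meta,
            "pre_cell_id": rec.pre_cell_id,
            "post_cell_id": rec.post_cell_id,
            "distance_um": rec.distance_um,
            "genotype": rec.genotype,
            "age_group": rec.age_group,
        },
    )
    write_sweepset(sweeps, path)


def read_pair_recording(path: str | Path) -> PairRecording:
    sweeps = read_sweepset(path)
    meta = sweeps.meta
    for key in ("pre_cell_id", "post_cell_id", "distance_um", "genotype", "age_group"):
        if key not in meta:
            raise SweepSetFormatError(f"{path}: missing pair field '{key}'")
    return PairRecording(
        pre_cell_id=str(meta["pre_cell_id"]),
        post_cell_id=str(meta["post_cell_id"]),
        distance_um=float(meta["distance_um"]),
        genotype=str(meta["genotype"]),
        age_group=str(meta["age_group"]),
        sweeps=sweeps,
    )


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def export_results_table(
    results: Sequence[Any], path: str | Path, kind: str | None = None
) -> None:
    """Write a homogeneous list of result dataclasses to a CSV table.

    One row per result, header row always present; float formatting is fixed
    (``%.8g``) so re-export of identical input is byte-identical. ``kind``
    names the result type for an empty list (``"detection"`` or ``"tuning"``).
    """
    kinds = {type(r).__name__ for r in results}
    if len(kinds) > 1:
        raise ValueError(f"mixed result kinds in one table: {sorted(kinds)}")
    rows = []
    for r in results:
        row: dict[str, Any] = {}
        for f_ in dataclasses.fields(r):
            value = getattr(r, f_.name)
            if isinstance(value, dict):
                for k, v in value.items():
                    row[f"{f_.name}_{k}"] = v
            elif isinstance(value, np.ndarray):
                row[f_.name] = json.dumps(value.tolist())
            else:
                row[f_.name] = value
        rows.append(row)
    if rows:
        df = pd.DataFrame(rows)
    else:
        columns = _EMPTY_COLUMNS.get(kind or "detection")
        if columns is None:
            raise ValueError(f"unknown result kind {kind!r} for empty export")
        df = pd.DataFrame(columns=columns)
    df.to_csv(path, index=False, float_format="%.8g")


_EMPTY_COLUMNS = {
    "detection": [f.name for f in dataclasses.fields(DetectionResult)],
    "tuning": [
        "cell_id",
        "dsi_magnitude",
        "preferred_angle_deg",
        "deviation_from_ventral_deg",
        "ventral_projection",
    ],
}
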