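"""Seeded generators for synthetic recordings, spike trains, mosaics, and
connectivity tables.

These emulate the statistical structure the analysis stages assume:
GABAergic postsynaptic currents (~7 ms latency, ~15 pA synaptic / ~20 pA
autaptic) riding on Gaussian baseline noise; depolarization-evoked intrinsic
transients decaying within 100 ms; von-Mises-tuned Poisson spike trains for
8 motion directions; exclusion-zone mosaics; and distance/genotype/age
structured connection probabilities. Every generator is a pure function of
(parameters, seed), and planted ground truth is emitted in metadata so
recovery tests never need to re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .mosaic import Mosaic
from .recordings import (
    AGE_GROUPS,
    GENOTYPES,
    PairRecording,
    StimulusProtocol,
    SweepSet,
)
from .tuning import DEFAULT_AXES, DIRECTIONS_DEG, SpikeTrainSet


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSCParams:
    """Difference-of-exponentials postsynaptic-current waveform parameters.

    Defaults follow the recorded SAC–SAC currents: ~15 pA peak at ~7 ms
    latency; kinetics (τ_rise 1 ms, τ_decay 20 ms) give a 10–90 % rise time
    under 4 ms. Trial-to-trial variability is a 20 % CV on amplitude with a
    10 % failure rate.
    """

    amplitude_pA: float = 15.0
    latency_ms: float = 7.0
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 20.0
    failure_prob: float = 0.1
    amp_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.amplitude_pA < 0:
            raise ValueError("amplitude_pA must be >= 0")
        if not self.tau_decay_ms > self.tau_rise_ms > 0:
            raise ValueError("require tau_decay_ms > tau_rise_ms > 0")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValueError("failure_prob must be in [0, 1]")

    @property
    def time_to_peak_ms(self) -> float:
        """Closed-form argmax of the difference of exponentials (after onset)."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return math.log(td / tr) * td * tr / (td - tr)


@dataclass(frozen=True)
class IntrinsicParams:
    """Double-exponential intrinsic transient after strong depolarization.

    The modeled transient must fall below 5 % of its peak within 100 ms of
    the return to the holding potential.
    """

    A1_pA: float = 200.0
    tau1_ms: float = 5.0
    A2_pA: float = 50.0
    tau2_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.tau1_ms <= 0 or self.tau2_ms <= 0:
            raise ValueError("time constants must be > 0")
        peak = self.value(0.0)
        if peak > 0 and self.value(100.0) >= 0.05 * peak:
            raise ValueError("intrinsic transient must decay to <5% of peak by 100 ms")

    def value(self, t_ms: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        out = self.A1_pA * np.exp(-t / self.tau1_ms) + self.A2_pA * np.exp(
            -t / self.tau2_ms
        )
        return float(out) if np.isscalar(t_ms) else out


@dataclass(frozen=True)
class TuningParams:
    """Von-Mises-shaped directional rate modulation.

    Expected ON peak rate in direction θ is
    ``baseline + peak · exp(κ (cos(θ − µ) − 1))``; the OFF response is the
    same shape scaled by ``on_off_gain``.
    """

    preferred_angle_deg: float = 270.0
    kappa: float = 2.0
    peak_rate_Hz: float = 100.0
    baseline_rate_Hz: float = 2.0
    on_off_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.peak_rate_Hz < 0 or self.baseline_rate_Hz < 0:
            raise ValueError("rates must be >= 0")

    def rate_Hz(self, theta_deg: float, epoch: str = "on") -> float:
        gain = 1.0 if epoch == "on" else self.on_off_gain
        mod = math.exp(
            self.kappa
            * (math.cos(math.radians(theta_deg - self.preferred_angle_deg)) - 1.0)
        )
        return self.baseline_rate_Hz + gain * self.peak_rate_Hz * mod


_DEFAULT_P_CONNECT: dict[str, dict[str, dict[str, float]]] = {
    # near = [35, 100) um, far = [100, 175] um.  Controls lose proximal
    # connections with age; Pcdhg0 retains them; Pcdhg1 connects at ~20 %
    # of control frequency at both ages.
    "Pcdhg22": {
        "juvenile": {"near": 0.60, "far": 0.25},
        "adult": {"near": 0.10, "far": 0.30},
    },
    "Pcdhg0": {
        "juvenile": {"near": 0.60, "far": 0.25},
        "adult": {"near": 0.60, "far": 0.30},
    },
    "Pcdhg1": {
        "juvenile": {"near": 0.12, "far": 0.05},
        "adult": {"near": 0.02, "far": 0.06},
    },
}


@dataclass
class PopulationModel:
    """Programmed connection/autapse probabilities for a simulated cohort."""

    p_connect: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            g: {a: dict(bins) for a, bins in ages.items()}
            for g, ages in _DEFAULT_P_CONNECT.items()
        }
    )
    distance_range_um: tuple[float, float] = (35.0, 175.0)
    near_far_boundary_um: float = 100.0
    autapse_prob: dict[str, float] = field(
        default_factory=lambda: {"Pcdhg22": 0.0, "Pcdhg0": 0.75, "Pcdhg1": 0.0}
    )
    dendritic_radius_um: float = 100.0
    amplitude_mean_pA: dict[str, float] = field(
        default_factory=lambda: {"Pcdhg22": 15.0, "Pcdhg0": 15.0, "Pcdhg1": 6.0}
    )
    amplitude_cv: float = 0.2

    def __post_init__(self) -> None:
        for g, ages in self.p_connect.items():
            for a, bins in ages.items():
                for b, p in bins.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"p_connect[{g}][{a}][{b}] = {p} outside [0, 1]"
                        )
        for g, p in self.autapse_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"autapse_prob[{g}] = {p} outside [0, 1]")
        lo, hi = self.distance_range_um
        if not 0 <= lo < hi:
            raise ValueError("invalid distance range")

    def lookup_p(self, distance_um: float, genotype: str, age_group: str) -> float:
        bin_label = "near" if distance_um < self.near_far_boundary_um else "far"
        try:
            return self.p_connect[genotype][age_group][bin_label]
        except KeyError as exc:
            raise KeyError(
                f"p_connect table missing cell ({bin_label}, {genotype}, {age_group})"
            ) from exc


# ---------------------------------------------------------------------------
# Waveforms and recordings
# ---------------------------------------------------------------------------

def simulate_psc_waveform(
    params: PSCParams,
    t0_ms: float,
    sampling_rate_Hz: float,
    duration_ms: float,
    amplitude_pA: float | None = None,
) -> np.ndarray:
    """Noiseless difference-of-exponentials PSC, peak-normalized.

    The event rises from zero at ``t0_ms + latency_ms`` and peaks at exactly
    ``amplitude_pA`` (outward positive). ``amplitude_pA`` overrides the
    parameter amplitude for per-trial jitter.
    """
    amp = params.amplitude_pA if amplitude_pA is None else amplitude_pA
    onset = t0_ms + params.latency_ms
    if duration_ms < onset + 5 * params.tau_decay_ms:
        raise ValueError(
            "duration must cover t0 + latency + 5 tau_decay "
            f"(need >= {onset + 5 * params.tau_decay_ms:.1f} ms)"
        )
    n = int(round(duration_ms * sampling_rate_Hz / 1000.0))
    t = np.arange(n) * (1000.0 / sampling_rate_Hz)
    s = t - onset
    out = np.zeros(n)
    if amp == 0:
        return out
    tr, td = params.tau_rise_ms, params.tau_decay_ms
    pos = s >= 0
    shape = np.exp(-s[pos] / td) - np.exp(-s[pos] / tr)
    s_peak = params.time_to_peak_ms
    norm = math.exp(-s_peak / td) - math.exp(-s_peak / tr)
    out[pos] = amp * shape / norm
    return out


def simulate_paired_recording(
    connected: bool,
    psc: PSCParams = PSCParams(),
    noise_sd_pA: float = 2.0,
    n_trials: int = 10,
    protocol: StimulusProtocol | None = None,
    seed: int | np.random.Generator | None = None,
    distance_um: float = 70.0,
    genotype: str = "Pcdhg22",
    age_group: str = "juvenile",
    sampling_rate_Hz: float = 20_000.0,
    present_mask: Sequence[bool] | None = None,
    pre_cell_id: str = "pre",
    post_cell_id: str = "post",
) -> PairRecording:
    """One simulated directed paired test with planted ground truth.

    Each non-failure trial of a connected pair carries one PSC time-locked
    to the presynaptic step onset, with i.i.d. lognormal-free amplitude
    jitter (Gaussian CV, truncated at zero). ``present_mask`` forces the
    per-trial presence pattern when given. Ground truth (per-trial planted
    amplitudes, latency, kinetics, noise SD) is stored in sweep metadata.
    """
    if noise_sd_pA < 0:
        raise ValueError("noise_sd_pA must be >= 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed)
    protocol = protocol or StimulusProtocol.paired()
    duration_ms = (
        protocol.step_onset_ms + psc.latency_ms + 6 * psc.tau_decay_ms + 40.0
    )
    n = int(round(duration_ms * sampling_rate_Hz / 1000.0))
    traces = rng.normal(0.0, noise_sd_pA, size=(n_trials, n))
    amplitudes = np.zeros(n_trials)
    if connected:
        if present_mask is None:
            present = rng.random(n_trials) >= psc.failure_prob
        else:
            present = np.asarray(present_mask, dtype=bool)
            if present.size != n_trials:
                raise ValueError("present_mask length must equal n_trials")
        amps = psc.amplitude_pA * (1.0 + psc.amp_cv * rng.standard_normal(n_trials))
        amps = np.clip(amps, 0.0, None)
        for i in range(n_trials):
            if present[i] and amps[i] > 0:
                traces[i] += simulate_psc_waveform(
                    psc,
                    t0_ms=protocol.step_onset_ms,
                    sampling_rate_Hz=sampling_rate_Hz,
                    duration_ms=duration_ms,
                    amplitude_pA=amps[i],
                )
                amplitudes[i] = amps[i]
    sweeps = SweepSet(
        traces=traces,
        sampling_rate_Hz=sampling_rate_Hz,
        protocol=protocol,
        meta={
            "ground_truth": {
                "connected": bool(connected),
                "amplitudes_pA": amplitudes.tolist(),
                "latency_ms": psc.latency_ms,
                "tau_rise_ms": psc.tau_rise_ms,
                "tau_decay_ms": psc.tau_decay_ms,
                "noise_sd_pA": noise_sd_pA,
            }
        },
    )
    return PairRecording(
        pre_cell_id=pre_cell_id,
        post_cell_id=post_cell_id,
        distance_um=distance_um,
        genotype=genotype,
        age_group=age_group,
        sweeps=sweeps,
    )


def simulate_autapse_recording(
    has_autapse: bool,
    intrinsic: IntrinsicParams = IntrinsicParams(),
    psc: PSCParams = PSCParams(amplitude_pA=20.0),
    noise_sd_pA: float = 2.0,
    n_trials: int = 10,
    protocol: StimulusProtocol | None = None,
    seed: int | np.random.Generator | None = None,
    sampling_rate_Hz: float = 20_000.0,
    genotype: str = "Pcdhg0",
    age_group: str = "juvenile",
) -> SweepSet:
    """Simulated single-cell autapse test.

    Every trial carries the intrinsic double-exponential transient beginning
    at the return to the −20 mV holding potential; autaptic cells add an
    outward PSC whose latency is referenced to the start of the brief +60 mV
    step. Ground truth lives in metadata.
    """
    if noise_sd_pA < 0:
        raise ValueError("noise_sd_pA must be >= 0")
    rng = _rng(seed)
    protocol = protocol or StimulusProtocol.autaptic()
    return_ms = protocol.step_onset_ms + protocol.step_duration_ms
    duration_ms = return_ms + 100.0 + 6 * psc.tau_decay_ms
    n = int(round(duration_ms * sampling_rate_Hz / 1000.0))
    t = np.arange(n) * (1000.0 / sampling_rate_Hz)
    base = np.zeros(n)
    after = t >= return_ms
    base[after] = intrinsic.value(t[after] - return_ms)
    traces = base[None, :] + rng.normal(0.0, noise_sd_pA, size=(n_trials, n))
    amplitudes = np.zeros(n_trials)
    if has_autapse:
        amps = np.clip(
            psc.amplitude_pA * (1.0 + psc.amp_cv * rng.standard_normal(n_trials)),
            0.0,
            None,
        )
        for i in range(n_trials):
            if amps[i] > 0:
                traces[i] += simulate_psc_waveform(
                    psc,
                    t0_ms=protocol.step_onset_ms,
                    sampling_rate_Hz=sampling_rate_Hz,
                    duration_ms=duration_ms,
                    amplitude_pA=amps[i],
                )
                amplitudes[i] = amps[i]
    return SweepSet(
        traces=traces,
        sampling_rate_Hz=sampling_rate_Hz,
        protocol=protocol,
        meta={
            "genotype": genotype,
            "age_group": age_group,
            "ground_truth": {
                "has_autapse": bool(has_autapse),
                "amplitudes_pA": amplitudes.tolist(),
                "latency_ms": psc.latency_ms,
                "intrinsic": [
                    intrinsic.A1_pA,
                    intrinsic.tau1_ms,
                    intrinsic.A2_pA,
                    intrinsic.tau2_ms,
                ],
                "noise_sd_pA": noise_sd_pA,
            },
        },
    )


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def _piecewise_poisson(
    rng: np.random.Generator, segments: list[tuple[float, float, float]]
) -> np.ndarray:
    """Spike times from a piecewise-constant intensity (start, stop, rate_Hz)."""
    times: list[np.ndarray] = []
    for start, stop, rate in segments:
        if rate <= 0 or stop <= start:
            continue
        n = rng.poisson(rate * (stop - start) / 1000.0)
        if n:
            times.append(rng.uniform(start, stop, size=n))
    if not times:
        return np.empty(0)
    return np.unique(np.concatenate(times))


def simulate_direction_response(
    tuning: TuningParams = TuningParams(),
    directions_deg: Sequence[float] = DIRECTIONS_DEG,
    n_reps: int = 4,
    bar_speed_um_s: float = 1000.0,
    bar_width_um: float = 300.0,
    bar_length_um: float = 1000.0,
    lead_in_um: float = 200.0,
    seed: int | np.random.Generator | None = None,
    axis_convention: Mapping[str, float] | None = None,
) -> SpikeTrainSet:
    """Inhomogeneous-Poisson spike trains for a moving-bar protocol.

    ON and OFF epochs are derived from bar geometry: the ON epoch spans the
    leading edge's crossing of a receptive-field window the width of the bar
    (300 µm) centered on the soma, the OFF epoch the trailing edge's
    crossing, at the programmed speed. Expected ON rate in direction θ is
    ``baseline + peak · exp(κ (cos(θ − µ) − 1))``.
    """
    if len(directions_deg) == 0:
        raise ValueError("empty direction list")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _rng(seed)
    v = bar_speed_um_s / 1000.0  # um per ms
    on_start = lead_in_um / v
    on_stop = (lead_in_um + bar_width_um) / v
    off_start = on_start + bar_length_um / v
    off_stop = on_stop + bar_length_um / v
    duration = off_stop + 100.0
    spikes: dict[float, list[np.ndarray]] = {}
    epochs: dict[float, dict[str, tuple[float, float]]] = {}
    for theta in directions_deg:
        r_on = tuning.rate_Hz(theta, "on")
        r_off = tuning.rate_Hz(theta, "off")
        b = tuning.baseline_rate_Hz
        segs = [
            (0.0, on_start, b),
            (on_start, on_stop, r_on),
            (on_stop, off_start, b),
            (off_start, off_stop, r_off),
            (off_stop, duration, b),
        ]
        spikes[float(theta)] = [_piecewise_poisson(rng, segs) for _ in range(n_reps)]
        epochs[float(theta)] = {"on": (on_start, on_stop), "off": (off_start, off_stop)}
    return SpikeTrainSet(
        spikes=spikes,
        directions_deg=tuple(float(d) for d in directions_deg),
        epochs=epochs,
        sweep_duration_ms=duration,
        axis_convention=dict(axis_convention or DEFAULT_AXES),
        meta={
            "ground_truth": {
                "preferred_angle_deg": tuning.preferred_angle_deg,
                "kappa": tuning.kappa,
                "peak_rate_Hz": tuning.peak_rate_Hz,
                "baseline_rate_Hz": tuning.baseline_rate_Hz,
                "on_off_gain": tuning.on_off_gain,
            }
        },
    )


# ---------------------------------------------------------------------------
# Mosaics and connectivity tables
# ---------------------------------------------------------------------------

class MosaicInfeasibleError(RuntimeError):
    """Raised when sequential-inhibition sampling cannot place all points."""


def simulate_mosaic(
    density_per_mm2: float,
    exclusion_radius_um: float,
    field_um: tuple[float, float] | float,
    seed: int | np.random.Generator | None = None,
    max_attempts_per_point: int = 10_000,
    cell_type_label: str = "",
) -> Mosaic:
    """Hard-core mosaic by random sequential adsorption.

    Points are placed uniformly, rejecting any candidate within the
    exclusion radius of an accepted point. With exclusion 0 this is a
    homogeneous Poisson (binomial) sample at the target density.
    """
    if np.isscalar(field_um):
        field_um = (float(field_um), float(field_um))
    w, h = field_um
    rng = _rng(seed)
    n_target = int(round(density_per_mm2 * w * h * 1e-6))
    if n_target < 1:
        raise ValueError("density and field give < 1 expected point")
    pts: list[np.ndarray] = []
    r2 = exclusion_radius_um**2
    for _ in range(n_target):
        for attempt in range(max_attempts_per_point):
            cand = rng.uniform((0.0, 0.0), (w, h))
            if r2 == 0 or not pts:
                pts.append(cand)
                break
            arr = np.asarray(pts)
            if np.min(((arr - cand) ** 2).sum(axis=1)) >= r2:
                pts.append(cand)
                break
        else:
            raise MosaicInfeasibleError(
                f"placed {len(pts)} of {n_target} points before exhausting "
                f"{max_attempts_per_point} attempts; density incompatible with "
                f"exclusion radius {exclusion_radius_um} um"
            )
    return Mosaic(
        points=np.asarray(pts),
        field_extent_um=(w, h),
        cell_type_label=cell_type_label,
        meta={
            "ground_truth": {
                "density_per_mm2": density_per_mm2,
                "exclusion_radius_um": exclusion_radius_um,
            }
        },
    )


def simulate_population_connectivity(
    model: PopulationModel,
    n_pairs: int,
    seed: int | np.random.Generator | None = None,
    genotype: str = "Pcdhg22",
    age_group: str = "juvenile",
) -> pd.DataFrame:
    """Directed connectivity table for ``n_pairs`` simulated pairs.

    Each pair draws a soma distance uniformly from the model's range and two
    independent directed Bernoulli connections at the programmed probability
    for its (distance bin, genotype, age). Connected directions get a peak
    amplitude from the genotype's amplitude distribution. The programmed
    probability is recorded per row (``p_true``).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if genotype not in GENOTYPES or age_group not in AGE_GROUPS:
        raise ValueError("unknown genotype or age group")
    rng = _rng(seed)
    lo, hi = model.distance_range_um
    distances = rng.uniform(lo, hi, size=n_pairs)
    p = np.array([model.lookup_p(d, genotype, age_group) for d in distances])
    conn_ab = rng.random(n_pairs) < p
    conn_ba = rng.random(n_pairs) < p
    amp_mean = model.amplitude_mean_pA[genotype]
    amps_ab = np.where(
        conn_ab,
        np.clip(
            amp_mean * (1 + model.amplitude_cv * rng.standard_normal(n_pairs)), 0, None
        ),
        np.nan,
    )
    amps_ba = np.where(
        conn_ba,
        np.clip(
            amp_mean * (1 + model.amplitude_cv * rng.standard_normal(n_pairs)), 0, None
        ),
        np.nan,
    )
    return pd.DataFrame(
        {
            "pair_id": [f"{genotype}_{age_group}_{i:05d}" for i in range(n_pairs)],
            "distance_um": distances,
            "genotype": genotype,
            "age_group": age_group,
            "tested_AB": True,
            "connected_AB": conn_ab,
            "tested_BA": True,
            "connected_BA": conn_ba,
            "peak_pA_AB": amps_ab,
            "peak_pA_BA": amps_ba,
            "p_true": p,
        }
    )
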