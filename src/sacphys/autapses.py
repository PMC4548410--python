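"""Autapse detection by double-exponential fitting and residual thresholds.

A brief depolarization to +60 mV followed by a return to −20 mV evokes an
intrinsic transient that decays within 100 ms. The first 30 ms of the
averaged trace after the return is fit with a double exponential; residuals
of the fit exceeding 2 SDs of the pre-stimulus baseline mark candidate
autaptic currents, which must then pass the same three criteria used for
synaptic connections, applied to the residual trace. Latency is referenced
to the beginning of the brief step to +60 mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import connections as conn
from .recordings import DetectionResult, SweepSet

FIT_WINDOW_MS = 30.0
#: the intrinsic model is fit over up to this much of the post-return decay
#: (criteria are still evaluated on the first 30 ms): the near-flat tail,
#: where any synaptic event has decayed, pins the slow component and offset
#: that a 30 ms window cannot identify once an event rides on the transient
INTRINSIC_FIT_WINDOW_MS = 100.0
#: averaged traces more inward (negative) than this are flagged as saturated
#: by calcium-like currents and excluded from classification
INWARD_SATURATION_PA = -500.0


@dataclass
class DoubleExpFit:
    """offset + A1·exp(−t/τ1) + A2·exp(−t/τ2) over the fit window."""

    A1_pA: float
    tau1_ms: float
    A2_pA: float
    tau2_ms: float
    offset_pA: float
    residual_trace: np.ndarray
    converged: bool
    rss: float

    def __post_init__(self) -> None:
        if self.converged and (self.tau1_ms <= 0 or self.tau2_ms <= 0):
            raise ValueError("fitted time constants must be > 0")

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        return _double_exp(
            np.asarray(t_ms, dtype=float),
            self.A1_pA,
            self.tau1_ms,
            self.A2_pA,
            self.tau2_ms,
            self.offset_pA,
        )


def _double_exp(t, A1, tau1, A2, tau2, offset):
    return offset + A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2)


def _peeling_init(t: np.ndarray, y: np.ndarray) -> list[float]:
    """Log-linear 'peeling' initialization: fit the tail for the slow
    component, then the early remainder for the fast one."""
    n = t.size
    tail = slice(2 * n // 3, n)
    y_tail = y[tail]
    offset0 = float(min(y_tail.min(), y[-1]))
    slow = y[tail] - offset0
    mask = slow > 0
    if mask.sum() >= 2:
        b, a = np.polyfit(t[tail][mask], np.log(slow[mask]), 1)
        tau2 = -1.0 / b if b < 0 else (t[-1] - t[0])
        A2 = float(np.exp(a))
    else:
        tau2, A2 = (t[-1] - t[0]), max(float(y[0] - offset0), 1e-6)
    tau2 = float(np.clip(tau2, 1e-3, 10 * (t[-1] - t[0])))
    rem = y - offset0 - A2 * np.exp(-t / tau2)
    head = slice(0, max(4, n // 5))
    fast = rem[head]
    mask = fast > 0
    if mask.sum() >= 2:
        b, a = np.polyfit(t[head][mask], np.log(fast[mask]), 1)
        tau1 = -1.0 / b if b < 0 else tau2 / 5
        A1 = float(np.exp(a))
    else:
        tau1, A1 = tau2 / 5, max(float(rem[0]), 1e-6)
    tau1 = float(np.clip(tau1, 1e-3, 10 * (t[-1] - t[0])))
    return [A1, tau1, A2, tau2, offset0]


def fit_double_exponential(
    trace_segment: np.ndarray,
    sampling_rate_Hz: float,
    n_restarts: int = 3,
    seed: int = 0,
    clip_threshold_pA: float | None = None,
    n_clip_iter: int = 3,
    fit_stride: int = 1,
) -> DoubleExpFit:
    """Least-squares double-exponential fit of a decay segment.

    The segment is the first 30 ms after the return to the holding
    potential, time origin at its first sample. Both component amplitudes
    are constrained non-negative: the intrinsic transient is a decaying
    outward current, and an unconstrained difference of exponentials could
    instead absorb a synaptic bump riding on the decay, erasing the very
    residual the classifier thresholds.

    When ``clip_threshold_pA`` is given, the fit is made robust to embedded
    synaptic events by iterative sigma-clipping: after each pass, samples
    whose outward residual exceeds the threshold are excluded and the
    remaining samples refit (up to ``n_clip_iter`` passes, always retaining
    at least ~30 samples so the decay stays identifiable — an event with a
    slow decay can legitimately contaminate most of the window). The
    returned residual is always computed on the full segment against the
    final parameters, so a clipped event appears in it at full size.
    ``fit_stride`` decimates the samples used by the optimizer (the smooth
    exponential model needs far fewer than 20 kHz); residuals are always
    full-resolution.

    Initialization is by log-linear peeling with up to ``n_restarts``
    randomized retries; a fit that never converges is returned with
    ``converged=False`` (the cell is then excluded from classification).
    """
    y = np.asarray(trace_segment, dtype=float)
    t = np.arange(y.size) * (1000.0 / sampling_rate_Hz)
    span = float(t[-1] - t[0])
    scale = max(float(np.max(np.abs(y))), 1e-9)
    rng = np.random.default_rng(seed)
    lower = [0.0, 1e-4, 0.0, 1e-4, -10 * scale]
    upper = [10 * scale, 50 * span, 10 * scale, 50 * span, 10 * scale]

    stride_mask = np.zeros(y.size, dtype=bool)
    stride_mask[:: max(1, fit_stride)] = True

    def _fit_once(mask: np.ndarray) -> np.ndarray | None:
        sel = mask & stride_mask
        if sel.sum() < 10:
            sel = mask
        p0 = _peeling_init(t[sel], y[sel])
        for _ in range(n_restarts + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _double_exp,
                        t[sel],
                        y[sel],
                        p0=np.clip(p0, lower, upper),
                        bounds=(lower, upper),
                        xtol=1e-10,
                        maxfev=2000,
                    )
                return popt
            except RuntimeError:
                jitter = 1.0 + 0.3 * rng.standard_normal(5)
                p0 = [p * j for p, j in zip(_peeling_init(t[sel], y[sel]), jitter)]
        return None

    min_keep = min(y.size, max(30, y.size // 20))
    mask = np.ones(y.size, dtype=bool)
    popt = _fit_once(mask)
    if popt is not None and clip_threshold_pA is not None:
        for _ in range(n_clip_iter):
            resid = y - _double_exp(t, *popt)
            new_mask = resid <= clip_threshold_pA
            if new_mask.sum() < min_keep or np.array_equal(new_mask, mask):
                break
            mask = new_mask
            refit = _fit_once(mask)
            if refit is None:
                break
            popt = refit
    if popt is None:
        return DoubleExpFit(
            A1_pA=np.nan,
            tau1_ms=np.nan,
            A2_pA=np.nan,
            tau2_ms=np.nan,
            offset_pA=np.nan,
            residual_trace=np.full_like(y, np.nan),
            converged=False,
            rss=np.nan,
        )
    resid = y - _double_exp(t, *popt)
    return DoubleExpFit(
        A1_pA=float(popt[0]),
        tau1_ms=float(popt[1]),
        A2_pA=float(popt[2]),
        tau2_ms=float(popt[3]),
        offset_pA=float(popt[4]),
        residual_trace=resid,
        converged=True,
        rss=float(np.sum(resid[mask] ** 2)),
    )


def _residual_pseudotrace(
    sweeps: SweepSet, trace: np.ndarray, residual: np.ndarray, base_mean: float
) -> np.ndarray:
    """Embed a fit residual back into sweep time for the criteria machinery.

    Pre-stimulus samples keep the raw trace (supplying real baseline noise),
    the step itself is held at the baseline mean, and the post-return
    segment carries baseline + residual.
    """
    p = sweeps.protocol
    i_on = sweeps.index_at(p.step_onset_ms)
    i_ret = sweeps.index_at(p.step_onset_ms + p.step_duration_ms)
    out = np.full(i_ret + residual.size, base_mean)
    out[:i_on] = trace[:i_on]
    out[i_ret:] = base_mean + residual
    return out


def detect_autapse(sweeps: SweepSet, sustain_ms: float = conn.SUSTAIN_MS) -> DetectionResult:
    """Residual-threshold autapse classifier for one cell.

    The averaged post-return segment is fit with a double exponential; the
    cell is a candidate when the residual exceeds 2 pre-stimulus-baseline
    SDs (outward). Candidates must then pass the connection criteria on the
    residual trace: residual peak (criterion 1), sustained per-trial
    residual excursions in >= 80 % of trials (criterion 2), and latency
    < 12 ms from the start of the +60 mV step with a 10-90 % rise < 4 ms
    (criterion 3).

    Per-trial residuals subtract the one intrinsic model fitted to the
    averaged trace: the intrinsic transient is trial-invariant, and
    refitting each noisy trial would absorb the event's own decay into the
    fit, shrinking the very residual the criterion thresholds.
    """
    p = sweeps.protocol
    mean_trace, base_mean, base_sd = conn.average_sweeps(sweeps)
    if base_sd == 0.0:
        raise ValueError("zero-variance pre-stimulus baseline")
    return_ms = p.step_onset_ms + p.step_duration_ms
    i_ret = sweeps.index_at(return_ms)
    i_end = sweeps.index_at(return_ms + FIT_WINDOW_MS)
    if i_end > sweeps.n_samples:
        raise ValueError("sweep too short for the 30 ms fit window")
    i_fit_end = min(sweeps.n_samples, sweeps.index_at(return_ms + INTRINSIC_FIT_WINDOW_MS))
    n_crit = i_end - i_ret
    segment = mean_trace[i_ret:i_fit_end]

    # saturation guard: cells dominated by large inward currents
    if float(segment.min()) < INWARD_SATURATION_PA:
        return DetectionResult(
            verdict=False,
            peak_pA=None,
            latency_ms=None,
            rise_10_90_ms=None,
            trial_fraction=None,
            criteria={"peak": False, "presence": False, "kinetics": False},
            baseline_sd_pA=base_sd,
            baseline_mean_pA=base_mean,
            anomaly=True,
            cell_id=str(sweeps.meta.get("cell_id", "")),
        )

    fit = fit_double_exponential(
        segment,
        sweeps.sampling_rate_Hz,
        clip_threshold_pA=conn.PEAK_SD_CRITERION * base_sd,
        fit_stride=4,
        n_clip_iter=6,
    )
    if not fit.converged:
        return DetectionResult(
            verdict=False,
            peak_pA=None,
            latency_ms=None,
            rise_10_90_ms=None,
            trial_fraction=None,
            criteria={"peak": False, "presence": False, "kinetics": False},
            baseline_sd_pA=base_sd,
            baseline_mean_pA=base_mean,
            anomaly=True,
            cell_id=str(sweeps.meta.get("cell_id", "")),
        )

    crit_residual = fit.residual_trace[:n_crit]
    resid_peak = float(crit_residual.max())
    candidate = resid_peak >= conn.PEAK_SD_CRITERION * base_sd

    latency: float | None = None
    rise: float | None = None
    fraction: float | None = None
    crit_presence = False
    crit_kinetics = False
    if candidate:
        intrinsic_model = fit.predict(np.arange(n_crit) * sweeps.dt_ms)
        fraction = _residual_presence_fraction(
            sweeps, i_ret, i_end, sustain_ms, intrinsic_model
        )
        crit_presence = fraction >= conn.PRESENCE_FRACTION_CRITERION
        pseudo = _residual_pseudotrace(sweeps, mean_trace, crit_residual, base_mean)
        try:
            latency = conn.measure_latency(
                pseudo,
                sweeps.sampling_rate_Hz,
                p.step_onset_ms,
                artifact_blank_ms=p.artifact_blank_ms,
                search_window_ms=FIT_WINDOW_MS,
            )
            rise = conn.measure_rise_time(
                pseudo,
                sweeps.sampling_rate_Hz,
                p.step_onset_ms,
                artifact_blank_ms=p.artifact_blank_ms,
                search_window_ms=FIT_WINDOW_MS,
            )
            crit_kinetics = (
                0.0 <= latency < conn.LATENCY_MAX_MS and rise < conn.RISE_MAX_MS
            )
        except conn.FitError:
            crit_kinetics = False

    criteria = {
        "peak": bool(candidate),
        "presence": bool(crit_presence),
        "kinetics": bool(crit_kinetics),
    }
    return DetectionResult(
        verdict=all(criteria.values()),
        peak_pA=resid_peak,
        latency_ms=latency,
        rise_10_90_ms=rise,
        trial_fraction=fraction,
        criteria=criteria,
        baseline_sd_pA=base_sd,
        baseline_mean_pA=base_mean,
        anomaly=False,
        cell_id=str(sweeps.meta.get("cell_id", "")),
    )


def _residual_presence_fraction(
    sweeps: SweepSet,
    i_ret: int,
    i_end: int,
    sustain_ms: float,
    intrinsic_model: np.ndarray,
) -> float:
    """Per-trial residual presence against the shared intrinsic model.

    Each trial's post-return segment minus the averaged-trace intrinsic fit
    is tested for an outward excursion >= 2 per-trial-baseline SDs
    sustained >= ``sustain_ms``.
    """
    p = sweeps.protocol
    i_b0 = sweeps.index_at(p.step_onset_ms - conn.BASELINE_WINDOW_MS)
    i_on = sweeps.index_at(p.step_onset_ms)
    run_len = max(1, int(np.ceil(sustain_ms / sweeps.dt_ms)))
    n_present = 0
    for trial in sweeps.traces:
        base = trial[i_b0:i_on]
        sd = float(base.std(ddof=1))
        if sd == 0.0:
            raise ValueError("zero-variance per-trial baseline")
        residual = trial[i_ret:i_end] - intrinsic_model
        above = residual >= conn.PEAK_SD_CRITERION * sd
        if conn._longest_run(above) >= run_len:
            n_present += 1
    return n_present / sweeps.n_trials


def classify_population(cells: list[SweepSet]) -> pd.DataFrame:
    """Per-genotype autapse frequency with binomial standard error.

    Each sweep set must carry ``meta['genotype']``. Returns one row per
    genotype with n, number autaptic, frequency p̂, and SE = √(p̂(1−p̂)/n).
    """
    if not cells:
        raise ValueError("no cells supplied")
    rows = []
    for sw in cells:
        genotype = sw.meta.get("genotype")
        if genotype is None:
            raise ValueError("cell missing meta['genotype']")
        rows.append({"genotype": genotype, "autaptic": detect_autapse(sw).verdict})
    df = pd.DataFrame(rows)
    out = []
    for genotype, grp in df.groupby("genotype", sort=True):
        n = len(grp)
        k = int(grp["autaptic"].sum())
        p_hat = k / n
        out.append(
            {
                "genotype": genotype,
                "n": n,
                "n_autaptic": k,
                "frequency": p_hat,
                "se": float(np.sqrt(p_hat * (1 - p_hat) / n)),
            }
        )
    return pd.DataFrame(out)
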