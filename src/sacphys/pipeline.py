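"""End-to-end orchestration: simulate cohorts, run every analysis stage,
and emit a consolidated, reproducible report bundle.

The report bundle is a pure function of (config, seed, package version):
per-stage RNG streams are derived from the config seed with fixed labels,
summary JSON is written with sorted keys, and the run log records the
config hash and per-stage status as JSON lines. A failing stage is isolated
— it is logged with a structured error and the remaining stages still run.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator
from scipy import stats

from . import __version__
from .autapses import classify_population
from .connections import benchmark_detector, detect_connection
from .connectivity import (
    amplitude_summary,
    connection_probability_by_distance,
    reciprocity_null,
)
from .mosaic import density_recovery_profile
from .synth import (
    PopulationModel,
    TuningParams,
    simulate_autapse_recording,
    simulate_direction_response,
    simulate_mosaic,
    simulate_paired_recording,
    simulate_population_connectivity,
)
from .tuning import analyze_tuning


class CohortConfig(BaseModel):
    genotype: Literal["Pcdhg22", "Pcdhg0", "Pcdhg1"]
    age_group: Literal["juvenile", "adult"]
    n_pairs: int = Field(50, ge=1)
    n_paired_recordings: int = Field(6, ge=0)
    n_autapse_cells: int = Field(6, ge=0)
    n_tuning_cells: int = Field(4, ge=0)


class MosaicConfig(BaseModel):
    density_per_mm2: float = Field(150.0, gt=0)
    exclusion_radius_um: float = Field(30.0, ge=0)
    field_um: float = Field(900.0, gt=0)
    bin_width_um: float = Field(10.0, gt=0)
    r_max_um: float = Field(150.0, gt=0)


class TuningConfig(BaseModel):
    kappa_by_genotype: dict[str, float] = Field(
        default_factory=lambda: {"Pcdhg22": 2.0, "Pcdhg0": 0.6, "Pcdhg1": 1.2}
    )
    angle_sd_deg_by_genotype: dict[str, float] = Field(
        default_factory=lambda: {"Pcdhg22": 10.0, "Pcdhg0": 45.0, "Pcdhg1": 12.0}
    )
    n_reps: int = Field(4, ge=1)


class PipelineConfig(BaseModel):
    seed: int = 0
    output_dir: str = "sacphys_report"
    cohorts: list[CohortConfig]
    reciprocity_n_sim: int = Field(20_000, ge=100)
    p_connect_override: dict[str, dict[str, dict[str, float]]] | None = None
    mosaic: MosaicConfig = Field(default_factory=MosaicConfig)
    tuning: TuningConfig = Field(default_factory=TuningConfig)

    @field_validator("p_connect_override")
    @classmethod
    def _probabilities_valid(cls, v):
        if v is None:
            return v
        for g, ages in v.items():
            for a, bins in ages.items():
                for b, p in bins.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"p_connect_override[{g}][{a}][{b}] = {p} outside [0, 1]"
                        )
        return v


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"invalid pipeline config {path}:\n{exc}") from exc


def _stage_seed(base: int, *labels: Any) -> np.random.Generator:
    """Deterministic per-stage RNG derived from the config seed."""
    digest = hashlib.sha256(
        ("|".join(str(x) for x in labels)).encode()
    ).digest()
    entropy = [base, int.from_bytes(digest[:8], "little")]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _round_floats(obj: Any, ndigits: int = 8) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def run_pipeline(config: str | Path | PipelineConfig, output_dir: str | None = None) -> dict:
    """Run every stage for every cohort and write the report bundle.

    Returns the summary dict (also written as ``summary.json``). Artifacts:
    per-cohort connectivity/detection/autapse/tuning CSVs, reciprocity JSON,
    per-genotype DRP JSON, a ``run_log.jsonl`` with stage status, and the
    consolidated ``summary.json`` keyed by genotype × age.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_f = open(log_path, "w")

    cfg_json = cfg.model_dump_json()
    config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()

    def log(stage: str, cohort: str, status: str, **extra: Any) -> None:
        log_f.write(
            json.dumps(
                {"stage": stage, "cohort": cohort, "status": status, **extra},
                sort_keys=True,
            )
            + "\n"
        )
        log_f.flush()

    model = PopulationModel()
    if cfg.p_connect_override:
        for g, ages in cfg.p_connect_override.items():
            for a, bins in ages.items():
                model.p_connect.setdefault(g, {}).setdefault(a, {}).update(bins)

    summary: dict[str, Any] = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash,
        "cohorts": {},
        "mosaics": {},
    }

    for cohort in cfg.cohorts:
        key = f"{cohort.genotype}:{cohort.age_group}"
        entry: dict[str, Any] = {}
        tag = f"{cohort.genotype}_{cohort.age_group}"

        # --- connectivity table, distance-binned p, reciprocity null
        try:
            rng = _stage_seed(cfg.seed, "connectivity", key)
            table = simulate_population_connectivity(
                model, cohort.n_pairs, seed=rng,
                genotype=cohort.genotype, age_group=cohort.age_group,
            )
            table.to_csv(out / f"connectivity_{tag}.csv", index=False,
                         float_format="%.8g")
            by_bin = connection_probability_by_distance(table)
            entry["connection_probability"] = {
                "bins": _round_floats(by_bin.to_dict(orient="records"))
            }
            try:
                amp = amplitude_summary(table)
                entry["amplitudes"] = _round_floats(amp.to_dict(orient="records"))
            except ValueError:
                entry["amplitudes"] = []
            null = reciprocity_null(
                table, n_sim=cfg.reciprocity_n_sim,
                seed=_stage_seed(cfg.seed, "reciprocity", key),
            )
            recip = {
                "p_hat": null.p_hat,
                "counts_observed": list(null.counts_observed),
                "null_means": list(null.null_means),
                "p_values": null.p_values,
                "p_values_mid": null.p_values_mid,
                "n_sim": null.n_sim,
                "degenerate": null.degenerate,
            }
            entry["reciprocity"] = _round_floats(recip)
            with open(out / f"reciprocity_{tag}.json", "w") as f:
                json.dump(_round_floats(recip), f, sort_keys=True, indent=2)
            log("connectivity", key, "ok", n_pairs=cohort.n_pairs)
        except Exception as exc:  # noqa: BLE001 — stage isolation by design
            entry["connectivity_error"] = repr(exc)
            log("connectivity", key, "error", error=repr(exc),
                trace=traceback.format_exc(limit=3))

        # --- paired-recording detection
        try:
            if cohort.n_paired_recordings:
                rng = _stage_seed(cfg.seed, "detection", key)
                results = []
                truths = []
                for i in range(cohort.n_paired_recordings):
                    connected = i % 2 == 0
                    rec = simulate_paired_recording(
                        connected, seed=rng,
                        genotype=cohort.genotype, age_group=cohort.age_group,
                        pre_cell_id=f"{tag}_pre{i}", post_cell_id=f"{tag}_post{i}",
                    )
                    truths.append(rec.sweeps.meta["ground_truth"]["connected"])
                    results.append(detect_connection(rec))
                df = pd.DataFrame(
                    {
                        "cell_id": [r.cell_id for r in results],
                        "ground_truth": truths,
                        "verdict": [r.verdict for r in results],
                        "peak_pA": [r.peak_pA for r in results],
                        "latency_ms": [r.latency_ms for r in results],
                        "rise_10_90_ms": [r.rise_10_90_ms for r in results],
                        "trial_fraction": [r.trial_fraction for r in results],
                    }
                )
                df.to_csv(out / f"detection_{tag}.csv", index=False,
                          float_format="%.8g")
                n_pos = sum(truths)
                hits = sum(r.verdict for r, t in zip(results, truths) if t)
                fps = sum(r.verdict for r, t in zip(results, truths) if not t)
                entry["detection"] = _round_floats(
                    {
                        "n": len(results),
                        "sensitivity": hits / n_pos if n_pos else None,
                        "false_positive_rate": fps / (len(truths) - n_pos)
                        if len(truths) > n_pos
                        else None,
                    }
                )
            log("detection", key, "ok")
        except Exception as exc:  # noqa: BLE001
            entry["detection_error"] = repr(exc)
            log("detection", key, "error", error=repr(exc))

        # --- autapse classification
        try:
            if cohort.n_autapse_cells:
                rng = _stage_seed(cfg.seed, "autapses", key)
                p_aut = model.autapse_prob.get(cohort.genotype, 0.0)
                cells = []
                for i in range(cohort.n_autapse_cells):
                    has = bool(rng.random() < p_aut)
                    sw = simulate_autapse_recording(
                        has, seed=rng, genotype=cohort.genotype,
                        age_group=cohort.age_group,
                    )
                    sw.meta["cell_id"] = f"{tag}_aut{i}"
                    cells.append(sw)
                freq = classify_population(cells)
                freq.to_csv(out / f"autapses_{tag}.csv", index=False,
                            float_format="%.8g")
                entry["autapses"] = _round_floats(freq.to_dict(orient="records"))
            log("autapses", key, "ok")
        except Exception as exc:  # noqa: BLE001
            entry["autapses_error"] = repr(exc)
            log("autapses", key, "error", error=repr(exc))

        # --- direction tuning
        try:
            if cohort.n_tuning_cells:
                rng = _stage_seed(cfg.seed, "tuning", key)
                kappa = cfg.tuning.kappa_by_genotype.get(cohort.genotype, 2.0)
                angle_sd = cfg.tuning.angle_sd_deg_by_genotype.get(
                    cohort.genotype, 10.0
                )
                rows = []
                for i in range(cohort.n_tuning_cells):
                    mu = 270.0 + angle_sd * rng.standard_normal()
                    sts = simulate_direction_response(
                        TuningParams(preferred_angle_deg=mu % 360.0, kappa=kappa),
                        n_reps=cfg.tuning.n_reps,
                        seed=rng,
                    )
                    tr = analyze_tuning(sts, cell_id=f"{tag}_cell{i}")
                    rows.append(
                        {
                            "cell_id": tr.cell_id,
                            "dsi": tr.dsi_magnitude,
                            "preferred_angle_deg": tr.preferred_angle_deg,
                            "deviation_from_ventral_deg": tr.deviation_from_ventral_deg,
                            "on_off_angle_difference_deg": tr.on_off_angle_difference_deg,
                            "ventral_projection": tr.ventral_projection,
                        }
                    )
                df = pd.DataFrame(rows)
                df.to_csv(out / f"tuning_{tag}.csv", index=False, float_format="%.8g")
                entry["tuning"] = _round_floats(
                    {
                        "n_cells": len(rows),
                        "dsi_values": [r["dsi"] for r in rows],
                        "mean_dsi": float(df["dsi"].mean()),
                        "mean_deviation_deg": float(
                            df["deviation_from_ventral_deg"].mean()
                        ),
                        "mean_ventral_projection": float(
                            df["ventral_projection"].mean()
                        ),
                    }
                )
            log("tuning", key, "ok")
        except Exception as exc:  # noqa: BLE001
            entry["tuning_error"] = repr(exc)
            log("tuning", key, "error", error=repr(exc))

        summary["cohorts"][key] = entry

    # --- one mosaic + DRP per genotype present
    for genotype in sorted({c.genotype for c in cfg.cohorts}):
        try:
            rng = _stage_seed(cfg.seed, "mosaic", genotype)
            mosaic = simulate_mosaic(
                cfg.mosaic.density_per_mm2,
                cfg.mosaic.exclusion_radius_um,
                cfg.mosaic.field_um,
                seed=rng,
                cell_type_label=genotype,
            )
            mosaic.to_csv(out / f"mosaic_{genotype}.csv")
            drp = density_recovery_profile(
                mosaic, bin_width_um=cfg.mosaic.bin_width_um,
                r_max_um=cfg.mosaic.r_max_um,
            )
            payload = _round_floats(
                {
                    "annulus_edges_um": drp.annulus_edges_um,
                    "densities_per_mm2": drp.densities_per_mm2,
                    "mean_density_per_mm2": drp.mean_density_per_mm2,
                    "effective_radius_um": drp.effective_radius_um,
                    "n_reference": drp.n_reference,
                }
            )
            with open(out / f"drp_{genotype}.json", "w") as f:
                json.dump(payload, f, sort_keys=True, indent=2)
            summary["mosaics"][genotype] = {
                "effective_radius_um": payload["effective_radius_um"],
                "mean_density_per_mm2": payload["mean_density_per_mm2"],
            }
            log("mosaic", genotype, "ok")
        except Exception as exc:  # noqa: BLE001
            summary["mosaics"][genotype] = {"error": repr(exc)}
            log("mosaic", genotype, "error", error=repr(exc))

    with open(out / "summary.json", "w") as f:
        json.dump(_round_floats(summary), f, sort_keys=True, indent=2)
    log_f.close()
    return summary


def compare_groups(
    summary: dict, contrast: tuple[str, str], metric: str = "dsi_values"
) -> dict[str, Any]:
    """Descriptive two-sample comparison of a per-cell metric between cohorts.

    ``contrast`` names two cohort keys (``"genotype:age_group"``); the
    p-value comes from a stock two-tailed t-test (Welch). Flagged as
    descriptive — the pipeline makes no multiplicity correction.
    """
    a_key, b_key = contrast
    values = []
    for key in contrast:
        cohort = summary["cohorts"].get(key)
        if cohort is None:
            raise KeyError(f"cohort {key!r} not in summary")
        tuning = cohort.get("tuning", {})
        if metric not in tuning:
            raise KeyError(f"metric {metric!r} not present for cohort {key!r}")
        values.append(np.asarray(tuning[metric], dtype=float))
    a, b = values
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both groups")
    if np.array_equal(a, b) and a.std() == 0:
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    return {
        "groups": list(contrast),
        "metric": metric,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "difference": float(a.mean() - b.mean()),
        "t_stat": float(t_stat),
        "p_value": float(p_value),
        "descriptive": True,
    }
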