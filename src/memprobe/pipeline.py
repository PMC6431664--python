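"""Stage orchestration: reproducible multi-stage runs from one config.

A run config (YAML mapping) selects stages and their inputs; outputs land
in one directory together with a provenance record (config hash, seed,
package version) and a merged JSON report.  When thermodynamic stages
run, a compound-level summary CSV (compound, K, dH, TdS, dG) is emitted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InputValidationError, SchemaError
from . import fluorometry as fl
from . import itc_partition as itc
from . import bilayer_analysis as ba
from . import bilayer_io
from . import synthetic_data as syn
from . import tables

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "gp", "anisotropy", "itc", "thermo", "bilayer")


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    stages: tuple[str, ...]
    out_dir: str
    seed: int = 0
    options: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stages:
            raise InputValidationError("empty stage list")
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise InputValidationError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError("run config must be a mapping")
        return cls(
            stages=tuple(raw.get("stages", ())),
            out_dir=str(raw.get("out_dir", "memprobe_out")),
            seed=int(raw.get("seed", 0)),
            options={k: v for k, v in raw.items() if k not in ("stages", "out_dir", "seed")},
        )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {"stages": config.stages, "seed": config.seed, "options": config.options},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _thermo_rows(entries: Sequence[Mapping]) -> pd.DataFrame:
    rows = []
    for e in entries:
        T_K = float(e.get("temperature_C", 26.0)) + 273.15
        th = itc.derive_thermodynamics(
            float(e["K_mM"]), float(e["dH_kJ_mol"]), T_K,
            float(e.get("standard_state_factor_M", itc.WATER_MOLARITY)),
        )
        rows.append({
            "compound": e.get("compound", "?"),
            "K_mM": float(e["K_mM"]),
            "dH_kJ_mol": float(e["dH_kJ_mol"]),
            "TdS_kJ_mol": th.TdS_kJ_mol,
            "dG_kJ_mol": th.dG_kJ_mol,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the merged report dict.

    Outputs are written under ``config.out_dir``; any stage failure
    raises with the stage named, after the partial report is flushed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "memprobe_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
        },
        "stages": {},
    }
    (out / "config_echo.yaml").write_text(yaml.safe_dump({
        "stages": list(config.stages), "out_dir": config.out_dir,
        "seed": config.seed, **dict(config.options),
    }))

    for stage in config.stages:
        opts = dict(config.options.get(stage, {}))
        try:
            report["stages"][stage] = _run_stage(stage, opts, config, out)
        except Exception:
            (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
            logger.error("stage %r failed", stage)
            raise
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _run_stage(stage: str, opts: dict, config: RunConfig, out: Path) -> dict:
    if stage == "simulate":
        return _stage_simulate(opts, config, out)
    if stage == "gp":
        return _stage_gp(opts, out)
    if stage == "anisotropy":
        return _stage_anisotropy(opts, out)
    if stage == "itc":
        return _stage_itc(opts, out)
    if stage == "thermo":
        df = _thermo_rows(opts.get("entries", ()))
        df.to_csv(out / "thermo_table.csv", index=False)
        return {"table": "thermo_table.csv", "rows": df.to_dict("records")}
    if stage == "bilayer":
        return _stage_bilayer(opts, out)
    raise InputValidationError(f"unknown stage {stage!r}")  # pragma: no cover


def _stage_simulate(opts: dict, config: RunConfig, out: Path) -> dict:
    kind = opts.get("kind", "gp")
    seed = int(opts.get("seed", config.seed))
    written: list[str] = []
    if kind == "gp":
        spec = syn.GPCurveSpec(seed=seed, **opts.get("spec", {}))
        syn.gen_gp_curve(spec).to_csv(out / "gp_plate.csv", index=False)
        written.append("gp_plate.csv")
    elif kind == "anisotropy":
        spec = syn.PolarizedQuadSpec(seed=seed, **opts.get("spec", {}))
        syn.gen_polarized_quad(spec).to_csv(out / "anisotropy_plate.csv", index=False)
        written.append("anisotropy_plate.csv")
    elif kind == "itc":
        spec = syn.ITCSpec(seed=seed, **opts.get("spec", {}))
        exp = syn.gen_itc_thermogram(spec)
        pd.DataFrame({
            "injection_index": np.arange(1, len(exp.heats) + 1),
            "heat": exp.heats,
        }).to_csv(out / "heats.csv", index=False)
        cfg = {
            "v_cell_ml": exp.V_cell_ml, "c_analyte_uM": exp.C_A0_uM,
            "c_lipid_syringe_mM": exp.C_syringe_mM,
            "temperature_C": exp.temperature_C,
            "injections": list(exp.schedule.volumes_ul),
            "discard_first": exp.schedule.discard_first,
            "interval_s": exp.schedule.interval_s,
            "heat_unit": exp.heat_unit,
        }
        (out / "itc_config.yaml").write_text(yaml.safe_dump(cfg))
        written += ["heats.csv", "itc_config.yaml"]
    elif kind == "bilayer":
        spec = syn.BilayerSpec(seed=seed, **opts.get("spec", {}))
        traj, topo = syn.gen_bilayer_frames(spec)
        bilayer_io.write_gro(out / "frames.gro", traj)
        bilayer_io.write_topology_json(out / "topology.json", topo)
        written += ["frames.gro", "topology.json"]
    else:
        raise InputValidationError(f"unknown simulate kind {kind!r}")
    return {"kind": kind, "seed": seed, "files": written}


def _stage_gp(opts: dict, out: Path) -> dict:
    df = tables.load_plate(opts["plate"])
    pairs = tables.gp_pairs_from_plate(df)
    rows = []
    tm_reports = {}
    for sample, plist in pairs.items():
        curve = fl.build_gp_curve(plist, composition_label=sample,
                                  method=opts.get("method", "mean_intensities"))
        for t, gp, sd in curve.points:
            rows.append({"sample_id": sample, "temperature_C": t, "GP": gp, "sd": sd})
        if opts.get("tm_report", True):
            try:
                est = fl.estimate_tm(curve)
                tm_reports[sample] = dataclasses.asdict(est)
            except fl.NoTransitionError as exc:
                tm_reports[sample] = {"error": str(exc)}
    pd.DataFrame(rows).to_csv(out / "gp.csv", index=False)
    (out / "tm.json").write_text(json.dumps(tm_reports, indent=2, default=float))
    return {"gp": "gp.csv", "tm": tm_reports}


def _stage_anisotropy(opts: dict, out: Path) -> dict:
    df = tables.load_plate(opts["plate"])
    quads = tables.quads_from_plate(df)
    rows = []
    for sample, qlist in quads.items():
        for q in qlist:
            res = fl.anisotropy(q)
            rows.append({"sample_id": sample, "temperature_C": q.temperature,
                         "r": res.r, "G": res.G})
    pd.DataFrame(rows).to_csv(out / "anisotropy.csv", index=False)
    return {"anisotropy": "anisotropy.csv", "n_samples": len(quads)}


def _stage_itc(opts: dict, out: Path) -> dict:
    cfg = tables.load_itc_config(opts["config"])
    if "trace" in opts:
        t, p = tables.load_trace_csv(opts["trace"])
        schedule = itc.InjectionSchedule(
            volumes_ul=tuple(float(v) for v in cfg["injections"]),
            discard_first=bool(cfg.get("discard_first", True)),
            interval_s=float(cfg.get("interval_s", 600.0)),
        )
        all_heats = itc.integrate_peaks(t, p, schedule,
                                        opts.get("baseline_mode", "linear"))
        heats = all_heats[schedule.retained_slice]
    else:
        heats = tables.load_heats_csv(opts["heats"])
    exp = tables.experiment_from_config(cfg, heats)
    mode = opts.get("mode", "dilution")
    fit = itc.fit_partition(exp, mode=mode)
    th = itc.derive_thermodynamics(
        fit.K_mM, fit.dH_kJ_mol, exp.temperature_K,
        float(opts.get("standard_state_factor_M", itc.WATER_MOLARITY)),
    )
    result = {
        "K_mM": fit.K_mM, "K_se": fit.K_se,
        "dH_kJ_mol": fit.dH_kJ_mol, "dH_se": fit.dH_se,
        "dG_kJ_mol": th.dG_kJ_mol, "TdS_kJ_mol": th.TdS_kJ_mol,
        "residual_norm": fit.residual_norm, "converged": fit.converged,
        "mode": mode, "standard_state_factor_M": th.standard_state_factor_M,
        "temperature_K": exp.temperature_K,
    }
    (out / "itc_fit.json").write_text(json.dumps(result, indent=2, default=float))
    df = _thermo_rows([{
        "compound": opts.get("compound", "sample"),
        "K_mM": fit.K_mM, "dH_kJ_mol": fit.dH_kJ_mol,
        "temperature_C": exp.temperature_C,
    }])
    df.to_csv(out / "thermo_table.csv", index=False)
    return result


def _stage_bilayer(opts: dict, out: Path) -> dict:
    path = str(opts["traj"])
    traj = bilayer_io.read_frames_xyz(path) if path.endswith(".xyz") else bilayer_io.read_gro(path)
    topo = bilayer_io.read_topology_json(opts["topo"])
    frac = float(opts.get("equilibration_fraction", 0.0))
    traj = ba.equilibration_split(traj, frac)
    result: dict[str, Any] = {}
    if "chain" in opts:
        prof = ba.order_parameters(traj, topo, opts["chain"],
                                   convention=opts.get("order_convention", "minus"))
        pd.DataFrame({
            "carbon_index": prof.carbon_indices,
            "minus_SCD": prof.values, "se": prof.se,
        }).to_csv(out / "order.csv", index=False)
        result["order"] = "order.csv"
    groups = opts.get("groups")
    if groups:
        zp = ba.z_profile(traj, topo, groups)
        pd.DataFrame({
            "group": zp.groups, "mean_abs_z_nm": zp.mean_abs_z_nm, "se": zp.se,
        }).to_csv(out / "zprofile.csv", index=False)
        result["zprofile"] = "zprofile.csv"
    thickness, se = ba.bilayer_thickness(traj, topo)
    (out / "thickness.json").write_text(json.dumps(
        {"thickness_nm": thickness, "se_nm": se}, indent=2))
    result["thickness_nm"] = thickness
    result["thickness_se_nm"] = se
    return result
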