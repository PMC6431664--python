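"""Delimited-table and config I/O for the fluorometry and ITC stages.

The plate schema is one row per instrument shot::

    sample_id, temperature_C, channel, intensity, is_blank, replicate

with ``channel`` one of em440/em490 (laurdan GP) or VV/VH/HV/HH (DPH
anisotropy).  Blank rows are matched to sample rows on
(sample_id, temperature_C, channel); blanks are averaged over replicates
and subtracted at the intensity level.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .fluorometry import EmissionPair, PolarizedQuad
from .itc_partition import InjectionSchedule, TitrationExperiment

__all__ = [
    "load_plate",
    "gp_pairs_from_plate",
    "quads_from_plate",
    "load_heats_csv",
    "load_trace_csv",
    "load_itc_config",
    "experiment_from_config",
]

PLATE_COLUMNS = ["sample_id", "temperature_C", "channel", "intensity", "is_blank", "replicate"]
GP_CHANNELS = ("em440", "em490")
POL_CHANNELS = ("VV", "VH", "HV", "HH")


def load_plate(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate table (CSV or TSV, sniffed by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plate table missing columns: {missing}")
    bad = set(df["channel"]) - set(GP_CHANNELS) - set(POL_CHANNELS)
    if bad:
        raise SchemaError(f"unknown channel labels: {sorted(bad)}")
    if not df["is_blank"].isin((0, 1)).all():
        raise SchemaError("is_blank must be 0 or 1")
    if not np.isfinite(df["intensity"]).all():
        raise SchemaError("non-finite intensities in plate table")
    return df


def _blank_means(df: pd.DataFrame) -> Mapping[tuple, float]:
    blanks = df[df["is_blank"] == 1]
    return blanks.groupby(["sample_id", "temperature_C", "channel"])["intensity"].mean().to_dict()


def _blank_subtracted(df: pd.DataFrame) -> pd.DataFrame:
    """Samples with the matched mean blank removed from each intensity."""
    blank = _blank_means(df)
    samples = df[df["is_blank"] == 0].copy()
    keys = list(zip(samples["sample_id"], samples["temperature_C"], samples["channel"]))
    samples["intensity"] = [
        inten - blank.get(k, 0.0) for k, inten in zip(keys, samples["intensity"])
    ]
    return samples


def gp_pairs_from_plate(df: pd.DataFrame) -> dict[str, list[EmissionPair]]:
    """Per-sample blank-subtracted emission pairs, one per replicate shot."""
    samples = _blank_subtracted(df[df["channel"].isin(GP_CHANNELS)])
    out: dict[str, list[EmissionPair]] = {}
    grouped = samples.pivot_table(
        index=["sample_id", "temperature_C", "replicate"],
        columns="channel", values="intensity", aggfunc="mean",
    )
    for ch in GP_CHANNELS:
        if ch not in grouped.columns:
            raise SchemaError(f"missing channel {ch} in GP table")
    if grouped[list(GP_CHANNELS)].isna().any().any():
        raise SchemaError("unpaired em440/em490 shots in GP table")
    for (sample, temp, _rep), row in grouped.iterrows():
        out.setdefault(str(sample), []).append(
            EmissionPair(I440=float(row["em440"]), I490=float(row["em490"]),
                         temperature=float(temp), replicate_count=1)
        )
    return out


def quads_from_plate(df: pd.DataFrame) -> dict[str, list[PolarizedQuad]]:
    """Per-sample polarized quads, replicates averaged at the intensity level."""
    samples = _blank_subtracted(df[df["channel"].isin(POL_CHANNELS)])
    if samples.empty:
        raise SchemaError("no polarized channels (VV/VH/HV/HH) in table")
    means = samples.groupby(["sample_id", "temperature_C", "channel"])["intensity"].mean()
    out: dict[str, list[PolarizedQuad]] = {}
    for (sample, temp), grp in means.groupby(level=[0, 1]):
        vals = grp.droplevel([0, 1])
        missing = [c for c in POL_CHANNELS if c not in vals.index]
        if missing:
            raise SchemaError(f"sample {sample} at {temp} C missing channels {missing}")
        out.setdefault(str(sample), []).append(PolarizedQuad(
            I_VV=float(vals["VV"]), I_VH=float(vals["VH"]),
            I_HV=float(vals["HV"]), I_HH=float(vals["HH"]),
            temperature=float(temp),
        ))
    return out


# ---------------------------------------------------------------------------
# ITC inputs
# ---------------------------------------------------------------------------

def load_heats_csv(path: str | Path) -> np.ndarray:
    """Two-column CSV (injection_index, heat) -> heats ordered by index."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError("heats CSV needs (injection_index, heat) columns")
    df = df.sort_values(df.columns[0])
    return df.iloc[:, 1].to_numpy(dtype=float)


def load_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column CSV (time_s, power) -> (time, power) arrays."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError("trace CSV needs (time_s, power) columns")
    return df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)


def load_itc_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise SchemaError("ITC config must be a mapping")
    return cfg


def experiment_from_config(cfg: Mapping, heats: np.ndarray) -> TitrationExperiment:
    """Assemble a :class:`TitrationExperiment` from a config mapping + heats.

    Required keys: v_cell_ml, c_analyte_uM, c_lipid_syringe_mM,
    temperature_C, injections (list of uL volumes); optional:
    discard_first (default true), interval_s (default 600),
    heat_unit (ucal|uJ, default ucal).
    """
    required = ["v_cell_ml", "c_analyte_uM", "c_lipid_syringe_mM", "temperature_C", "injections"]
    missing = [k for k in required if k not in cfg]
    if missing:
        raise SchemaError(f"ITC config missing keys: {missing}")
    schedule = InjectionSchedule(
        volumes_ul=tuple(float(v) for v in cfg["injections"]),
        discard_first=bool(cfg.get("discard_first", True)),
        interval_s=float(cfg.get("interval_s", 600.0)),
    )
    return TitrationExperiment(
        V_cell_ml=float(cfg["v_cell_ml"]),
        C_A0_uM=float(cfg["c_analyte_uM"]),
        C_syringe_mM=float(cfg["c_lipid_syringe_mM"]),
        schedule=schedule,
        heats=tuple(float(h) for h in heats),
        temperature_C=float(cfg["temperature_C"]),
        heat_unit=cfg.get("heat_unit", "ucal"),
    )
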