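"""Seeded generators emulating the three experiment types.

Each generator is the exact inverse of its analysis stage in the
noiseless limit: intensities are constructed so that the GP/anisotropy
formulas return the requested truth, thermograms are first differences
of the partition isotherm, and bilayer frames are bead-chain geometries
whose order parameters, z-profiles and thickness follow directly from
the construction.  Identical specs (same seed) give identical output.

The bilayer generator is a geometric stand-in, not a physical simulator:
chains are rigid all-trans zigzags whose tilt distribution interpolates
between perfectly aligned (order level ``s = 1``) and isotropic
(``s = 0``), which is exactly the degree of freedom the order-parameter
and thickness observables measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bilayer_analysis import BilayerFrame, SpeciesRoles, TopologyMap, Trajectory
from .errors import InputValidationError
from .itc_partition import (
    ConcMode,
    InjectionSchedule,
    TitrationExperiment,
    concentration_series,
    cumulative_heat_model,
    default_schedule,
)

__all__ = [
    "GPCurveSpec",
    "PolarizedQuadSpec",
    "ITCSpec",
    "BilayerSpec",
    "gen_gp_curve",
    "gen_polarized_quad",
    "gen_itc_thermogram",
    "gen_itc_trace",
    "gen_bilayer_frames",
    "make_all_trans_chain",
    "default_bilayer_topology",
]

# rigid zigzag geometry: C-C bond 0.153 nm, backbone half-angle ~35.25 deg
_BOND_NM = 0.153
_HALF_ANGLE = math.radians(35.25)
_DZ = _BOND_NM * math.cos(_HALF_ANGLE)      # rise per carbon along the axis
_RX = _BOND_NM * math.sin(_HALF_ANGLE) / 2  # lateral zigzag half-offset


# ---------------------------------------------------------------------------
# fluorometry generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPCurveSpec:
    """Truth for a sigmoidal GP melting curve.

    ``noise_sd`` is on the GP scale per shot; intensities are built so
    the blank-subtracted GP of each replicate equals truth + noise.
    """

    seed: int = 0
    Tm: float = 41.5            # degC, gel-to-fluid midpoint
    width: float = 0.7          # degC
    GP_gel: float = 0.55
    GP_fluid: float = -0.2
    temperatures: tuple[float, ...] = tuple(float(t) for t in range(31, 56, 2))
    replicates: int = 12
    noise_sd: float = 0.0
    total_intensity: float = 1000.0
    blank_level: float = 50.0
    sample_id: str = "synthetic"


def _logistic(t: np.ndarray, spec: GPCurveSpec) -> np.ndarray:
    return spec.GP_fluid + (spec.GP_gel - spec.GP_fluid) / (
        1.0 + np.exp((t - spec.Tm) / spec.width)
    )


def gen_gp_curve(spec: GPCurveSpec) -> pd.DataFrame:
    """Emit a plate table of replicated em440/em490 intensities plus blanks.

    Rows follow the standard plate schema (sample_id, temperature_C,
    channel, intensity, is_blank, replicate) so the output feeds the
    fluorometry reader unchanged.
    """
    t = np.asarray(spec.temperatures, dtype=float)
    if spec.Tm < t.min() or spec.Tm > t.max():
        import logging
        logging.getLogger(__name__).warning(
            "temperature grid [%s, %s] does not span Tm=%s", t.min(), t.max(), spec.Tm
        )
    rng = np.random.default_rng(spec.seed)
    truth = _logistic(t, spec)
    rows = []
    for temp, gp_true in zip(t, truth):
        for rep in range(1, spec.replicates + 1):
            gp = gp_true + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            gp = float(np.clip(gp, -1.0, 1.0))
            i440 = spec.total_intensity * (1.0 + gp) / 2.0
            i490 = spec.total_intensity * (1.0 - gp) / 2.0
            rows.append((spec.sample_id, temp, "em440", i440 + spec.blank_level, 0, rep))
            rows.append((spec.sample_id, temp, "em490", i490 + spec.blank_level, 0, rep))
        rows.append((spec.sample_id, temp, "em440", spec.blank_level, 1, 1))
        rows.append((spec.sample_id, temp, "em490", spec.blank_level, 1, 1))
    return pd.DataFrame(
        rows, columns=["sample_id", "temperature_C", "channel", "intensity", "is_blank", "replicate"]
    )


@dataclass(frozen=True)
class PolarizedQuadSpec:
    """Truth for one polarized-intensity quadruplet."""

    seed: int = 0
    r_true: float = 0.2
    G_true: float = 1.0
    temperature: float = 50.0
    total_intensity: float = 1000.0
    blank_level: float = 20.0
    replicates: int = 12
    noise_sd: float = 0.0       # additive, intensity units, per shot
    sample_id: str = "synthetic"


def gen_polarized_quad(spec: PolarizedQuadSpec) -> pd.DataFrame:
    """Plate table of VV/VH/HV/HH intensities consistent with (r_true, G_true).

    With I_VH = x, setting I_VV = G*x*(1+2r)/(1-r) makes the anisotropy
    formula return r exactly; I_HV = G*I_HH fixes the G-factor.  r = 1
    is realized with I_VH = 0.
    """
    if not (-0.5 < spec.r_true <= 1.0):
        raise InputValidationError("r_true must lie in (-0.5, 1]")
    if spec.G_true <= 0:
        raise InputValidationError("G_true must be > 0")
    rng = np.random.default_rng(spec.seed)
    ihh = spec.total_intensity / 4.0
    ihv = spec.G_true * ihh
    if spec.r_true == 1.0:
        ivh, ivv = 0.0, spec.total_intensity / 2.0
    else:
        ivh = spec.total_intensity / 8.0
        ivv = spec.G_true * ivh * (1.0 + 2.0 * spec.r_true) / (1.0 - spec.r_true)
    rows = []
    for channel, value in (("VV", ivv), ("VH", ivh), ("HV", ihv), ("HH", ihh)):
        for rep in range(1, spec.replicates + 1):
            noisy = value + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            rows.append((spec.sample_id, spec.temperature, channel,
                         noisy + spec.blank_level, 0, rep))
        rows.append((spec.sample_id, spec.temperature, channel, spec.blank_level, 1, 1))
    return pd.DataFrame(
        rows, columns=["sample_id", "temperature_C", "channel", "intensity", "is_blank", "replicate"]
    )


# ---------------------------------------------------------------------------
# ITC generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCSpec:
    """Truth for one lipid-into-solute titration.

    Defaults mirror the standard run: 1.4565 mL cell, a 2 uL discarded
    priming injection followed by 28 x 10 uL at 600 s spacing, 26 degC.
    ``noise_sd`` is multiplicative on per-injection heats.
    """

    seed: int = 0
    K_mM: float = 1.69
    dH_kJ_mol: float = 1.47
    V_cell_ml: float = 1.4565
    C_A0_uM: float = 75.0
    C_syringe_mM: float = 5.0
    schedule: InjectionSchedule = field(default_factory=default_schedule)
    temperature_C: float = 26.0
    mode: ConcMode = "dilution"
    noise_sd: float = 0.0


def gen_itc_thermogram(spec: ITCSpec) -> TitrationExperiment:
    """Per-injection heats from first differences of the partition isotherm."""
    series = concentration_series(
        spec.V_cell_ml, spec.C_A0_uM, spec.C_syringe_mM, spec.schedule, spec.mode
    )
    cum = cumulative_heat_model(spec.K_mM, spec.dH_kJ_mol, spec.V_cell_ml, series, "ucal")
    dh = np.diff(np.concatenate([[0.0], cum]))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dh = dh * (1.0 + rng.normal(0.0, spec.noise_sd, size=len(dh)))
    retained = dh[spec.schedule.retained_slice]
    return TitrationExperiment(
        V_cell_ml=spec.V_cell_ml,
        C_A0_uM=spec.C_A0_uM,
        C_syringe_mM=spec.C_syringe_mM,
        schedule=spec.schedule,
        heats=tuple(float(h) for h in retained),
        temperature_C=spec.temperature_C,
        heat_unit="ucal",
    )


def gen_itc_trace(
    spec: ITCSpec,
    peak_width_s: float = 20.0,
    baseline_ucal_s: float = 0.5,
    sampling_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the thermogram as a power trace of Gaussian injection peaks.

    Each injection contributes a Gaussian of area equal to its heat,
    centered ``3*peak_width_s`` after the injection time, on a flat
    baseline.  Returns (time_s, power) with power in ucal/s.
    """
    series = concentration_series(
        spec.V_cell_ml, spec.C_A0_uM, spec.C_syringe_mM, spec.schedule, spec.mode
    )
    cum = cumulative_heat_model(spec.K_mM, spec.dH_kJ_mol, spec.V_cell_ml, series, "ucal")
    dh = np.diff(np.concatenate([[0.0], cum]))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dh = dh * (1.0 + rng.normal(0.0, spec.noise_sd, size=len(dh)))
    dt = spec.schedule.interval_s
    n = spec.schedule.n_injections
    t = np.arange(0.0, n * dt, sampling_s)
    power = np.full_like(t, baseline_ucal_s)
    for k, h in enumerate(dh):
        center = k * dt + 3.0 * peak_width_s
        power += h / (peak_width_s * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((t - center) / peak_width_s) ** 2
        )
    return t, power


# ---------------------------------------------------------------------------
# bilayer generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BilayerSpec:
    """Geometric truth for synthetic bead-chain bilayer frames.

    ``order_level`` s in [0, 1] sets the chain tilt cone: axes are drawn
    uniformly in solid angle within a cone of half-angle (1-s)*90 deg
    about the bilayer normal, so s = 1 is all-trans along z (-S_CD = 0.5)
    and s = 0 is isotropic (-S_CD = 0).  ``head_separation_nm`` pins the
    P-plane distance; when None it follows the mean chain extent, so more
    ordered bilayers are thicker.
    """

    seed: int = 0
    n_lipids: int = 140
    chain_length: int = 16
    order_level: float = 1.0
    n_frames: int = 10
    head_separation_nm: float | None = None
    lipid_to_herbicide_ratio: float | None = None   # e.g. 5.0 -> 5:1
    herbicide_chain_length: int = 9
    herbicide_polar_depth_nm: float = 1.2           # |z_polar - z_COM|
    noise_sd: float = 0.0                            # rigid-body jitter, nm
    area_per_lipid_nm2: float = 0.64
    box_Lz_nm: float = 12.0
    frame_dt_ps: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_lipids <= 0 or self.n_lipids % 2:
            raise InputValidationError("n_lipids must be positive and even")
        if self.chain_length < 3:
            raise InputValidationError("chain_length must be >= 3")
        if not 0.0 <= self.order_level <= 1.0:
            raise InputValidationError("order_level must be in [0, 1]")


def make_all_trans_chain(n: int, axis_theta: float = 0.0, axis_phi: float = 0.0,
                         zigzag_phi: float = 0.0) -> np.ndarray:
    """Coordinates (nm) of a rigid all-trans zigzag of ``n`` carbons.

    Built along +z (first carbon at the origin) then rotated: the zigzag
    plane is first spun by ``zigzag_phi`` about the chain axis, then the
    axis is tilted by ``axis_theta`` from z and rotated by ``axis_phi``
    about z.
    """
    k = np.arange(n)
    pts = np.stack([_RX * (-1.0) ** k, np.zeros(n), k * _DZ], axis=1)
    pts = pts @ _rot_z(zigzag_phi).T
    pts = pts @ _rot_y(axis_theta).T
    pts = pts @ _rot_z(axis_phi).T
    return pts


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _cone_theta(rng: np.random.Generator, order_level: float) -> float:
    """Tilt drawn uniformly in solid angle within the order-level cone."""
    theta_max = (1.0 - order_level) * math.pi / 2.0
    u = rng.uniform(0.0, 1.0)
    cos_t = 1.0 - u * (1.0 - math.cos(theta_max))
    return math.acos(min(1.0, max(-1.0, cos_t)))


def default_bilayer_topology(spec: BilayerSpec) -> TopologyMap:
    """Topology sidecar matching :func:`gen_bilayer_frames` output."""
    chain = tuple(f"C{i}" for i in range(1, spec.chain_length + 1))
    species = {
        "LIP": SpeciesRoles(
            role="lipid",
            chains={"palmitoyl": chain},
            phosphorus="P",
            glycerol=("G",),
        )
    }
    if spec.lipid_to_herbicide_ratio:
        hchain = tuple(f"H{i}" for i in range(1, spec.herbicide_chain_length + 1))
        species["HRB"] = SpeciesRoles(
            role="herbicide",
            chains={"alkyl": hchain},
            polar=("OP",),
            terminal_methyl=hchain[-1],
        )
    return TopologyMap(species=species)


def gen_bilayer_frames(spec: BilayerSpec) -> tuple[Trajectory, TopologyMap]:
    """Build two leaflets of bead-chain lipids (plus optional solute chains).

    Each lipid is P and glycerol beads above a rigid acyl chain whose
    tilt follows the order-level cone; leaflets are mirror images about
    the midplane (placed at Lz/2).  Herbicide chains hang from a polar
    bead pinned at ``herbicide_polar_depth_nm`` from the midplane.
    """
    rng = np.random.default_rng(spec.seed)
    n_leaf = spec.n_lipids // 2
    mean_cos = 0.5 * (1.0 + math.cos((1.0 - spec.order_level) * math.pi / 2.0))
    chain_extent = (spec.chain_length - 1) * _DZ
    if spec.head_separation_nm is None:
        d_head = 0.2 + chain_extent * mean_cos
    else:
        d_head = spec.head_separation_nm / 2.0
    if d_head <= 0:
        raise InputValidationError("non-positive head-plane separation: leaflets overlap")

    n_herb = 0
    if spec.lipid_to_herbicide_ratio:
        n_herb_f = spec.n_lipids / spec.lipid_to_herbicide_ratio
        if abs(n_herb_f - round(n_herb_f)) > 1e-9:
            raise InputValidationError("non-integral herbicide count for the given ratio")
        n_herb = int(round(n_herb_f))

    side = math.ceil(math.sqrt(n_leaf + math.ceil(n_herb / 2)))
    pitch = math.sqrt(spec.area_per_lipid_nm2)
    L_xy = side * pitch
    z_mid = spec.box_Lz_nm / 2.0
    box = np.array([L_xy, L_xy, spec.box_Lz_nm])

    frames = []
    for fidx in range(spec.n_frames):
        names, species, mids, coords = [], [], [], []
        mol_id = 0
        slot = 0
        for leaflet in (+1, -1):
            for _ in range(n_leaf):
                gx = (slot % side + 0.5) * pitch
                gy = (slot // side % side + 0.5) * pitch
                slot += 1
                mol_id += 1
                jitter = rng.normal(0.0, spec.noise_sd, 3) if spec.noise_sd > 0 else np.zeros(3)
                theta = _cone_theta(rng, spec.order_level)
                chain = make_all_trans_chain(
                    spec.chain_length, axis_theta=theta,
                    axis_phi=rng.uniform(0, 2 * math.pi),
                    zigzag_phi=rng.uniform(0, 2 * math.pi),
                )
                if leaflet > 0:
                    chain = chain * np.array([1.0, 1.0, -1.0])  # chains point down
                base = np.array([gx, gy, z_mid + leaflet * (d_head - 0.2)]) + jitter
                head = np.array([gx, gy, z_mid + leaflet * d_head]) + jitter
                glyc = np.array([gx, gy, z_mid + leaflet * (d_head - 0.1)]) + jitter
                names.append("P"); species.append("LIP"); mids.append(mol_id); coords.append(head)
                names.append("G"); species.append("LIP"); mids.append(mol_id); coords.append(glyc)
                for ci, pt in enumerate(chain, start=1):
                    names.append(f"C{ci}"); species.append("LIP"); mids.append(mol_id)
                    coords.append(base + pt)
        for h in range(n_herb):
            leaflet = +1 if h % 2 == 0 else -1
            gx = rng.uniform(0, L_xy)
            gy = rng.uniform(0, L_xy)
            mol_id += 1
            jitter = rng.normal(0.0, spec.noise_sd, 3) if spec.noise_sd > 0 else np.zeros(3)
            theta = _cone_theta(rng, spec.order_level)
            chain = make_all_trans_chain(
                spec.herbicide_chain_length, axis_theta=theta,
                axis_phi=rng.uniform(0, 2 * math.pi),
                zigzag_phi=rng.uniform(0, 2 * math.pi),
            )
            if leaflet > 0:
                chain = chain * np.array([1.0, 1.0, -1.0])
            polar = np.array([gx, gy, z_mid + leaflet * spec.herbicide_polar_depth_nm]) + jitter
            base = polar + np.array([0.0, 0.0, -leaflet * 0.15])
            names.append("OP"); species.append("HRB"); mids.append(mol_id); coords.append(polar)
            for ci, pt in enumerate(chain, start=1):
                names.append(f"H{ci}"); species.append("HRB"); mids.append(mol_id)
                coords.append(base + pt)
        frames.append(BilayerFrame(
            coords=np.asarray(coords),
            box=box.copy(),
            atom_names=np.asarray(names, dtype=object),
            species=np.asarray(species, dtype=object),
            mol_ids=np.asarray(mids, dtype=int),
            time_ps=fidx * spec.frame_dt_ps,
        ))
    return Trajectory(frames=tuple(frames)), default_bilayer_topology(spec)
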