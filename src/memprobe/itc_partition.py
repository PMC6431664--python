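"""Isothermal titration calorimetry: lipid-into-solute partition analysis.

The experiment titrates lipid vesicles (syringe) into a dilute solute
solution (cell).  As the lipid concentration rises, a growing fraction of
the solute partitions into the bilayers and the per-injection heats decay.
The cumulative heat after *i* injections follows a single-parameter
partition isotherm,

    sum_k dh_k = dH * V_cell * C_A0(i) * K*C_L0(i) / (1 + K*C_L0(i))

where K (mM^-1) is the partition constant, dH (kJ/mol) the molar transfer
enthalpy water->bilayer, and C_A0 / C_L0 the total solute and lipid
concentrations in the cell after i injections.  Fitting the observed
cumulative heats to this isotherm yields (K, dH); the free energy uses a
mole-fraction standard state, dG = -R*T*ln(55.5 * K[M^-1]), and
T*dS = dH - dG.

Injected volume is a non-negligible fraction of the cell volume here
(282 uL into 1.4565 mL, ~19%), so by default both concentrations carry a
volume-additive dilution correction; ``mode="naive"`` (no correction) and
``mode="overfill"`` (perfusion-cell displacement) are selectable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import lmfit

from .errors import InputValidationError, MissingDataError

__all__ = [
    "InjectionSchedule",
    "TitrationExperiment",
    "ConcentrationSeries",
    "PartitionFit",
    "ThermoParams",
    "default_schedule",
    "concentration_series",
    "integrate_peaks",
    "cumulative_heat_model",
    "fit_partition",
    "derive_thermodynamics",
    "CAL_TO_J",
    "WATER_MOLARITY",
    "R_KJ",
]

logger = logging.getLogger(__name__)

CAL_TO_J = 4.184
WATER_MOLARITY = 55.5       # mol/L, mole-fraction standard-state factor
R_KJ = 8.314462618e-3       # kJ mol^-1 K^-1

HeatUnit = Literal["ucal", "uJ"]
ConcMode = Literal["naive", "dilution", "overfill"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injection volumes (uL) with the spacing used for peak windows.

    When ``discard_first`` is set, the first injection's heat is excluded
    from fitting but its volume still counts toward the concentration
    bookkeeping (the customary treatment of the small priming injection).
    """

    volumes_ul: tuple[float, ...]
    discard_first: bool = True
    interval_s: float = 600.0

    def __post_init__(self) -> None:
        if len(self.volumes_ul) == 0:
            raise InputValidationError("empty injection schedule")
        if any(v <= 0 for v in self.volumes_ul):
            raise InputValidationError("injection volumes must be > 0")

    @property
    def n_injections(self) -> int:
        return len(self.volumes_ul)

    @property
    def retained_slice(self) -> slice:
        return slice(1, None) if self.discard_first else slice(0, None)

    @property
    def total_volume_ul(self) -> float:
        return float(sum(self.volumes_ul))


def default_schedule() -> InjectionSchedule:
    """2 uL priming injection (discarded) followed by 28 x 10 uL, 600 s apart."""
    return InjectionSchedule(volumes_ul=(2.0,) + (10.0,) * 28)


@dataclass(frozen=True)
class TitrationExperiment:
    """One lipid-into-solute titration: geometry, schedule, observed heats.

    ``heats`` are per-injection heats for the *non-discarded* injections,
    in the unit named by ``heat_unit``.
    """

    V_cell_ml: float
    C_A0_uM: float              # solute (analyte) in the cell before titration
    C_syringe_mM: float         # lipid in the syringe
    schedule: InjectionSchedule
    heats: tuple[float, ...]
    temperature_C: float = 26.0
    heat_unit: HeatUnit = "ucal"

    def __post_init__(self) -> None:
        if self.V_cell_ml <= 0 or self.C_A0_uM <= 0 or self.C_syringe_mM <= 0:
            raise InputValidationError("cell volume and concentrations must be > 0")
        n_retained = self.schedule.n_injections - int(self.schedule.discard_first)
        if len(self.heats) != n_retained:
            raise InputValidationError(
                f"{len(self.heats)} heats supplied for {n_retained} retained injections"
            )
        if not all(math.isfinite(h) for h in self.heats):
            raise InputValidationError("heats must be finite")

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15


@dataclass(frozen=True)
class ConcentrationSeries:
    """Total lipid and solute cell concentrations after each injection."""

    C_L0_mM: tuple[float, ...]
    C_A0_uM: tuple[float, ...]
    mode: ConcMode

    def __post_init__(self) -> None:
        cl = self.C_L0_mM
        if any(b <= a for a, b in zip(cl, cl[1:])):
            raise InputValidationError("lipid concentration must increase with injections")

    def retained(self, schedule: InjectionSchedule) -> "ConcentrationSeries":
        sl = schedule.retained_slice
        return ConcentrationSeries(self.C_L0_mM[sl], self.C_A0_uM[sl], self.mode)


@dataclass(frozen=True)
class PartitionFit:
    """Fitted partition isotherm parameters with standard errors."""

    K_mM: float
    dH_kJ_mol: float
    K_se: float
    dH_se: float
    residual_norm: float        # RMS residual, heat units of the experiment
    converged: bool
    mode: ConcMode = "dilution"
    message: str = ""


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic decomposition of a partition constant at temperature T."""

    dG_kJ_mol: float
    dH_kJ_mol: float
    TdS_kJ_mol: float
    T_K: float
    standard_state_factor_M: float = WATER_MOLARITY


# ---------------------------------------------------------------------------
# concentrations
# ---------------------------------------------------------------------------

def concentration_series(
    V_cell_ml: float,
    C_A0_uM: float,
    C_syringe_mM: float,
    schedule: InjectionSchedule,
    mode: ConcMode = "dilution",
) -> ConcentrationSeries:
    """Cell concentrations after each injection, under a chosen volume model.

    naive
        C_L0(i) = C_syr * sum(V_j)/V_cell; solute concentration constant.
    dilution (default)
        volume-additive: both species live in volume V_cell + sum(V_j), so
        the naive values are scaled by V_cell/(V_cell + sum(V_j)).
    overfill
        perfusion-cell displacement: each injection of volume v expels
        mixed cell content; pre-existing concentrations scale by
        d = (1 - v/2V)/(1 + v/2V) per injection and the fresh lipid enters
        as C_syr*(v/V)/(1 + v/2V).
    """
    vols_ml = np.asarray(schedule.volumes_ul, dtype=float) * 1e-3
    V = float(V_cell_ml)
    cum = np.cumsum(vols_ml)
    if cum[-1] > 0.25 * V:
        logger.warning(
            "cumulative injected volume %.0f uL exceeds 25%% of the cell "
            "volume: concentration model accuracy degrades", cum[-1] * 1e3,
        )
    if mode == "naive":
        cl = C_syringe_mM * cum / V
        ca = np.full_like(cl, C_A0_uM)
    elif mode == "dilution":
        factor = V / (V + cum)
        cl = C_syringe_mM * cum / V * factor
        ca = C_A0_uM * factor
    elif mode == "overfill":
        cl_list, ca_list = [], []
        cl_cur, ca_cur = 0.0, C_A0_uM
        for v in vols_ml:
            d = (1.0 - v / (2 * V)) / (1.0 + v / (2 * V))
            cl_cur = cl_cur * d + C_syringe_mM * (v / V) / (1.0 + v / (2 * V))
            ca_cur = ca_cur * d
            cl_list.append(cl_cur)
            ca_list.append(ca_cur)
        cl, ca = np.array(cl_list), np.array(ca_list)
    else:
        raise InputValidationError(f"unknown concentration mode {mode!r}")
    return ConcentrationSeries(tuple(float(x) for x in cl), tuple(float(x) for x in ca), mode)


# ---------------------------------------------------------------------------
# peak integration
# ---------------------------------------------------------------------------

def integrate_peaks(
    time_s: Sequence[float],
    power: Sequence[float],
    schedule: InjectionSchedule,
    baseline_mode: Literal["linear", "median"] = "linear",
    t0_s: float = 0.0,
) -> np.ndarray:
    """Integrate a power-versus-time thermogram into per-injection heats.

    Injection *k* is assumed at ``t0_s + k*interval`` and its window runs
    to the next injection time.  Within each window the baseline is either
    a line through the window's leading and trailing 10% (``linear``) or
    the window median (``median``); the heat is the trapezoidal integral
    of (power - baseline).  Units follow the trace (ucal/s -> ucal).
    """
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(power, dtype=float)
    if t.ndim != 1 or t.shape != p.shape:
        raise InputValidationError("time and power must be 1-D and equal length")
    dt = schedule.interval_s
    heats = []
    for k in range(schedule.n_injections):
        lo, hi = t0_s + k * dt, t0_s + (k + 1) * dt
        sel = (t >= lo) & (t < hi)
        if sel.sum() < 4:
            raise MissingDataError(
                f"injection window {k} [{lo:.0f}, {hi:.0f}) s has "
                f"{int(sel.sum())} samples; trace does not cover the schedule"
            )
        tw, pw = t[sel], p[sel]
        m = max(2, int(0.1 * len(tw)))
        if baseline_mode == "linear":
            edges_t = np.concatenate([tw[:m], tw[-m:]])
            edges_p = np.concatenate([pw[:m], pw[-m:]])
            slope, intercept = np.polyfit(edges_t, edges_p, 1)
            baseline = slope * tw + intercept
        elif baseline_mode == "median":
            baseline = np.full_like(pw, np.median(pw))
        else:
            raise InputValidationError(f"unknown baseline mode {baseline_mode!r}")
        heats.append(float(np.trapezoid(pw - baseline, tw)))
    return np.asarray(heats)


# ---------------------------------------------------------------------------
# isotherm model and fit
# ---------------------------------------------------------------------------

def cumulative_heat_model(
    K_mM: float,
    dH_kJ_mol: float,
    V_cell_ml: float,
    series: ConcentrationSeries,
    heat_unit: HeatUnit = "ucal",
) -> np.ndarray:
    """Cumulative heat after each injection under the partition isotherm.

    Returns one value per entry of ``series`` in the requested heat unit.
    """
    if K_mM <= 0:
        raise InputValidationError("K must be > 0")
    cl = np.asarray(series.C_L0_mM)            # mM
    ca = np.asarray(series.C_A0_uM) * 1e-6     # M
    bound_fraction = K_mM * cl / (1.0 + K_mM * cl)
    q_joule = dH_kJ_mol * 1e3 * (V_cell_ml * 1e-3) * ca * bound_fraction
    if heat_unit == "ucal":
        return q_joule / CAL_TO_J * 1e6
    if heat_unit == "uJ":
        return q_joule * 1e6
    raise InputValidationError(f"unknown heat unit {heat_unit!r}")


def fit_partition(
    exp: TitrationExperiment,
    mode: ConcMode = "dilution",
    weights: Sequence[float] | None = None,
    fit_offset: bool = False,
) -> PartitionFit:
    """Weighted least-squares fit of observed cumulative heats to the isotherm.

    K is constrained positive through a log parameterization.  Starting
    values: dH from the last cumulative heat read as the saturation
    plateau, K from the lipid concentration nearest half-plateau.  A
    non-convergent or rank-deficient fit is returned flagged
    (``converged=False``), never silently.  ``fit_offset`` adds a constant
    per-injection nuisance heat absorbing the heat of dilution.
    """
    heats = np.asarray(exp.heats, dtype=float)
    if len(heats) < 5:
        raise InputValidationError("need >= 5 retained injections to fit")
    series_full = concentration_series(
        exp.V_cell_ml, exp.C_A0_uM, exp.C_syringe_mM, exp.schedule, mode
    )
    series = series_full.retained(exp.schedule)
    # heat released before the first retained injection: excluded from the
    # observed cumulative sum but present in the isotherm, so the model is
    # referenced to the state after the discarded priming injection
    discard_idx = 0 if exp.schedule.discard_first else None
    cum = np.cumsum(heats)
    sd = np.std(heats[-5:])
    drops = np.diff(cum) < -3.0 * max(sd, 1e-30)
    if drops.any():
        logger.warning(
            "cumulative heat decreases by > 3 sd at %d injection(s): "
            "check integration or exothermic contamination", int(drops.sum()),
        )

    # initial guesses from the data
    plateau = cum[-1]
    ca_last = series.C_A0_uM[-1] * 1e-6
    q_unit = 1.0 / CAL_TO_J * 1e6 if exp.heat_unit == "ucal" else 1e6
    dh0 = plateau / (exp.V_cell_ml * 1e-3 * ca_last * q_unit) * 1e-3  # kJ/mol
    if not math.isfinite(dh0) or dh0 == 0:
        dh0 = 1.0
    half = 0.5 * plateau
    k_idx = int(np.argmin(np.abs(cum - half)))
    cl_half = series.C_L0_mM[k_idx]
    k0 = 1.0 / cl_half if cl_half > 0 else 1.0

    params = lmfit.Parameters()
    params.add("logK", value=math.log(max(k0, 1e-6)), min=math.log(1e-6), max=math.log(1e6))
    params.add("dH", value=dh0)
    params.add("offset", value=0.0, vary=fit_offset)

    w = np.ones_like(cum) if weights is None else np.asarray(weights, dtype=float)
    idx = np.arange(1, len(cum) + 1)

    sl = exp.schedule.retained_slice

    def residual(p: lmfit.Parameters) -> np.ndarray:
        K = math.exp(p["logK"].value)
        model_full = cumulative_heat_model(
            K, p["dH"].value, exp.V_cell_ml, series_full, exp.heat_unit
        )
        model = model_full[sl]
        if discard_idx is not None:
            model = model - model_full[discard_idx]
        model = model + p["offset"].value * idx
        return (model - cum) * w

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = lmfit.minimize(residual, params, method="leastsq")

    K = math.exp(result.params["logK"].value)
    dH = float(result.params["dH"].value)
    logk_se = result.params["logK"].stderr
    dh_se = result.params["dH"].stderr
    have_errors = (
        bool(result.errorbars) and logk_se is not None and dh_se is not None
        and math.isfinite(logk_se) and math.isfinite(dh_se)
    )
    K_se = K * logk_se if have_errors else float("nan")
    resid = float(np.sqrt(np.mean(residual(result.params) ** 2)))
    converged = bool(result.success) and have_errors
    if float(np.max(np.abs(cum))) == 0.0:
        # no heat signal at all: dH -> 0 and K is unidentifiable
        converged = False
    return PartitionFit(
        K_mM=K, dH_kJ_mol=dH,
        K_se=float(K_se), dH_se=float(dh_se) if have_errors else float("nan"),
        residual_norm=resid, converged=converged, mode=mode,
        message=str(result.message),
    )


def derive_thermodynamics(
    K_mM: float,
    dH_kJ_mol: float,
    T_K: float,
    standard_state_factor_M: float = WATER_MOLARITY,
) -> ThermoParams:
    """Free energy and entropic term from a fitted partition constant.

    dG = -R*T*ln(f * K) with K converted to M^-1 and f the mole-fraction
    standard-state factor (water molarity, 55.5 M, by default); then
    T*dS = dH - dG.
    """
    if K_mM <= 0 or T_K <= 0:
        raise InputValidationError("K and T must be > 0")
    K_M = K_mM * 1e3  # mM^-1 -> M^-1
    dG = -R_KJ * T_K * math.log(standard_state_factor_M * K_M)
    return ThermoParams(
        dG_kJ_mol=dG, dH_kJ_mol=dH_kJ_mol, TdS_kJ_mol=dH_kJ_mol - dG,
        T_K=T_K, standard_state_factor_M=standard_state_factor_M,
    )
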