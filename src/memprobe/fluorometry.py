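"""Steady-state fluorescence reduction for membrane probes.

Two observables are produced here:

* **Laurdan generalized polarization (GP)** — a normalized two-channel
  emission ratio, ``GP = (I440 - I490) / (I440 + I490)``, computed from
  blank-subtracted intensities at 440 and 490 nm.  GP is high (~0.5) for
  gel-phase bilayers and low/negative for fluid-phase bilayers, so a
  GP-versus-temperature curve traces the melting transition of the lipid;
  its midpoint is the transition temperature Tm.

* **DPH fluorescence anisotropy (r)** — computed from the four
  polarizer-orientation intensity combinations,
  ``r = (I_VV - G*I_VH) / (I_VV + 2*G*I_VH)`` with the instrument
  G-factor ``G = I_HV / I_HH`` correcting the emission channel's
  polarization bias.  High r means a rigid hydrophobic core.

Replicate shots are averaged at the *intensity* level before the ratio is
formed (ratio of means); the per-shot alternative (mean of ratios) is
available through ``build_gp_curve(..., method="per_shot")``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateSignalError,
    InputValidationError,
    NoTransitionError,
    SchemaError,
)

__all__ = [
    "EmissionPair",
    "GPCurve",
    "TmEstimate",
    "PolarizedQuad",
    "AnisotropyResult",
    "blank_subtract",
    "generalized_polarization",
    "build_gp_curve",
    "estimate_tm",
    "steepest_descent_tm",
    "g_factor",
    "anisotropy",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionPair:
    """Blank-subtracted emission intensities at 440 and 490 nm.

    ``replicate_count`` records how many instrument shots were averaged
    into these intensities (1 for a single raw shot).
    """

    I440: float
    I490: float
    temperature: float  # degC
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.I440) and math.isfinite(self.I490)):
            raise InputValidationError("emission intensities must be finite")
        if not math.isfinite(self.temperature):
            raise InputValidationError("temperature must be finite")
        if self.replicate_count < 1:
            raise InputValidationError("replicate_count must be >= 1")


@dataclass(frozen=True)
class GPCurve:
    """GP as a function of temperature for one sample composition.

    ``points`` is ordered by strictly increasing temperature; each entry
    is ``(temperature_degC, GP, sd)`` where ``sd`` is the standard error
    of the GP value propagated from replicate scatter.
    """

    points: tuple[tuple[float, float, float], ...]
    composition_label: str = ""

    def __post_init__(self) -> None:
        temps = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise SchemaError("GPCurve temperatures must be strictly increasing")
        for _, gp, _ in self.points:
            if not -1.0 <= gp <= 1.0:
                raise InputValidationError(f"GP={gp} outside [-1, 1]")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def gp(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def sd(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


@dataclass(frozen=True)
class TmEstimate:
    """Result of a sigmoidal melting-curve fit.

    GP(T) = GP_fluid + (GP_gel - GP_fluid) / (1 + exp((T - Tm)/width))
    """

    Tm: float          # degC, midpoint
    width: float       # degC, transition steepness (> 0)
    GP_gel: float      # low-temperature plateau
    GP_fluid: float    # high-temperature plateau
    fit_residual: float  # RMS residual of the fit
    fallback_Tm: float   # model-free steepest-descent estimate


@dataclass(frozen=True)
class PolarizedQuad:
    """Blank-subtracted intensities for the four polarizer orientations.

    Subscripts name excitation then emission polarizer (V vertical,
    H horizontal); e.g. ``I_VH`` is vertical excitation, horizontal
    emission.
    """

    I_VV: float
    I_VH: float
    I_HV: float
    I_HH: float
    temperature: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("I_VV", "I_VH", "I_HV", "I_HH"):
            if not math.isfinite(getattr(self, name)):
                raise InputValidationError(f"{name} must be finite")


@dataclass(frozen=True)
class AnisotropyResult:
    r: float
    G: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def blank_subtract(sample_intensity: float, blank_intensity: float) -> float:
    """Subtract the probe-free blank from a sample intensity.

    The result may be negative (over-subtraction); downstream ratio
    computations decide whether that is tolerable.
    """
    if not (math.isfinite(sample_intensity) and math.isfinite(blank_intensity)):
        raise InputValidationError("intensities must be finite")
    return sample_intensity - blank_intensity


def generalized_polarization(pair: EmissionPair) -> float:
    """Laurdan GP = (I440 - I490) / (I440 + I490)."""
    total = pair.I440 + pair.I490
    if total <= 0:
        raise DegenerateSignalError(
            f"I440 + I490 = {total} <= 0: GP undefined (check blanks)"
        )
    return (pair.I440 - pair.I490) / total


def _group_by_temperature(
    measurements: Iterable[EmissionPair],
) -> dict[float, list[EmissionPair]]:
    groups: dict[float, list[EmissionPair]] = {}
    for m in measurements:
        groups.setdefault(m.temperature, []).append(m)
    if not groups:
        raise SchemaError("no measurements supplied")
    return groups


def build_gp_curve(
    measurements: Sequence[EmissionPair],
    composition_label: str = "",
    method: Literal["mean_intensities", "per_shot"] = "mean_intensities",
) -> GPCurve:
    """Reduce replicated emission pairs to a GP-versus-temperature curve.

    Replicates sharing a temperature are combined; with the default
    ``mean_intensities`` method the (replicate-count-weighted) mean I440
    and I490 are formed first and GP is computed on the means.  The
    reported ``sd`` is the standard error of GP obtained by first-order
    propagation of the replicate scatter of the mean intensities
    (``per_shot``: mean and standard error of per-replicate GP values).
    Points are returned sorted by temperature.
    """
    pts: list[tuple[float, float, float]] = []
    for temp, group in sorted(_group_by_temperature(measurements).items()):
        w = np.array([m.replicate_count for m in group], dtype=float)
        i440 = np.array([m.I440 for m in group])
        i490 = np.array([m.I490 for m in group])
        n = int(w.sum())
        if method == "mean_intensities":
            m440 = float(np.average(i440, weights=w))
            m490 = float(np.average(i490, weights=w))
            gp = generalized_polarization(EmissionPair(m440, m490, temp, n))
            if len(group) > 1:
                # delta method: dGP/dI440 = 2*I490/S^2, dGP/dI490 = -2*I440/S^2
                s = m440 + m490
                var_mean440 = float(np.var(i440, ddof=1)) / len(group)
                var_mean490 = float(np.var(i490, ddof=1)) / len(group)
                var_gp = (2 * m490 / s**2) ** 2 * var_mean440 + (2 * m440 / s**2) ** 2 * var_mean490
                sd = math.sqrt(max(var_gp, 0.0))
            else:
                sd = 0.0
        elif method == "per_shot":
            gps = np.array(
                [generalized_polarization(m) for m in group], dtype=float
            )
            gp = float(np.average(gps, weights=w))
            sd = float(np.std(gps, ddof=1) / math.sqrt(len(gps))) if len(gps) > 1 else 0.0
        else:  # pragma: no cover - guarded by Literal type
            raise ValueError(f"unknown method {method!r}")
        pts.append((temp, gp, sd))
    return GPCurve(points=tuple(pts), composition_label=composition_label)


def _logistic_gp(T: np.ndarray, Tm: float, width: float, gp_gel: float, gp_fluid: float) -> np.ndarray:
    return gp_fluid + (gp_gel - gp_fluid) / (1.0 + np.exp((T - Tm) / width))


def steepest_descent_tm(curve: GPCurve) -> float:
    """Model-free Tm: temperature of the steepest finite-difference drop.

    Uses centered midpoints of adjacent temperature pairs; robust when the
    sigmoid fit is not trusted.
    """
    T, gp = curve.temperatures, curve.gp
    if len(T) < 2:
        raise NoTransitionError("need >= 2 temperatures for a slope estimate")
    slopes = np.diff(gp) / np.diff(T)
    k = int(np.argmin(slopes))  # most negative slope
    return float(0.5 * (T[k] + T[k + 1]))


def estimate_tm(curve: GPCurve, min_gp_range: float = 0.2) -> TmEstimate:
    """Fit a descending logistic to a GP melting curve and report Tm.

    The curve must span both plateaus: the GP range must exceed
    ``min_gp_range``, otherwise a :class:`NoTransitionError` is raised
    rather than extrapolating a transition that is not in the data.
    """
    T, gp = curve.temperatures, curve.gp
    gp_range = float(gp.max() - gp.min())
    if gp_range <= min_gp_range:
        raise NoTransitionError(
            f"GP range {gp_range:.3f} <= threshold {min_gp_range}: "
            "no gel-to-fluid transition in the sampled window"
        )
    if len(T) < 4:
        raise NoTransitionError("need >= 4 points to fit a 4-parameter sigmoid")

    tm0 = steepest_descent_tm(curve)
    span = float(T.max() - T.min())
    p0 = [tm0, max(span / 20.0, 0.1), float(gp.max()), float(gp.min())]
    bounds = (
        [float(T.min()) - span, 1e-6, -1.0, -1.0],
        [float(T.max()) + span, span, 1.0, 1.0],
    )
    popt, _ = curve_fit(_logistic_gp, T, gp, p0=p0, bounds=bounds, maxfev=20000)
    tm, width, gp_gel, gp_fluid = (float(v) for v in popt)
    if gp_gel <= gp_fluid:
        raise NoTransitionError("fitted curve is not a melting transition (GP_gel <= GP_fluid)")
    resid = float(np.sqrt(np.mean((_logistic_gp(T, *popt) - gp) ** 2)))
    return TmEstimate(
        Tm=tm, width=width, GP_gel=gp_gel, GP_fluid=gp_fluid,
        fit_residual=resid, fallback_Tm=tm0,
    )


def g_factor(quad: PolarizedQuad) -> float:
    """Instrument G-factor, G = I_HV / I_HH."""
    if quad.I_HH <= 0:
        raise DegenerateSignalError("I_HH <= 0: G-factor undefined")
    return quad.I_HV / quad.I_HH


def anisotropy(quad: PolarizedQuad) -> AnisotropyResult:
    """DPH anisotropy r = (I_VV - G*I_VH) / (I_VV + 2*G*I_VH).

    G is computed from the same quad (all four orientations are measured
    per sample, so no global instrument constant is assumed).
    """
    G = g_factor(quad)
    denom = quad.I_VV + 2.0 * G * quad.I_VH
    if denom <= 0:
        raise DegenerateSignalError("I_VV + 2*G*I_VH <= 0: anisotropy undefined")
    r = (quad.I_VV - G * quad.I_VH) / denom
    return AnisotropyResult(r=r, G=G)
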