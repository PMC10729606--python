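"""Particle-level aerosol physics.

Lognormal size-distribution handling (MMAD/GSD), Cunningham slip
correction, gravitational settling, Brownian diffusion, and species-specific
inhalability.  Aerodynamic diameters are in µm, everything else in CGS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import config

__all__ = [
    "AerosolSpec",
    "SizeBin",
    "GasConditions",
    "discretize_lognormal",
    "slip_correction",
    "settling_velocity",
    "diffusion_coefficient",
    "aerodynamic_to_physical",
    "rat_inhalability_curve",
    "inhalable_fraction",
]


@dataclass(frozen=True)
class AerosolSpec:
    """Exposure atmosphere: lognormal aerosol described by its mass distribution.

    Parameters
    ----------
    mmad :
        Mass median aerodynamic diameter, µm.
    gsd :
        Geometric standard deviation of the mass distribution (≥ 1).
    density :
        Particle material density, g/cm³.
    concentration :
        Aerosol mass concentration, mg/m³ (equivalently µg/L·10³; 1 mg/m³ =
        0.001 µg/cm³).
    """

    mmad: float
    gsd: float
    density: float = 1.0
    concentration: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.mmad, self.gsd, self.density, self.concentration)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("aerosol spec fields must be finite")
        if self.mmad <= 0:
            raise ValueError("mmad must be > 0")
        if self.gsd < 1:
            raise ValueError("gsd must be >= 1")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def concentration_ug_cm3(self) -> float:
        return self.concentration * 1e-3


@dataclass(frozen=True)
class SizeBin:
    """One quadrature node of the discretized lognormal mass distribution."""

    d_ae: float  # aerodynamic diameter, µm
    mass_fraction: float

    def __post_init__(self) -> None:
        if self.d_ae <= 0:
            raise ValueError("d_ae must be > 0")
        if not 0.0 <= self.mass_fraction <= 1.0:
            raise ValueError("mass_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GasConditions:
    """Carrier-gas state: defaults are airway-lumen (body) conditions."""

    temperature: float = config.DEFAULT_GAS["temperature_k"]  # K
    air_viscosity: float = config.DEFAULT_GAS["air_viscosity_g_cm_s"]  # g/(cm s)
    mean_free_path: float = config.DEFAULT_GAS["mean_free_path_um"]  # µm
    gravity: float = config.DEFAULT_GAS["gravity_cm_s2"]  # cm/s²

    def __post_init__(self) -> None:
        for name in ("temperature", "air_viscosity", "mean_free_path", "gravity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def discretize_lognormal(
    spec: AerosolSpec,
    n_bins: int = config.N_BINS_DEFAULT,
    span_sigmas: float = config.SPAN_SIGMAS_DEFAULT,
) -> list[SizeBin]:
    """Discretize the lognormal mass distribution into geometric size bins.

    Bins are geometrically spaced over ``mmad * gsd**(±span_sigmas)``; each
    bin carries the lognormal mass-distribution probability of its interval,
    renormalized so the fractions sum to exactly 1.  The representative
    diameter is the geometric midpoint of the bin.

    A monodisperse aerosol (``gsd == 1``) collapses to a single bin at the
    MMAD regardless of ``n_bins``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if span_sigmas <= 0:
        raise ValueError("span_sigmas must be > 0")
    if spec.gsd == 1.0:
        return [SizeBin(d_ae=spec.mmad, mass_fraction=1.0)]
    ln_gsd = math.log(spec.gsd)
    edges = np.exp(
        np.log(spec.mmad) + np.linspace(-span_sigmas, span_sigmas, n_bins + 1) * ln_gsd
    )
    mids = np.sqrt(edges[:-1] * edges[1:])
    dist = stats.lognorm(s=ln_gsd, scale=spec.mmad)
    probs = np.diff(dist.cdf(edges))
    probs /= probs.sum()
    return [SizeBin(d_ae=float(d), mass_fraction=float(p)) for d, p in zip(mids, probs)]


def slip_correction(d: float | np.ndarray, gas: GasConditions = GasConditions()):
    """Cunningham slip correction C(d) for a particle of diameter ``d`` µm.

    C = 1 + (λ/d)·(2.514 + 0.800·exp(−0.55·d/λ)); ≥ 1 and decreasing in d.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("particle diameter must be > 0")
    lam = gas.mean_free_path
    c = 1.0 + (lam / d) * (2.514 + 0.800 * np.exp(-0.55 * d / lam))
    return float(c) if c.ndim == 0 else c


def settling_velocity(d_ae: float | np.ndarray, gas: GasConditions = GasConditions()):
    """Terminal settling velocity (cm/s) of an aerodynamic diameter ``d_ae`` µm.

    Uses the aerodynamic-diameter convention: unit density ρ₀ = 1 g/cm³, so
    v_ts = ρ₀ d_ae² g C(d_ae) / (18 µ).
    """
    d_ae = np.asarray(d_ae, dtype=float)
    if np.any(d_ae <= 0):
        raise ValueError("d_ae must be > 0")
    d_cm = d_ae * 1e-4
    v = 1.0 * d_cm**2 * gas.gravity * slip_correction(d_ae, gas) / (18.0 * gas.air_viscosity)
    return float(v) if v.ndim == 0 else v


def diffusion_coefficient(d: float | np.ndarray, gas: GasConditions = GasConditions()):
    """Stokes-Einstein Brownian diffusion coefficient (cm²/s), d in µm."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("particle diameter must be > 0")
    d_cm = d * 1e-4
    coef = (
        config.BOLTZMANN_ERG_PER_K
        * gas.temperature
        * slip_correction(d, gas)
        / (3.0 * math.pi * gas.air_viscosity * d_cm)
    )
    return float(coef) if coef.ndim == 0 else coef


def aerodynamic_to_physical(d_ae: float, density: float) -> float:
    """Convert aerodynamic to physical diameter: d_p = d_ae / sqrt(ρ/ρ₀).

    With the study materials (ρ = 1 g/cm³) the two coincide; the conversion
    exists for generality.  Slip-correction differences are neglected (valid
    for supra-micron particles).
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    return d_ae / math.sqrt(density / 1.0)


def rat_inhalability_curve(d_ae: float | np.ndarray) -> float | np.ndarray:
    """Fraction of airborne particles of size ``d_ae`` µm inhalable by a rat.

    Logistic in ln(d_ae): IF = 1 − 1/(1 + exp(a − b·ln d)).  Tends to 1 for
    very fine particles and falls off above ~1 µm, reflecting the sharply
    declining aspiration efficiency of the rat nose for supra-micron
    aerosols.  Coefficients are frozen in :mod:`lungdosim.config`.
    """
    d_ae = np.asarray(d_ae, dtype=float)
    a = config.RAT_INHALABILITY["a"]
    b = config.RAT_INHALABILITY["b"]
    f = 1.0 - 1.0 / (1.0 + np.exp(a - b * np.log(d_ae)))
    return float(f) if f.ndim == 0 else f


def inhalable_fraction(
    spec: AerosolSpec, species: str, bins: list[SizeBin] | None = None
) -> float:
    """Mass-weighted inhalable fraction of an atmosphere for a species.

    Humans inhale essentially all particles below ~10 µm, so the human value
    is 1 for the study aerosols; rats are obligate nose breathers whose
    inhalability drops steeply above 1 µm aerodynamic diameter.
    """
    if species not in ("rat", "human"):
        raise ValueError(f"unknown species {species!r}")
    if bins is None:
        bins = discretize_lognormal(spec)
    d = np.array([b.d_ae for b in bins])
    w = np.array([b.mass_fraction for b in bins])
    total = w.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError("bins must be normalized")
    if species == "human":
        # Human inhalability only falls off above ~10 µm; the study aerosols
        # carry essentially no mass there, so no correction is applied.
        return 1.0
    return float(np.sum(w * rat_inhalability_curve(d)) / total)
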