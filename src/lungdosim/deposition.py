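"""Whole-lung deposition engine: serial filtration over tidal breathing.

For each size bin of the discretized aerosol the engine applies, in order:

1. species-specific inhalability (rat exposures only),
2. empirical extrathoracic (head) filtration for the breathing route,
3. serial filtration root→leaves during inspiration, with per-airway
   combined efficiency η = 1 − (1−η_I)(1−η_S)(1−η_D) from inertial
   impaction, gravitational sedimentation and Brownian diffusion,
4. alveolar capture of the air stored in the alveolar sleeves of the
   airways it reached, plus an optional breath-hold (pause) with quiescent
   sedimentation/diffusion in the duct lumina,
5. serial filtration leaves→root during expiration, with the expired
   stream passing the head filter once more on its way out.

Air is treated as an incompressible plug: fresh aerosol enters the trachea
only after the extrathoracic dead space is washed out, and the parcel
inhaled at time t penetrates along the tree — filling each airway's lumen
and attached alveolar sleeves — until inspiration ends.  Only the fraction
of the tidal volume that clears an airway's cumulative upstream volume
ever transits it, which reproduces the characteristic absence of
deposition in the terminal alveolar generations: their cumulative volume
exceeds the resting tidal breath.  Deposition never feeds back on the
airflow (one-way coupling): even a nominally obstructed airway keeps
filtering as if open, which understates proximal pile-up at extreme
concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import config
from .aerosol import (
    AerosolSpec,
    GasConditions,
    SizeBin,
    diffusion_coefficient,
    discretize_lognormal,
    inhalable_fraction,
    rat_inhalability_curve,
    settling_velocity,
)
from .geometry import Airway, AirwayTree, validate_tree

__all__ = [
    "VentilationPattern",
    "ExposureScenario",
    "DepositionResult",
    "airway_flows",
    "efficiency_impaction",
    "efficiency_sedimentation",
    "efficiency_diffusion",
    "extrathoracic_deposition",
    "run_deposition",
]

ROUTES = ("nasal", "oral", "nose-only")


@dataclass(frozen=True)
class VentilationPattern:
    """Breathing physiology: tidal volume (mL), frequency (breaths/min), route.

    The breathing waveform is a square wave; ``inspiratory_fraction`` and
    ``pause_fraction`` partition the breath period, the remainder being
    expiration.
    """

    tidal_volume: float
    frequency: float
    route: str = "nasal"
    inspiratory_fraction: float = 0.5
    pause_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.tidal_volume <= 0 or self.frequency <= 0:
            raise ValueError("tidal volume and frequency must be > 0")
        if self.route not in ROUTES:
            raise ValueError(f"unknown breathing route {self.route!r}")
        if not (0.0 < self.inspiratory_fraction <= 1.0):
            raise ValueError("inspiratory_fraction must be in (0, 1]")
        if not (0.0 <= self.pause_fraction < 1.0):
            raise ValueError("pause_fraction must be in [0, 1)")
        if self.inspiratory_fraction + self.pause_fraction > 1.0:
            raise ValueError("inspiratory + pause fraction exceed the breath")

    @property
    def period_s(self) -> float:
        return 60.0 / self.frequency

    @property
    def inspiratory_time_s(self) -> float:
        return self.inspiratory_fraction * self.period_s

    @property
    def pause_time_s(self) -> float:
        return self.pause_fraction * self.period_s

    @property
    def mean_inspiratory_flow(self) -> float:
        """Mean inspiratory flow at the airway opening, cm³/s."""
        return self.tidal_volume / self.inspiratory_time_s

    @property
    def minute_volume(self) -> float:
        """Ventilation, cm³/min."""
        return self.tidal_volume * self.frequency


@dataclass
class ExposureScenario:
    """One exposure condition: aerosol + ventilation + tree + duration (h)."""

    aerosol: AerosolSpec
    ventilation: VentilationPattern
    tree: AirwayTree
    duration: float  # hours
    inhalability_on: bool = False
    gas: GasConditions = field(default_factory=GasConditions)
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class DepositionResult:
    """Deposition outcome of a scenario, on the basis of *inhaled* mass.

    ``per_airway_fraction`` maps an airway record id to the fraction of
    inhaled mass deposited in that record (a whole generation for symmetric
    trees); ``per_airway_mass`` is µg deposited per *single* airway.
    Regional fractions (head/TB/PUL) plus ``exhaled_fraction`` sum to 1.
    """

    scenario: ExposureScenario | None
    inhalable_fraction: float
    per_airway_fraction: dict[str, float]
    per_airway_mass: dict[str, float]
    regional: dict[str, float]  # keys: head, TB, PUL
    exhaled_fraction: float
    total_inhaled_mass: float  # µg
    per_generation: dict[int, float] = field(default_factory=dict)

    def mass_balance_error(self) -> float:
        return abs(
            self.regional["head"]
            + self.regional["TB"]
            + self.regional["PUL"]
            + self.exhaled_fraction
            - 1.0
        )


# ---------------------------------------------------------------------------
# Flow apportionment
# ---------------------------------------------------------------------------


def airway_flows(tree: AirwayTree, ventilation: VentilationPattern) -> dict[str, float]:
    """Mean inspiratory flow (cm³/s) through each *single* airway.

    The root carries the full inspiratory flow; at every branch point the
    flow splits in proportion to the subtended distal volumes, so the flow
    into each airway matches the ventilation demand of the tissue it serves.
    """
    flows: dict[str, float] = {}
    root = tree.root
    flows[root.id] = ventilation.mean_inspiratory_flow / root.multiplicity
    for a in tree.topological_order():
        kids = tree.children(a.id)
        if not kids:
            continue
        weights = [c.distal_volume * c.multiplicity for c in kids]
        total = sum(weights)
        if total <= 0:
            raise ValueError(f"zero distal volume below airway {a.id!r}")
        parent_total = flows[a.id] * a.multiplicity
        for c, w in zip(kids, weights):
            flows[c.id] = parent_total * (w / total) / c.multiplicity
    return flows


# ---------------------------------------------------------------------------
# Single-airway deposition efficiencies
# ---------------------------------------------------------------------------


def efficiency_impaction(
    airway: Airway,
    flow: float,
    bin: SizeBin | np.ndarray,
    gas: GasConditions = GasConditions(),
):
    """Inertial impaction efficiency at the airway's inlet bifurcation.

    Uses the arccos-form impaction probability for a bend of angle θ (the
    branching angle) at Stokes number Stk = v_ts·U/(g·d_airway): with
    ε = θ·Stk, η = 1 − (2/π)·arccos(ε) + (1/π)·sin(2·arccos(ε)) for ε < 1
    and η = 1 beyond.  A straight continuation (θ = 0) never impacts.
    """
    d_ae = bin.d_ae if isinstance(bin, SizeBin) else np.asarray(bin, dtype=float)
    theta = math.radians(airway.branching_angle)
    if theta == 0.0:
        out = np.zeros_like(np.asarray(d_ae, dtype=float))
        return float(out) if out.ndim == 0 else out
    u = flow / (math.pi / 4.0 * airway.diameter**2)
    stk = settling_velocity(d_ae, gas) * u / (gas.gravity * airway.diameter)
    eps = np.minimum(theta * stk, 1.0)
    acos = np.arccos(eps)
    eta = 1.0 - (2.0 / math.pi) * acos + (1.0 / math.pi) * np.sin(2.0 * acos)
    eta = np.clip(eta, 0.0, 1.0)
    return float(eta) if eta.ndim == 0 else eta


def efficiency_sedimentation(
    airway: Airway,
    flow: float,
    bin: SizeBin | np.ndarray,
    gas: GasConditions = GasConditions(),
    length: float | None = None,
):
    """Gravitational sedimentation efficiency over a transit of the airway.

    η_S = 1 − exp(−(4/π)·v_ts·L·sin(φ)/(d·U)) with φ the angle between the
    airway axis and the gravity vector; vertical airways (φ = 0) collect
    nothing because settling is then purely streamwise.
    """
    d_ae = bin.d_ae if isinstance(bin, SizeBin) else np.asarray(bin, dtype=float)
    L = airway.length if length is None else length
    u = flow / (math.pi / 4.0 * airway.diameter**2)
    vts = settling_velocity(d_ae, gas)
    sin_phi = math.sin(math.radians(airway.gravity_angle))
    eta = 1.0 - np.exp(-(4.0 / math.pi) * vts * L * sin_phi / (airway.diameter * u))
    eta = np.clip(eta, 0.0, 1.0)
    return float(eta) if eta.ndim == 0 else eta


def efficiency_diffusion(
    airway: Airway,
    flow: float,
    bin: SizeBin | np.ndarray,
    gas: GasConditions = GasConditions(),
    length: float | None = None,
):
    """Brownian diffusion efficiency for laminar tube flow (Ingham series).

    x = D·L/(4·U·R²);
    η_D = 1 − 0.819·e^(−14.63x) − 0.0976·e^(−89.22x) − 0.0325·e^(−228x)
        − 0.0509·e^(−125.9·x^(2/3)).
    Negligible next to impaction + sedimentation for supra-micron particles
    in large airways, dominant for ultrafines.
    """
    d_ae = bin.d_ae if isinstance(bin, SizeBin) else np.asarray(bin, dtype=float)
    L = airway.length if length is None else length
    u = flow / (math.pi / 4.0 * airway.diameter**2)
    radius = airway.diameter / 2.0
    diff = diffusion_coefficient(d_ae, gas)
    x = diff * L / (4.0 * u * radius**2)
    eta = (
        1.0
        - 0.819 * np.exp(-14.63 * x)
        - 0.0976 * np.exp(-89.22 * x)
        - 0.0325 * np.exp(-228.0 * x)
        - 0.0509 * np.exp(-125.9 * np.power(x, 2.0 / 3.0))
    )
    eta = np.clip(eta, 0.0, 1.0)
    return float(eta) if eta.ndim == 0 else eta


def _quiescent_efficiency(
    airway: Airway, hold_time: float, d_ae: np.ndarray, gas: GasConditions
) -> np.ndarray:
    """Deposition during a breath-hold: settling + diffusion in still air."""
    vts = settling_velocity(d_ae, gas)
    sin_phi = math.sin(math.radians(airway.gravity_angle))
    sed = 1.0 - np.exp(-(4.0 / math.pi) * vts * sin_phi * hold_time / airway.diameter)
    diff = diffusion_coefficient(d_ae, gas)
    radius = airway.diameter / 2.0
    dif = 1.0 - np.exp(-5.784 * diff * hold_time / radius**2)
    return np.clip(1.0 - (1.0 - sed) * (1.0 - dif), 0.0, 1.0)


def extrathoracic_deposition(
    route: str,
    species: str,
    flow: float,
    bin: SizeBin | np.ndarray,
):
    """Empirical head (nose/mouth-through-larynx) collection efficiency.

    η = 1 − exp(−a·(d_ae²·Q)^b) with d_ae in µm and Q the mean inspiratory
    flow in L/min; coefficients per species/route are frozen in
    :mod:`lungdosim.config`.  ``flow`` is in cm³/s.
    """
    key = (species, route)
    if key not in config.EXTRATHORACIC:
        raise ValueError(f"no extrathoracic coefficients for species/route {key}")
    coeff = config.EXTRATHORACIC[key]
    d_ae = bin.d_ae if isinstance(bin, SizeBin) else np.asarray(bin, dtype=float)
    q_lpm = flow * 60.0 / 1000.0
    eta = 1.0 - np.exp(-coeff["a"] * np.power(np.asarray(d_ae) ** 2 * q_lpm, coeff["b"]))
    eta = np.clip(eta, 0.0, 1.0)
    return float(eta) if np.ndim(eta) == 0 else eta


# ---------------------------------------------------------------------------
# Whole-lung serial filtration
# ---------------------------------------------------------------------------


def run_deposition(
    scenario: ExposureScenario,
    n_bins: int = config.N_BINS_DEFAULT,
    span_sigmas: float = config.SPAN_SIGMAS_DEFAULT,
) -> DepositionResult:
    """Run the full serial-filtration deposition model for one scenario.

    Returns per-airway, per-generation and regional deposition fractions of
    the inhaled mass, the exhaled fraction, and deposited masses per single
    airway over the exposure duration.
    """
    tree = scenario.tree
    problems = validate_tree(tree)
    if problems:
        raise ValueError(f"invalid tree: {problems[:5]}")
    vent = scenario.ventilation
    gas = scenario.gas

    bins = discretize_lognormal(scenario.aerosol, n_bins, span_sigmas)
    d_ae = np.array([b.d_ae for b in bins])
    w = np.array([b.mass_fraction for b in bins])

    # inhalability: re-weight the atmosphere by what actually enters the nose
    if scenario.inhalability_on:
        if_curve = np.asarray(rat_inhalability_curve(d_ae))
        if_total = float(np.sum(w * if_curve))
        w = w * if_curve / if_total
    else:
        if_total = 1.0

    flows = airway_flows(tree, vent)
    order = tree.topological_order()

    # extrathoracic filtration at the airway opening
    eta_et = np.asarray(
        extrathoracic_deposition(vent.route, tree.species, vent.mean_inspiratory_flow, d_ae)
    )
    head_frac = float(np.sum(w * eta_et))

    t_insp = vent.inspiratory_time_s
    t_pause = vent.pause_time_s

    # Precompute per-record efficiencies and breath-fraction bookkeeping.
    # Inlined forms of efficiency_{impaction,sedimentation,diffusion} with
    # the particle-side factors (settling velocity, diffusivity) hoisted out
    # of the per-airway loop; the public functions are the reference
    # implementation these must match.
    vts = np.asarray(settling_velocity(d_ae, gas))
    diff = np.asarray(diffusion_coefficient(d_ae, gas))

    def _ingham(x: np.ndarray) -> np.ndarray:
        return np.clip(
            1.0
            - 0.819 * np.exp(-14.63 * x)
            - 0.0976 * np.exp(-89.22 * x)
            - 0.0325 * np.exp(-228.0 * x)
            - 0.0509 * np.exp(-125.9 * np.power(x, 2.0 / 3.0)),
            0.0,
            1.0,
        )

    # Attached alveolar (sleeve) volume per single airway: what remains of
    # the distal volume after the lumen and the children's subtrees.
    alv_vol: dict[str, float] = {}
    for a in order:
        kids = tree.children(a.id)
        below = sum(c.distal_volume * c.multiplicity for c in kids) / a.multiplicity
        alv_vol[a.id] = max(0.0, a.distal_volume - a.lumen_volume - below)

    # Alveolar capture: aerosol stored in the alveoli during inspiration
    # settles/diffuses onto the alveolar walls while it waits (half the
    # expiration, plus any pause) to be drawn back out.
    r_alv = config.ALVEOLUS_RADIUS_CM.get(tree.species, 0.0105)
    t_exp = vent.period_s - t_insp - t_pause
    t_hold = t_pause + 0.5 * t_exp
    eta_alv = 1.0 - np.exp(
        -(0.75 * vts / r_alv + 5.784 * diff / r_alv**2) * t_hold
    )

    eta_full: dict[str, np.ndarray] = {}
    eta_half: dict[str, np.ndarray] = {}
    tau: dict[str, float] = {}  # cumulative residence time to the END of record
    rho: dict[str, float] = {}  # fraction of the breath fully transiting
    enter: dict[str, float] = {}  # fraction of the breath entering
    sigma: dict[str, float] = {}  # fraction ending the inspiration inside
    for a in order:
        q = flows[a.id]
        u = q / (math.pi / 4.0 * a.diameter**2)
        theta = math.radians(a.branching_angle)
        if theta > 0.0:
            eps = np.minimum(theta * vts * u / (gas.gravity * a.diameter), 1.0)
            acos = np.arccos(eps)
            e_i = np.clip(
                1.0 - (2.0 / math.pi) * acos + (1.0 / math.pi) * np.sin(2.0 * acos),
                0.0,
                1.0,
            )
        else:
            e_i = 0.0
        k_sed = (
            (4.0 / math.pi)
            * a.length
            * math.sin(math.radians(a.gravity_angle))
            / (a.diameter * u)
        )
        surv_s = np.exp(-k_sed * vts)
        x_dif = diff * a.length / (4.0 * u * (a.diameter / 2.0) ** 2)
        eta_full[a.id] = 1.0 - (1.0 - e_i) * surv_s * (1.0 - _ingham(x_dif))
        # partial transit: the bifurcation has been passed, half the length not
        eta_half[a.id] = 1.0 - (1.0 - e_i) * np.sqrt(surv_s) * (1.0 - _ingham(x_dif / 2.0))
        # the advancing front also fills the airway's alveolar sleeves
        residence = (a.lumen_volume + alv_vol[a.id]) / q  # seconds
        if a.parent_id is not None:
            upstream = tau[a.parent_id]
        else:
            # the head must be washed out before fresh aerosol enters
            et_volume = config.ET_DEAD_SPACE_CM3.get(tree.species, 0.0)
            upstream = et_volume / vent.mean_inspiratory_flow
        tau[a.id] = upstream + residence
        enter[a.id] = max(0.0, 1.0 - upstream / t_insp)
        rho[a.id] = max(0.0, 1.0 - tau[a.id] / t_insp)
        sigma[a.id] = max(0.0, enter[a.id] - rho[a.id])

    # Inspiration sweep root→leaves: T[j] = mass (per unit inhaled, per bin)
    # delivered to j's inlet per unit of breath-fraction, after upstream
    # filtration and flow splitting.
    T: dict[str, np.ndarray] = {}
    deposited: dict[str, np.ndarray] = {}
    for a in order:
        if a.parent_id is None:
            T[a.id] = 1.0 - eta_et
        deposited[a.id] = T[a.id] * (
            rho[a.id] * eta_full[a.id] + sigma[a.id] * eta_half[a.id]
        )
        passed = T[a.id] * (1.0 - eta_full[a.id])
        kids = tree.children(a.id)
        if kids:
            weights = [c.distal_volume * c.multiplicity for c in kids]
            total = sum(weights)
            for c, wt in zip(kids, weights):
                T[c.id] = passed * (wt / total)

    # End-of-inspiration hold: aerosol parked in each record (fraction
    # sigma) splits between the duct lumen and the attached alveolar
    # sleeves in proportion to their volumes.  The alveolar share is held
    # until the expiration draws it back and settles onto the alveolar
    # walls with the capture efficiency; the lumen share only deposits
    # further during an explicit breath-hold.  Air that overshot a leaf
    # sits in the acinus beyond it and is subject to the same capture.
    pause_left: dict[str, np.ndarray] = {}
    leaf_over: dict[str, np.ndarray] = {}
    for a in order:
        stalled = T[a.id] * sigma[a.id] * (1.0 - eta_half[a.id])
        vol_alv = alv_vol[a.id]
        f_alv = vol_alv / (vol_alv + a.lumen_volume) if vol_alv > 0.0 else 0.0
        in_alv = stalled * f_alv
        in_duct = stalled - in_alv
        deposited[a.id] = deposited[a.id] + in_alv * eta_alv
        in_alv = in_alv * (1.0 - eta_alv)
        if t_pause > 0.0:
            q_eta = _quiescent_efficiency(a, t_pause, d_ae, gas)
            deposited[a.id] = deposited[a.id] + in_duct * q_eta
            in_duct = in_duct * (1.0 - q_eta)
        pause_left[a.id] = in_duct + in_alv
        if not tree.children(a.id):
            over = T[a.id] * rho[a.id] * (1.0 - eta_full[a.id])
            deposited[a.id] = deposited[a.id] + over * eta_alv
            leaf_over[a.id] = over * (1.0 - eta_alv)

    # Expiration sweep leaves→root: streams retrace their path; efficiencies
    # are re-applied with the flow reversed (same magnitudes).
    up: dict[str, np.ndarray] = {}
    for a in reversed(order):  # noqa: B007 — leaves first
        stream = np.zeros_like(d_ae)
        for c in tree.children(a.id):
            stream = stream + up[c.id]
        # air that turned around beyond the leaf re-enters it fully
        if a.id in leaf_over:
            deposited[a.id] = deposited[a.id] + leaf_over[a.id] * eta_full[a.id]
            stream = stream + leaf_over[a.id] * (1.0 - eta_full[a.id])
        # through-stream from deeper airways
        deposited[a.id] = deposited[a.id] + stream * eta_full[a.id]
        out = stream * (1.0 - eta_full[a.id])
        # air that stalled inside this record exits through its upper half
        out = out + pause_left[a.id] * (1.0 - eta_half[a.id])
        deposited[a.id] = deposited[a.id] + pause_left[a.id] * eta_half[a.id]
        up[a.id] = out
    # aerosol drawn in during the last moments of inspiration never clears
    # the head dead space; it is expelled with the expired stream
    head_resident = (1.0 - eta_et) * (1.0 - enter[tree.root.id])
    # the expired stream passes the head a second time before leaving
    stream_out = up[tree.root.id] + head_resident
    head_frac += float(np.sum(w * stream_out * eta_et))
    exhaled = float(np.sum(w * stream_out * (1.0 - eta_et)))

    per_airway_fraction = {aid: float(np.sum(w * dep)) for aid, dep in deposited.items()}
    tb = sum(f for aid, f in per_airway_fraction.items() if tree.get(aid).region == "TB")
    pul = sum(f for aid, f in per_airway_fraction.items() if tree.get(aid).region == "PUL")

    balance = head_frac + tb + pul + exhaled
    if abs(balance - 1.0) > 1e-9:
        raise RuntimeError(f"mass balance violated: sum of fractions = {balance!r}")

    # total inhaled mass over the exposure, µg
    total_inhaled = (
        scenario.aerosol.concentration_ug_cm3
        * vent.minute_volume
        * scenario.duration
        * 60.0
        * if_total
    )
    per_airway_mass = {
        aid: frac * total_inhaled / tree.get(aid).multiplicity
        for aid, frac in per_airway_fraction.items()
    }
    per_generation: dict[int, float] = {}
    for aid, frac in per_airway_fraction.items():
        g = tree.get(aid).generation
        per_generation[g] = per_generation.get(g, 0.0) + frac

    return DepositionResult(
        scenario=scenario,
        inhalable_fraction=if_total,
        per_airway_fraction=per_airway_fraction,
        per_airway_mass=per_airway_mass,
        regional={"head": head_frac, "TB": tb, "PUL": pul},
        exhaled_fraction=exhaled,
        total_inhaled_mass=total_inhaled,
        per_generation=dict(sorted(per_generation.items())),
    )
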