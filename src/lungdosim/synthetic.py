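"""Synthetic airway trees and exposure-scenario fixtures.

The asymmetric cast-based rat geometry used by multiple-path dosimetry
models is not publicly tabulated, so this module generates a *synthetic
monopodial surrogate*: a rat-like tree with 28 tracheobronchial
generations, pulmonary offshoots budding from generations 8-28, and eight
pulmonary generations appended to every complete tracheobronchial path
(total depth 36).  The surrogate reproduces the structural features the
analysis depends on (monopodial asymmetry, early pulmonary outgrowths,
desk-scale airway counts of order 10³-10⁴ conducting airways) but makes no
claim of anatomical fidelity to any specific lung cast.

Scenario fixtures reproduce the five exposure conditions of the acute
inhalation study: three rat nose-only exposures (5212, 2000 and 1084 mg/m³)
and human nasal and oral breathing at 5212 mg/m³, all 4 h at rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .aerosol import AerosolSpec, GasConditions
from .deposition import ExposureScenario, VentilationPattern
from .geometry import Airway, AirwayTree, builtin_human_tree, validate_tree

__all__ = ["TreeGenParams", "generate_monopodial_tree", "scenario_fixtures"]

#: Total alveolar volume appended to terminal pulmonary airways, cm³.
ALVEOLAR_VOLUME_CM3 = {"rat": 3.5, "human": 3000.0}

RAT_LOBES = ("left", "right_cranial", "right_middle", "right_caudal", "accessory")


@dataclass(frozen=True)
class TreeGenParams:
    """Parameters of the monopodial tree generator.

    ``diameter_ratio`` and ``length_to_diameter`` are (mean, spread) pairs of
    lognormal draws; ``asymmetry`` is the probability that a tracheobronchial
    airway inside ``pulmonary_offshoot_range`` buds a pulmonary offshoot;
    ``target_airway_count`` is the approximate number of tracheobronchial
    airways the tree should contain (the side-branching probability is solved
    from it).
    """

    species_template: str = "rat"
    n_tb_generations: int = 28
    pulmonary_offshoot_range: tuple[int, int] = (8, 28)
    terminal_pul_generations: int = 8
    diameter_ratio: tuple[float, float] = (0.90, 0.02)
    length_to_diameter: tuple[float, float] = (3.2, 0.5)
    asymmetry: float = 0.35
    target_airway_count: int = 6000
    seed: int = 0
    trachea_diameter_cm: float = 0.34
    trachea_length_cm: float = 2.30

    def __post_init__(self) -> None:
        if self.n_tb_generations < 1 or self.terminal_pul_generations < 1:
            raise ValueError("generation counts must be >= 1")
        if not (0.0 < self.diameter_ratio[0] <= 1.0):
            raise ValueError("diameter ratio mean must be in (0, 1]")
        if not (0.0 <= self.asymmetry <= 1.0):
            raise ValueError("asymmetry must be a probability")
        if self.target_airway_count < 1:
            raise ValueError("target_airway_count must be >= 1")
        lo, hi = self.pulmonary_offshoot_range
        if lo < 2 or hi > self.n_tb_generations:
            raise ValueError("pulmonary_offshoot_range outside the TB tree")


def _side_branch_probability(params: TreeGenParams) -> float:
    """Solve the TB side-branching probability for the target airway count.

    With each TB airway continuing one major daughter and spawning a minor
    TB daughter with probability p, the expected per-generation count grows
    as (1+p)**(g-1); the total TB count is ((1+p)**G - 1)/p.
    """
    G = params.n_tb_generations
    target = float(params.target_airway_count)
    if target <= G:
        return 0.0

    def excess(p: float) -> float:
        return ((1.0 + p) ** G - 1.0) / p - target

    if excess(1.0) < 0:
        return 1.0
    return float(optimize.brentq(excess, 1e-9, 1.0, xtol=1e-10))


def generate_monopodial_tree(params: TreeGenParams | None = None) -> AirwayTree:
    """Generate a reproducible monopodial (rat-like) airway tree.

    Identical ``params`` (including ``seed``) produce an identical tree.
    Child diameters are strictly smaller than their parent's.
    """
    params = params or TreeGenParams()
    rng = np.random.default_rng(params.seed)
    p_side = _side_branch_probability(params)
    lo_off, hi_off = params.pulmonary_offshoot_range
    max_depth = params.n_tb_generations + params.terminal_pul_generations

    dr_mean, dr_sd = params.diameter_ratio
    ld_mean, ld_sd = params.length_to_diameter

    def draw_ratio(scale: float = 1.0) -> float:
        mu = math.log(dr_mean * scale)
        sigma = dr_sd / dr_mean
        return float(np.exp(rng.normal(mu, sigma)))

    def draw_length(diameter: float) -> float:
        mu = math.log(ld_mean)
        sigma = ld_sd / ld_mean
        return float(diameter * np.exp(rng.normal(mu, sigma)))

    def draw_gravity() -> float:
        return float(np.clip(rng.normal(45.0, 15.0), 0.0, 90.0))

    airways: list[Airway] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter}"

    def add(a: Airway) -> Airway:
        airways.append(a)
        return a

    def pulmonary_chain(parent: Airway, n_gen: int) -> None:
        """Append a monopodial chain of pulmonary (acinar duct) airways."""
        prev = parent
        for _ in range(n_gen):
            d = min(
                max(prev.diameter * draw_ratio(0.95), 0.004),
                prev.diameter * 0.97,
            )
            prev = add(
                Airway(
                    id=new_id(),
                    parent_id=prev.id,
                    generation=prev.generation + 1,
                    region="PUL",
                    length=draw_length(d),
                    diameter=d,
                    branching_angle=float(np.clip(rng.normal(40.0, 10.0), 0.0, 90.0)),
                    gravity_angle=draw_gravity(),
                    multiplicity=1,
                    lobe=parent.lobe,
                )
            )

    trachea = add(
        Airway(
            id=new_id(),
            parent_id=None,
            generation=1,
            region="TB",
            length=params.trachea_length_cm,
            diameter=params.trachea_diameter_cm,
            branching_angle=0.0,
            gravity_angle=0.0,
            multiplicity=1,
            lobe=None,
        )
    )

    frontier = [trachea]
    lobe_cycle = 0
    for gen in range(1, params.n_tb_generations):
        # Side branches are allocated per generation (random placement, but
        # counts tracking the geometric growth schedule (1+p)^g): independent
        # per-airway coin flips would compound early fluctuations
        # multiplicatively and miss target_airway_count by factors of 2-3.
        scheduled_next = (1.0 + p_side) ** gen
        n_minor = int(np.clip(round(scheduled_next - len(frontier)), 0, len(frontier)))
        minor_parents = set(
            rng.choice(len(frontier), size=n_minor, replace=False).tolist()
        ) if n_minor else set()
        next_frontier: list[Airway] = []
        for idx, parent in enumerate(frontier):
            # dominant daughter continuing the monopodial trunk
            d_major = min(parent.diameter * draw_ratio(), parent.diameter * 0.97)
            major = add(
                Airway(
                    id=new_id(),
                    parent_id=parent.id,
                    generation=gen + 1,
                    region="TB",
                    length=draw_length(d_major),
                    diameter=d_major,
                    branching_angle=float(np.clip(rng.normal(15.0, 5.0), 0.0, 60.0)),
                    gravity_angle=draw_gravity(),
                    multiplicity=1,
                    lobe=parent.lobe,
                )
            )
            next_frontier.append(major)
            # lateral (minor) TB daughter
            if idx in minor_parents:
                d_minor = min(parent.diameter * draw_ratio(0.72), d_major * 0.97)
                if parent.lobe is None:
                    lobe = RAT_LOBES[lobe_cycle % len(RAT_LOBES)]
                    lobe_cycle += 1
                else:
                    lobe = parent.lobe
                minor = add(
                    Airway(
                        id=new_id(),
                        parent_id=parent.id,
                        generation=gen + 1,
                        region="TB",
                        length=draw_length(d_minor),
                        diameter=d_minor,
                        branching_angle=float(np.clip(rng.normal(60.0, 10.0), 0.0, 90.0)),
                        gravity_angle=draw_gravity(),
                        multiplicity=1,
                        lobe=lobe,
                    )
                )
                next_frontier.append(minor)
            # pulmonary offshoot budding off early TB generations
            if lo_off <= parent.generation <= hi_off and rng.random() < params.asymmetry:
                pulmonary_chain(
                    parent,
                    min(params.terminal_pul_generations, max_depth - parent.generation),
                )
        frontier = next_frontier
    # terminal pulmonary generations appended to every complete TB path
    for tip in frontier:
        pulmonary_chain(tip, params.terminal_pul_generations)

    tree = AirwayTree(
        airways=airways,
        species="rat" if params.species_template == "rat" else params.species_template,
        representation="asymmetric",
        body_weight=300.0 if params.species_template == "rat" else None,
        provenance=(
            f"synthetic monopodial surrogate (seed={params.seed}, "
            f"target TB count={params.target_airway_count})"
        ),
    )
    _assign_distal_volumes(tree, ALVEOLAR_VOLUME_CM3.get(tree.species, 3.5))
    problems = validate_tree(tree)
    if problems:
        raise RuntimeError(f"generated tree violates invariants: {problems[:5]}")
    return tree


def _assign_distal_volumes(tree: AirwayTree, alveolar_volume: float) -> None:
    """Fill distal volumes bottom-up: own lumen + children + alveoli on leaves."""
    leaves = [a for a in tree.airways if not tree.children(a.id)]
    alv_per_leaf = alveolar_volume / max(len(leaves), 1)
    distal: dict[str, float] = {}
    for a in reversed(tree.topological_order()):
        kids = tree.children(a.id)
        below = sum(distal[c.id] for c in kids) if kids else alv_per_leaf
        distal[a.id] = a.lumen_volume + below
    for i, a in enumerate(tree.airways):
        tree.airways[i] = Airway(
            id=a.id,
            parent_id=a.parent_id,
            generation=a.generation,
            region=a.region,
            length=a.length,
            diameter=a.diameter,
            branching_angle=a.branching_angle,
            gravity_angle=a.gravity_angle,
            multiplicity=a.multiplicity,
            lobe=a.lobe,
            distal_volume=distal[a.id],
        )
    tree.__post_init__()  # rebuild indices with the replaced records


# ---------------------------------------------------------------------------
# Exposure-scenario fixtures
# ---------------------------------------------------------------------------

RAT_VENTILATION = VentilationPattern(
    tidal_volume=2.12614, frequency=166.0, route="nose-only"
)
HUMAN_TIDAL_ML = 625.0
HUMAN_FREQUENCY_BPM = 12.0
EXPOSURE_DURATION_H = 4.0


def scenario_fixtures(seed: int = 0, rat_tree: AirwayTree | None = None) -> list[ExposureScenario]:
    """The five study exposure scenarios, ready to run.

    Three rat nose-only exposures on a shared synthetic monopodial surrogate
    tree (5212, 2000 and 1084 mg/m³) and human nasal plus oral breathing on
    the builtin symmetric tree at 5212 mg/m³; density 1 g/cm³ and a 4-h
    duration throughout.  Inhalability correction is applied for rats only.
    """
    if rat_tree is None:
        rat_tree = generate_monopodial_tree(TreeGenParams(seed=seed))
    human_tree = builtin_human_tree()
    gas = GasConditions()
    scenarios = []
    for conc, mmad, gsd in ((5212.0, 2.74, 2.8), (2000.0, 2.01, 3.0), (1084.0, 2.01, 3.0)):
        scenarios.append(
            ExposureScenario(
                aerosol=AerosolSpec(mmad=mmad, gsd=gsd, density=1.0, concentration=conc),
                ventilation=RAT_VENTILATION,
                tree=rat_tree,
                duration=EXPOSURE_DURATION_H,
                inhalability_on=True,
                gas=gas,
                label=f"rat nose-only {conc:g} mg/m3",
            )
        )
    for route in ("nasal", "oral"):
        scenarios.append(
            ExposureScenario(
                aerosol=AerosolSpec(mmad=2.74, gsd=2.8, density=1.0, concentration=5212.0),
                ventilation=VentilationPattern(
                    tidal_volume=HUMAN_TIDAL_ML, frequency=HUMAN_FREQUENCY_BPM, route=route
                ),
                tree=human_tree,
                duration=EXPOSURE_DURATION_H,
                inhalability_on=False,
                gas=gas,
                label=f"human {route} 5212 mg/m3",
            )
        )
    return scenarios
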