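"""Shared fixtures: trees, scenarios and cached deposition runs."""

from __future__ import annotations

import math

import pytest

import lungdosim as ld
from lungdosim.synthetic import TreeGenParams, generate_monopodial_tree, scenario_fixtures


@pytest.fixture(scope="session")
def human_tree():
    return ld.builtin_human_tree()


@pytest.fixture(scope="session")
def small_rat_params():
    # desk-scale surrogate for the engine tests; structure identical to the
    # default rat template, just fewer conducting airways
    return TreeGenParams(seed=11, target_airway_count=800)


@pytest.fixture(scope="session")
def small_rat_tree(small_rat_params):
    return generate_monopodial_tree(small_rat_params)


@pytest.fixture(scope="session")
def study_scenarios(small_rat_tree):
    """The five study scenarios, rat ones on the small surrogate tree."""
    return scenario_fixtures(seed=11, rat_tree=small_rat_tree)


@pytest.fixture(scope="session")
def nasal_result(study_scenarios):
    return ld.run_deposition(study_scenarios[3])


@pytest.fixture(scope="session")
def oral_result(study_scenarios):
    return ld.run_deposition(study_scenarios[4])


@pytest.fixture(scope="session")
def rat_results(study_scenarios):
    """Deposition for the three rat concentrations (5212, 2000, 1084 mg/m³)."""
    return [ld.run_deposition(s, n_bins=300) for s in study_scenarios[:3]]


def make_chain_tree(
    dims: list[tuple[float, float]],
    species: str = "human",
    gravity_angle: float = 45.0,
    branching_angles: list[float] | None = None,
) -> ld.AirwayTree:
    """A single-path chain of airways (multiplicity 1), no alveolar sleeves."""
    branching_angles = branching_angles or [0.0] + [30.0] * (len(dims) - 1)
    airways = []
    distal = [0.0] * (len(dims) + 1)
    for i in range(len(dims) - 1, -1, -1):
        length, diam = dims[i]
        distal[i] = math.pi / 4 * diam**2 * length + distal[i + 1]
    for i, (length, diam) in enumerate(dims):
        airways.append(
            ld.Airway(
                id=f"c{i + 1}",
                parent_id=f"c{i}" if i else None,
                generation=i + 1,
                region="TB",
                length=length,
                diameter=diam,
                branching_angle=branching_angles[i],
                gravity_angle=gravity_angle,
                multiplicity=1,
                distal_volume=distal[i],
            )
        )
    return ld.AirwayTree(
        airways=airways, species=species, representation="asymmetric",
        provenance="synthetic test chain",
    )
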