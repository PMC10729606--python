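"""Deposition engine: flows, single-airway efficiencies, whole-lung runs,
and the hand-unrolled serial-filtration oracle."""

import copy
import dataclasses
import math

import numpy as np
import pytest

import lungdosim as ld
from lungdosim import config
from lungdosim.aerosol import GasConditions
from lungdosim.deposition import ExposureScenario, VentilationPattern
from lungdosim.geometry import Airway

from conftest import make_chain_tree

GAS = GasConditions()

HUMAN_VENT = VentilationPattern(tidal_volume=625.0, frequency=12.0, route="nasal")


def _airway(**kw):
    base = dict(id="x", parent_id=None, generation=1, region="TB",
                length=1.0, diameter=0.3, branching_angle=30.0,
                gravity_angle=45.0, distal_volume=1.0)
    base.update(kw)
    return Airway(**base)


class TestAirwayFlows:
    def test_tracheal_flow_from_ventilation(self, human_tree):
        flows = ld.airway_flows(human_tree, HUMAN_VENT)
        # 625 mL over half a 5-s breath
        assert flows["G1"] == pytest.approx(250.0, rel=1e-12)

    def test_symmetric_child_flow_is_half(self, human_tree):
        flows = ld.airway_flows(human_tree, HUMAN_VENT)
        for g in range(1, 24):
            assert flows[f"G{g + 1}"] == pytest.approx(flows[f"G{g}"] / 2, rel=1e-9)

    def test_terminal_flows_conserve_root_flow(self, small_rat_tree):
        vent = VentilationPattern(tidal_volume=2.12614, frequency=166.0,
                                  route="nose-only")
        flows = ld.airway_flows(small_rat_tree, vent)
        leaves = [a for a in small_rat_tree.airways
                  if not small_rat_tree.children(a.id)]
        total = sum(flows[a.id] * a.multiplicity for a in leaves)
        assert total == pytest.approx(vent.mean_inspiratory_flow, rel=1e-9)

    def test_zero_distal_volume_rejected(self):
        root = _airway(id="r", distal_volume=0.0)
        child = _airway(id="c", parent_id="r", generation=2, distal_volume=0.0)
        tree = ld.AirwayTree([root, child], species="human",
                             representation="asymmetric")
        with pytest.raises(ValueError, match="distal volume"):
            ld.airway_flows(tree, HUMAN_VENT)


class TestSingleAirwayEfficiencies:
    def test_impaction_zero_for_straight_continuation(self):
        a = _airway(branching_angle=0.0)
        assert ld.efficiency_impaction(a, 100.0, ld.SizeBin(5.0, 1.0), GAS) == 0.0

    def test_impaction_vanishes_for_fine_particles(self):
        a = _airway()
        assert ld.efficiency_impaction(a, 100.0, ld.SizeBin(0.01, 1.0), GAS) < 1e-4

    def test_impaction_monotone_in_size_and_flow(self):
        a = _airway()
        e1 = ld.efficiency_impaction(a, 100.0, ld.SizeBin(1.0, 1.0), GAS)
        e4 = ld.efficiency_impaction(a, 100.0, ld.SizeBin(4.0, 1.0), GAS)
        e4_fast = ld.efficiency_impaction(a, 300.0, ld.SizeBin(4.0, 1.0), GAS)
        assert 0.0 <= e1 < e4 < e4_fast <= 1.0

    def test_sedimentation_zero_for_vertical_airway(self):
        a = _airway(gravity_angle=0.0)
        assert ld.efficiency_sedimentation(a, 10.0, ld.SizeBin(5.0, 1.0), GAS) == 0.0

    def test_sedimentation_vanishes_for_tiny_particles(self):
        a = _airway()
        assert ld.efficiency_sedimentation(a, 10.0, ld.SizeBin(0.01, 1.0), GAS) < 1e-4

    def test_sedimentation_increases_with_residence(self):
        short = _airway(length=0.5)
        long = _airway(length=1.0)
        b = ld.SizeBin(3.0, 1.0)
        assert ld.efficiency_sedimentation(long, 10.0, b, GAS) > \
            ld.efficiency_sedimentation(short, 10.0, b, GAS)

    def test_diffusion_limits(self):
        a = _airway(diameter=0.05, length=0.2)
        # ultrafine particle at near-zero flow: complete capture
        assert ld.efficiency_diffusion(a, 1e-6, ld.SizeBin(0.001, 1.0), GAS) == \
            pytest.approx(1.0, abs=1e-6)
        assert ld.efficiency_diffusion(a, 10.0, ld.SizeBin(0.01, 1.0), GAS) > \
            ld.efficiency_diffusion(a, 10.0, ld.SizeBin(1.0, 1.0), GAS)

    def test_all_efficiencies_bounded(self):
        a = _airway()
        for d in (0.01, 1.0, 10.0, 50.0):
            for fn in (ld.efficiency_impaction, ld.efficiency_sedimentation,
                       ld.efficiency_diffusion):
                assert 0.0 <= fn(a, 50.0, ld.SizeBin(d, 1.0), GAS) <= 1.0


class TestExtrathoracic:
    def test_vanishes_for_fine_particles(self):
        assert ld.extrathoracic_deposition("nasal", "human", 250.0,
                                           ld.SizeBin(0.01, 1.0)) < 1e-3

    def test_monotone_in_impaction_parameter(self):
        e = [ld.extrathoracic_deposition("nasal", "human", 250.0,
                                         ld.SizeBin(d, 1.0))
             for d in (0.5, 2.0, 8.0)]
        assert e[0] < e[1] < e[2] <= 1.0

    def test_unknown_route_species_pair_rejected(self):
        with pytest.raises(ValueError, match="extrathoracic"):
            ld.extrathoracic_deposition("oral", "rat", 10.0, ld.SizeBin(1.0, 1.0))


def _toy_scenario(concentration=5212.0, tidal=200.0, n_gens=3):
    tree = make_chain_tree(
        [(40.0, 1.5)] * n_gens, branching_angles=[0.0, 30.0, 30.0][:n_gens]
    )
    return ExposureScenario(
        aerosol=ld.AerosolSpec(mmad=2.74, gsd=2.8, density=1.0,
                               concentration=concentration),
        ventilation=VentilationPattern(tidal_volume=tidal, frequency=12.0,
                                       route="oral"),
        tree=tree,
        duration=4.0,
        inhalability_on=False,
    )


class TestRunDeposition:
    def test_mass_balance_on_toy_and_human(self, nasal_result):
        toy = ld.run_deposition(_toy_scenario(), n_bins=50)
        assert toy.mass_balance_error() < 1e-9
        assert nasal_result.mass_balance_error() < 1e-9

    def test_zero_concentration_zeroes_masses_not_fractions(self):
        ref = ld.run_deposition(_toy_scenario(), n_bins=50)
        zero = ld.run_deposition(_toy_scenario(concentration=0.0), n_bins=50)
        assert zero.total_inhaled_mass == 0.0
        assert all(m == 0.0 for m in zero.per_airway_mass.values())
        for aid, f in ref.per_airway_fraction.items():
            assert zero.per_airway_fraction[aid] == pytest.approx(f, rel=1e-12)

    def test_fractions_concentration_invariant_masses_linear(self):
        base = ld.run_deposition(_toy_scenario(concentration=1084.0), n_bins=50)
        for mult in (2.0, 10.0):
            scaled = ld.run_deposition(
                _toy_scenario(concentration=1084.0 * mult), n_bins=50
            )
            for region in ("head", "TB", "PUL"):
                assert scaled.regional[region] == pytest.approx(
                    base.regional[region], rel=1e-12
                )
            for aid in base.per_airway_mass:
                assert scaled.per_airway_mass[aid] == pytest.approx(
                    base.per_airway_mass[aid] * mult, rel=1e-9
                )

    def test_total_inhaled_mass_arithmetic(self, rat_results):
        res = rat_results[0]
        expected = 5.212 * 2.12614 * 166.0 * 240.0 * res.inhalable_fraction
        assert res.total_inhaled_mass == pytest.approx(expected, rel=1e-9)
        assert res.total_inhaled_mass == pytest.approx(4.4e5 * res.inhalable_fraction,
                                                       rel=0.01)

    def test_symmetric_generations_receive_equal_per_airway_fractions(self):
        # expanded 4-generation dichotomous tree: all airways of a generation
        # must be indistinguishable to the engine
        dims = [(10.0, 2.0), (5.0, 1.5), (3.0, 1.0), (2.0, 0.7)]
        airways = []
        counter = [0]

        def add(parent, gen):
            counter[0] += 1
            aid = f"a{counter[0]}"
            length, diam = dims[gen - 1]
            airways.append(Airway(
                id=aid, parent_id=parent, generation=gen, region="TB",
                length=length, diameter=diam, branching_angle=0.0 if gen == 1 else 35.0,
                gravity_angle=50.0, distal_volume=0.0,
            ))
            if gen < 4:
                add(aid, gen + 1)
                add(aid, gen + 1)

        add(None, 1)
        # distal volumes bottom-up
        by_id = {a.id: a for a in airways}
        children = {a.id: [] for a in airways}
        for a in airways:
            if a.parent_id:
                children[a.parent_id].append(a.id)
        def fill(aid):
            a = by_id[aid]
            below = sum(fill(c) for c in children[aid])
            total = a.lumen_volume + below + (0.5 if not children[aid] else 0.0)
            by_id[aid] = dataclasses.replace(a, distal_volume=total)
            return total
        fill("a1")
        tree = ld.AirwayTree(list(by_id.values()), species="human",
                             representation="asymmetric")
        scen = ExposureScenario(
            aerosol=ld.AerosolSpec(2.74, 2.8, 1.0, 5212.0),
            ventilation=VentilationPattern(100.0, 12.0, route="oral"),
            tree=tree, duration=4.0,
        )
        res = ld.run_deposition(scen, n_bins=40)
        by_gen = {}
        for aid, frac in res.per_airway_fraction.items():
            by_gen.setdefault(by_id[aid].generation, []).append(frac)
        for gen, fracs in by_gen.items():
            assert max(fracs) == pytest.approx(min(fracs), rel=1e-9), gen

    def test_human_terminal_generations_receive_nothing(self, nasal_result):
        for g in (22, 23, 24):
            assert nasal_result.per_generation[g] <= 1e-12
        assert nasal_result.per_generation[17] > 1e-3

    def test_pause_increases_deposition(self):
        base = ld.run_deposition(_toy_scenario(), n_bins=50)
        scen = _toy_scenario()
        scen.ventilation = VentilationPattern(
            tidal_volume=200.0, frequency=12.0, route="oral",
            inspiratory_fraction=0.4, pause_fraction=0.2,
        )
        paused = ld.run_deposition(scen, n_bins=50)
        assert paused.regional["TB"] > base.regional["TB"]
        assert paused.mass_balance_error() < 1e-9

    def test_invalid_tree_rejected(self):
        scen = _toy_scenario()
        bad = copy.copy(scen)
        bad.tree = ld.AirwayTree(
            [_airway(id="r"), _airway(id="c", parent_id="ghost", generation=2)],
            species="human", representation="asymmetric",
        )
        with pytest.raises(ValueError, match="invalid tree"):
            ld.run_deposition(bad, n_bins=10)


class TestSerialFiltrationOracle:
    """Hand-unrolled 3-generation, 2-bin serial filtration, scalar arithmetic."""

    def test_engine_matches_hand_unrolled_calculation(self):
        scen = _toy_scenario()
        res = ld.run_deposition(scen, n_bins=2)

        # --- independent scalar reconstruction -------------------------
        bins = ld.discretize_lognormal(scen.aerosol, n_bins=2)
        vent = scen.ventilation
        q = vent.tidal_volume / (0.5 * 60.0 / vent.frequency)  # 80 cm³/s
        t_insp = 0.5 * 60.0 / vent.frequency
        coeff = config.EXTRATHORACIC[("human", "oral")]
        airways = scen.tree.airways
        et_volume = config.ET_DEAD_SPACE_CM3["human"]

        per_airway = {a.id: 0.0 for a in airways}
        head = 0.0
        exhaled = 0.0
        for b in bins:
            w = b.mass_fraction
            d = b.d_ae
            # particle-side physics
            lam = GAS.mean_free_path
            slip = 1.0 + lam / d * (2.514 + 0.8 * math.exp(-0.55 * d / lam))
            vts = (d * 1e-4) ** 2 * GAS.gravity * slip / (18.0 * GAS.air_viscosity)
            dif = (config.BOLTZMANN_ERG_PER_K * GAS.temperature * slip /
                   (3.0 * math.pi * GAS.air_viscosity * d * 1e-4))
            eta_et = 1.0 - math.exp(
                -coeff["a"] * (d**2 * q * 60.0 / 1000.0) ** coeff["b"]
            )

            eta, eta_h = [], []
            tau = [et_volume / q]
            for a in airways:
                u = q / (math.pi / 4.0 * a.diameter**2)
                theta = math.radians(a.branching_angle)
                if theta > 0.0:
                    eps = min(theta * vts * u / (GAS.gravity * a.diameter), 1.0)
                    e_i = (1.0 - 2.0 / math.pi * math.acos(eps)
                           + 1.0 / math.pi * math.sin(2.0 * math.acos(eps)))
                else:
                    e_i = 0.0
                k = (4.0 / math.pi) * a.length * math.sin(
                    math.radians(a.gravity_angle)) / (a.diameter * u)
                e_s = 1.0 - math.exp(-k * vts)
                x = dif * a.length / (4.0 * u * (a.diameter / 2.0) ** 2)
                def ingham(xx):
                    return (1.0 - 0.819 * math.exp(-14.63 * xx)
                            - 0.0976 * math.exp(-89.22 * xx)
                            - 0.0325 * math.exp(-228.0 * xx)
                            - 0.0509 * math.exp(-125.9 * xx ** (2.0 / 3.0)))
                eta.append(1 - (1 - e_i) * (1 - e_s) * (1 - ingham(x)))
                eta_h.append(1 - (1 - e_i) * math.sqrt(1 - e_s)
                             * (1 - ingham(x / 2.0)))
                tau.append(tau[-1] + a.lumen_volume / q)
            enter = [max(0.0, 1.0 - tau[i] / t_insp) for i in range(3)]
            rho = [max(0.0, 1.0 - tau[i + 1] / t_insp) for i in range(3)]
            sigma = [max(0.0, enter[i] - rho[i]) for i in range(3)]

            T = [0.0] * 3
            T[0] = 1.0 - eta_et
            for i in (1, 2):
                T[i] = T[i - 1] * (1.0 - eta[i - 1])
            dep = [T[i] * (rho[i] * eta[i] + sigma[i] * eta_h[i]) for i in range(3)]
            left = [T[i] * sigma[i] * (1.0 - eta_h[i]) for i in range(3)]
            up = T[2] * rho[2] * 0.0  # the front never clears the leaf
            for i in (2, 1, 0):
                dep[i] += up * eta[i] + left[i] * eta_h[i]
                up = up * (1.0 - eta[i]) + left[i] * (1.0 - eta_h[i])
            head_resident = (1.0 - eta_et) * (1.0 - enter[0])
            out = up + head_resident
            head += w * (eta_et + out * eta_et)
            exhaled += w * out * (1.0 - eta_et)
            for i, a in enumerate(airways):
                per_airway[a.id] += w * dep[i]
        # ----------------------------------------------------------------

        assert res.regional["head"] == pytest.approx(head, rel=1e-12)
        assert res.exhaled_fraction == pytest.approx(exhaled, rel=1e-12)
        for aid, frac in per_airway.items():
            assert res.per_airway_fraction[aid] == pytest.approx(frac, rel=1e-12)
        total = head + exhaled + sum(per_airway.values())
        assert total == pytest.approx(1.0, abs=1e-12)
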