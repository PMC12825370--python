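import numpy as np
import pytest

from xrrfilm import (
    OLEIC_ACID,
    POLYSORBATE_80,
    WATER,
    InterfaceModel,
    Slab,
    SpeciesFragments,
    area_from_excess,
    area_per_molecule,
    electrons_from_formula,
    mixed_layer_composition,
    molar_surface_ratio,
    surface_excess,
    volume_balance_residual,
    waters_from_excesses,
    waters_per_headgroup,
)
from xrrfilm.synthetic_data import make_scenario, stack_from_composition

from conftest import OA_349, OA_454


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "formula,expected",
        [("H2O", 10), ("C17H33", 135), ("CO2H", 23), ("C18H34O2", 158),
         ("C64H124O26", 716)],
    )
    def test_known_molecules(self, formula, expected):
        assert electrons_from_formula(formula) == expected

    @pytest.mark.parametrize("bad", ["C17X3", "h2o", "C17-H33", ""])
    def test_malformed_formula_rejected(self, bad):
        with pytest.raises(ValueError):
            electrons_from_formula(bad)

    def test_builtin_fragments_are_consistent(self):
        for frag in (OLEIC_ACID, POLYSORBATE_80, WATER):
            assert frag.electrons_tail + frag.electrons_head == pytest.approx(
                frag.electrons_total
            )
        assert OLEIC_ACID.electrons_total == 158
        assert OLEIC_ACID.electrons_tail == 135
        assert POLYSORBATE_80.molar_mass == 1310.0

    def test_inconsistent_fragments_rejected(self):
        with pytest.raises(ValueError):
            SpeciesFragments(name="bad", molar_mass=100.0, electrons_total=50,
                             electrons_tail=30, electrons_head=30)


class TestTwoSlabBalances:
    """The printed OA slab parameters reproduce the derived film quantities."""

    def test_area_per_molecule_low_compression(self):
        a = area_per_molecule(Slab(OA_454["d1"], OA_454["rho1"]), 135)
        assert a == pytest.approx(40.70, rel=0.01)

    def test_area_per_molecule_high_compression(self):
        a = area_per_molecule(Slab(OA_349["d1"], OA_349["rho1"]), 135)
        assert a == pytest.approx(38.19, rel=0.01)

    def test_surface_excess_low_compression(self):
        a = area_per_molecule(Slab(OA_454["d1"], OA_454["rho1"]), 135)
        assert surface_excess(282.46, a) == pytest.approx(1.15, rel=0.01)

    def test_waters_per_headgroup_low_compression(self):
        a = area_per_molecule(Slab(OA_454["d1"], OA_454["rho1"]), 135)
        nw = waters_per_headgroup(Slab(OA_454["d2"], OA_454["rho2"]), a, 23)
        assert nw == pytest.approx(4.8, rel=0.02)

    def test_waters_per_headgroup_high_compression(self):
        a = area_per_molecule(Slab(OA_349["d1"], OA_349["rho1"]), 135)
        nw = waters_per_headgroup(Slab(OA_349["d2"], OA_349["rho2"]), a, 23)
        assert nw == pytest.approx(5.8, rel=0.02)

    def test_water_excess_low_compression(self):
        a = area_per_molecule(Slab(OA_454["d1"], OA_454["rho1"]), 135)
        nw = waters_per_headgroup(Slab(OA_454["d2"], OA_454["rho2"]), a, 23)
        gw = surface_excess(18.015, a / nw)
        assert gw == pytest.approx(0.35, rel=0.03)

    def test_head_slab_too_dilute_rejected(self):
        with pytest.raises(ValueError, match="fewer electrons"):
            waters_per_headgroup(Slab(5.0, 0.05), 40.0, 23)


class TestExcessIdentities:
    def test_area_excess_round_trip(self):
        a = 40.7
        assert area_from_excess(282.46, surface_excess(282.46, a)) == pytest.approx(a)

    def test_waters_from_excesses_ps80_at_cmc(self):
        # measured PS80 and water excesses at the cmc imply ~66 waters/headgroup
        assert waters_from_excesses(1.63, 1.79, 1310.0) == pytest.approx(
            66.20, rel=0.01
        )

    def test_molar_surface_ratio_mixed_film(self):
        # surface OA/PS80 molar ratio at bulk ratio 5.9
        assert molar_surface_ratio(1.34, 1.09, 282.46, 1310.0) == pytest.approx(
            5.69, rel=0.01
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            surface_excess(282.46, 0.0)
        with pytest.raises(ValueError):
            area_from_excess(282.46, 0.0)
        with pytest.raises(ValueError):
            waters_from_excesses(1.0, 0.0, 1310.0)
        with pytest.raises(ValueError):
            molar_surface_ratio(1.0, 0.0, 282.46, 1310.0)


class TestMixedLayerSolver:
    def test_two_slab_oa_matches_direct_balances(self):
        slabs = (Slab(OA_454["d1"], OA_454["rho1"]),
                 Slab(OA_454["d2"], OA_454["rho2"]))
        oa = OLEIC_ACID
        partition = {
            "OA": [oa.electrons_tail / oa.electrons_total,
                   oa.electrons_head / oa.electrons_total],
            "water": [0.0, 1.0],
        }
        sol = mixed_layer_composition(slabs, {"OA": oa}, partition)
        a_direct = area_per_molecule(slabs[0], 135)
        nw_direct = waters_per_headgroup(slabs[1], a_direct, 23)
        assert sol.composition.area_per_molecule == pytest.approx(a_direct, rel=1e-9)
        assert sol.composition.waters_per_headgroup == pytest.approx(
            nw_direct, rel=1e-9
        )
        assert np.all(sol.residuals < 1e-9)

    def test_three_slab_round_trip(self):
        """Forward-constructed mixed stack inverts back to its composition."""
        truth = make_scenario("mixed-3-slab")
        sol = mixed_layer_composition(
            truth.model.slabs, truth.fragments, truth.partition
        )
        assert sol.composition.gamma["OA"] == pytest.approx(1.34, rel=1e-6)
        assert sol.composition.gamma["PS80"] == pytest.approx(1.09, rel=1e-6)
        assert sol.composition.gamma_water == pytest.approx(1.51, rel=1e-6)

    def test_round_trip_fuzzing(self):
        """Random compositions and partitions always invert exactly."""
        rng = np.random.default_rng(7)
        fragments = {"OA": OLEIC_ACID, "PS80": POLYSORBATE_80}
        for _ in range(25):
            counts = {"OA": rng.uniform(0.005, 0.03),
                      "PS80": rng.uniform(0.0002, 0.002)}
            water = rng.uniform(0.01, 0.08)
            head2 = rng.uniform(0.2, 0.8)
            w2 = rng.uniform(0.1, 0.9)
            partition = {
                "OA": [135 / 158, 23 / 158, 0.0],
                "PS80": [135 / 716, head2 * 581 / 716, (1 - head2) * 581 / 716],
                "water": [0.0, w2, 1 - w2],
            }
            thick = rng.uniform(8, 20, 3).tolist()
            model = stack_from_composition(counts, water, fragments, partition,
                                           thick, sigma=3.0)
            sol = mixed_layer_composition(model.slabs, fragments, partition)
            for k, c in counts.items():
                assert sol.counts[k] == pytest.approx(c, rel=1e-6)
            assert sol.water_count == pytest.approx(water, rel=1e-6)

    def test_missing_water_partition_rejected(self):
        with pytest.raises(ValueError, match="water"):
            mixed_layer_composition((Slab(10, 0.3),), {"OA": OLEIC_ACID},
                                    {"OA": [1.0]})

    def test_partition_not_summing_to_one_rejected(self):
        slabs = (Slab(10, 0.3), Slab(5, 0.35))
        with pytest.raises(ValueError, match="sum to 1"):
            mixed_layer_composition(
                slabs, {"OA": OLEIC_ACID},
                {"OA": [0.5, 0.4], "water": [0.0, 1.0]},
            )

    def test_negative_counts_trigger_nonnegative_refit(self):
        # a head slab far too dilute for the forced partition drives the
        # unconstrained water count negative
        slabs = (Slab(10.0, 0.45), Slab(5.0, 0.02))
        partition = {"OA": [135 / 158, 23 / 158], "water": [0.0, 1.0]}
        with pytest.warns(UserWarning, match="non-negativity"):
            sol = mixed_layer_composition(slabs, {"OA": OLEIC_ACID}, partition)
        assert sol.water_count >= 0.0


class TestVolumeBalance:
    def test_consistent_volumes_give_small_residual(self):
        truth = make_scenario("OA-monolayer")
        sol = mixed_layer_composition(truth.model.slabs, truth.fragments,
                                      truth.partition)
        count = sol.counts["OA"]
        nw_slab2 = sol.water_per_slab[1]
        d1, d2 = (s.thickness for s in truth.model.slabs)
        # volumes chosen to exactly fill each slab: residual ~ 0
        v_tail = d1 / count
        v_head = (d2 - nw_slab2 * 29.9) / count
        res = volume_balance_residual(
            truth.model.slabs, sol, {"OA": [v_tail, v_head]}
        )
        assert np.all(res < 1e-9)

    def test_missing_volumes_rejected(self):
        truth = make_scenario("OA-monolayer")
        sol = mixed_layer_composition(truth.model.slabs, truth.fragments,
                                      truth.partition)
        with pytest.raises(ValueError, match="missing"):
            volume_balance_residual(truth.model.slabs, sol, {})
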