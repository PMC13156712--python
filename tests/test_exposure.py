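"""Tier equations: oracles, round trips, homogeneity, tier selection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophicast.core import Guild, Matrix, ResidueRecord, Tissue, Units, ValidationError
from trophicast.exposure import (
    add_carnivore_tier2,
    add_herbivore_tier2,
    add_omnivore,
    add_tier1,
    carnivore_tissue,
    herbivore_tissue_from_plant,
    reconstruct_doses,
    run_foodchain,
    run_tier3_chain,
    select_tier,
    weighted_tissue_mean,
)
from trophicast.plant import PlantUptakeParams, baf_plant

positive = st.floats(0.01, 1e3, allow_nan=False)


class TestTier1:
    def test_unit_constructed_value(self):
        est = add_tier1(2.0, btf=0.5, bw=4.0)
        assert est.add == pytest.approx(1.0)
        assert est.tier == 1

    def test_zero_tissue_gives_zero(self):
        assert add_tier1(0.0, btf=1.0, bw=1.0).add == 0.0

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValidationError):
            add_tier1(1.0, btf=0.0, bw=1.0)
        with pytest.raises(ValidationError):
            add_tier1(1.0, btf=1.0, bw=-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(btf=positive, ir=positive, bw=positive, c_food=positive)
    def test_reverse_dosimetry_round_trip(self, btf, ir, bw, c_food):
        """Forward tissue simulation then Tier-1 inversion returns IR·C/BW."""
        tissue = herbivore_tissue_from_plant(
            {Tissue.MUSCLE: btf}, ir, c_food, tissues=(Tissue.MUSCLE,)
        )[Tissue.MUSCLE]
        est = add_tier1(tissue, btf=btf, bw=bw)
        assert est.add == pytest.approx(ir * c_food / bw, rel=1e-12)


class TestTier2:
    @pytest.mark.parametrize(
        "c_plant, ir, bw, expected",
        [(1.0, 1.0, 1.0, 1.0), (0.5, 2.0, 10.0, 0.1), (0.0, 3.0, 5.0, 0.0)],
    )
    def test_herbivore(self, c_plant, ir, bw, expected):
        assert add_herbivore_tier2(c_plant, ir, bw).add == pytest.approx(expected)

    @pytest.mark.parametrize(
        "c_bar, ir, bw, expected",
        [(1.0, 1.0, 1.0, 1.0), (3.0, 0.4, 6.0, 0.2), (0.0, 1.0, 1.0, 0.0)],
    )
    def test_carnivore(self, c_bar, ir, bw, expected):
        assert add_carnivore_tier2(c_bar, ir, bw).add == pytest.approx(expected)

    @pytest.mark.parametrize(
        "btf, ir, c, expected",
        [(1.0, 1.0, 1.0, 1.0), (0.0001, 1.0, 0.0, 0.0), (0.3, 2.0, 0.5, 0.3)],
    )
    def test_tissue_forward_model(self, btf, ir, c, expected):
        out = herbivore_tissue_from_plant(
            {Tissue.MUSCLE: btf} if btf > 0 else {}, ir, c,
            tissues=(Tissue.MUSCLE,) if btf > 0 else (),
        )
        if btf > 0:
            assert out[Tissue.MUSCLE] == pytest.approx(expected)

    def test_missing_btf_names_tissue(self):
        with pytest.raises(ValidationError, match="fat"):
            herbivore_tissue_from_plant({Tissue.MUSCLE: 1.0}, 1.0, 1.0)

    def test_carnivore_tissue_mirrors_herbivore(self):
        btf = {Tissue.MUSCLE: 0.3, Tissue.FAT: 0.7}
        assert carnivore_tissue(btf, 2.0, 0.5) == herbivore_tissue_from_plant(btf, 2.0, 0.5)


class TestWeightedMean:
    def test_equal_weights_is_arithmetic_mean(self):
        conc = {Tissue.MUSCLE: 2.0, Tissue.FAT: 4.0}
        weights = {Tissue.MUSCLE: 1.0, Tissue.FAT: 1.0}
        assert weighted_tissue_mean(conc, weights) == pytest.approx(3.0)

    def test_single_weight_selects_tissue(self):
        conc = {Tissue.MUSCLE: 2.0, Tissue.FAT: 4.0}
        assert weighted_tissue_mean(conc, {Tissue.FAT: 1.0}) == pytest.approx(4.0)

    def test_weighted_mean_oracle(self):
        conc = {Tissue.MUSCLE: 1.0, Tissue.FAT: 5.0}
        weights = {Tissue.MUSCLE: 3.0, Tissue.FAT: 1.0}
        assert weighted_tissue_mean(conc, weights) == pytest.approx(2.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError, match="[Dd]egenerate"):
            weighted_tissue_mean({Tissue.MUSCLE: 1.0}, {Tissue.MUSCLE: 0.0})


class TestOmnivore:
    def test_pure_plant_diet_reduces_to_herbivore_equation(self):
        o = add_omnivore(0.7, 9.9, 9.9, (1.0, 0.0, 0.0), ir=2.0, bw=5.0)
        h = add_herbivore_tier2(0.7, 2.0, 5.0)
        assert o.add == pytest.approx(h.add)

    def test_pure_herbivore_diet(self):
        assert add_omnivore(0.0, 1.0, 0.0, (0.0, 1.0, 0.0), 1.0, 1.0).add == pytest.approx(1.0)

    def test_mixed_diet_oracle(self):
        est = add_omnivore(1.0, 2.0, 5.0, (0.5, 0.3, 0.2), ir=1.0, bw=2.0)
        assert est.add == pytest.approx(1.05)

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            add_omnivore(1.0, 1.0, 1.0, (0.5, 0.4, 0.3), 1.0, 1.0)


class TestChains:
    def test_tier3_equals_tier2_when_modeled_plant_matches(self, roster):
        """Forcing C_plant,model = C_plant,measured collapses Tier 3 to Tier 2."""
        c_plant = 0.034
        c_soil = 0.85
        # params built so BAF = c_plant / c_soil exactly
        params = PlantUptakeParams(
            q_transpiration=c_plant / c_soil, kd=1.0, alh=1.0, g=1.0,
            kla=1000.0, lambda_loss=0.0, mlh=1.0,
        )
        assert baf_plant(params) == pytest.approx(c_plant / c_soil)
        tier2 = run_foodchain(c_plant, roster, tier=2)
        tier3 = run_tier3_chain(c_soil, params, roster)
        assert len(tier2) == len(tier3) > 0
        for e2, e3 in zip(tier2, tier3):
            assert e3.species == e2.species
            assert e3.tier == 3
            assert e3.add == pytest.approx(e2.add, rel=1e-12)

    def test_zero_soil_zeroes_all_guilds(self, roster):
        params = PlantUptakeParams(
            q_transpiration=1.0, kd=1.0, alh=1.0, g=1.0, kla=1000.0,
            lambda_loss=0.0, mlh=1.0,
        )
        for est in run_tier3_chain(0.0, params, roster):
            assert est.add == 0.0

    def test_full_chain_matches_hand_computation(self, roster):
        """Step-by-step nested-product oracle through all four species."""
        c_plant = 0.01
        ests = {e.species: e.add for e in run_foodchain(c_plant, roster, tier=2)}
        rabbit, deer = roster["rabbit"], roster["deer"]
        fox, boar = roster["fox"], roster["wild_boar"]

        assert ests["rabbit"] == pytest.approx(c_plant * 0.12 / 1.8)
        # prey means per herbivore, then roster average
        rb = {t: rabbit.btf_by_tissue[t] * 0.12 * c_plant for t in (Tissue.MUSCLE, Tissue.FAT)}
        de = {t: deer.btf_by_tissue[t] * 2.2 * c_plant for t in (Tissue.MUSCLE, Tissue.FAT)}
        cb_h = (
            (rb[Tissue.MUSCLE] * 0.65 + rb[Tissue.FAT] * 0.35)
            + (de[Tissue.MUSCLE] * 0.7 + de[Tissue.FAT] * 0.3)
        ) / 2
        assert ests["fox"] == pytest.approx(cb_h * 0.45 / 6.0, rel=1e-12)
        fx = {t: fox.btf_by_tissue[t] * 0.45 * cb_h for t in (Tissue.MUSCLE, Tissue.FAT)}
        cb_c = fx[Tissue.MUSCLE] * 0.6 + fx[Tissue.FAT] * 0.4
        mix = 0.5 * c_plant + 0.3 * cb_h + 0.2 * cb_c
        assert ests["wild_boar"] == pytest.approx(mix * 3.5 / 90.0, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(0.01, 100.0), c=st.floats(0.001, 10.0))
    def test_homogeneity_in_source_concentration(self, roster, k, c):
        base = {e.species: e.add for e in run_foodchain(c, roster, tier=2)}
        scaled = {e.species: e.add for e in run_foodchain(k * c, roster, tier=2)}
        for sp in base:
            assert scaled[sp] == pytest.approx(k * base[sp], rel=1e-10)

    def test_add_decreasing_in_bw_increasing_in_ir(self):
        assert add_herbivore_tier2(1.0, 2.0, 5.0).add > add_herbivore_tier2(1.0, 2.0, 9.0).add
        assert add_herbivore_tier2(1.0, 3.0, 5.0).add > add_herbivore_tier2(1.0, 2.0, 5.0).add

    def test_trophic_magnification_with_strong_links(self, magnifying_roster):
        """BTF·IR > 1 per link makes burdens grow up the chain."""
        c_plant = 0.01
        run_foodchain(c_plant, magnifying_roster, tier=2)
        vole = magnifying_roster["vole"]
        tissues = herbivore_tissue_from_plant(vole.btf_by_tissue, vole.ir_kg_per_day, c_plant)
        c_bar_herb = weighted_tissue_mean(tissues, vole.tissue_weights)
        stoat = magnifying_roster["stoat"]
        c_bar_carn = weighted_tissue_mean(
            carnivore_tissue(stoat.btf_by_tissue, stoat.ir_kg_per_day, c_bar_herb),
            stoat.tissue_weights,
        )
        assert c_bar_carn > c_bar_herb > c_plant


class TestTierSelection:
    @pytest.mark.parametrize(
        "tissue, plant, soil, expected",
        [
            (True, True, True, 1),
            (False, True, True, 2),
            (False, False, True, 3),
            (False, False, False, None),
        ],
    )
    def test_most_direct_data_rule(self, tissue, plant, soil, expected):
        assert select_tier(tissue, plant, soil) == expected

    def test_dataset_tiers_follow_availability(self, roster):
        def soil_rec(country):
            return ResidueRecord(
                country=country, site_id=f"{country}-s", matrix=Matrix.SOIL,
                chemical_cas="50-29-3", concentration=100.0, units=Units.NG_PER_G_DW,
            )

        def plant_rec(country):
            return ResidueRecord(
                country=country, site_id=f"{country}-s", matrix=Matrix.WILD_PLANT,
                chemical_cas="50-29-3", concentration=10.0, units=Units.NG_PER_G,
            )

        def liver_rec(country):
            return ResidueRecord(
                country=country, site_id=f"{country}-s", matrix=Matrix.ANIMAL,
                species="rabbit", guild=Guild.HERBIVORE, tissue=Tissue.LIVER,
                chemical_cas="50-29-3", concentration=50.0,
                units=Units.NG_PER_G_LIPID, lipid_fraction=0.06,
            )

        records = [
            liver_rec("t1"), plant_rec("t1"), soil_rec("t1"),
            plant_rec("t2"), soil_rec("t2"),
            soil_rec("t3"),
        ]
        params = {"50-29-3": PlantUptakeParams(
            q_transpiration=0.1, kd=1.0, alh=1.0, g=1.0, kla=1000.0,
            lambda_loss=0.0, mlh=1.0,
        )}
        rabbit_only = {"rabbit": roster["rabbit"]}
        ests = reconstruct_doses(records, rabbit_only, params)
        tiers = {e.country: e.tier for e in ests if e.species == "rabbit"}
        assert tiers == {"t1": 1, "t2": 2, "t3": 3}
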