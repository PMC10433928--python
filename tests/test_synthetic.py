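import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from hydrotrait import synthetic, traits, units
from hydrotrait.gs_model import leaf_vpd


def _csv_bytes(df):
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue().encode()


class TestConfigValidation:
    def test_rejects_inverted_d_range(self):
        with pytest.raises(ValueError):
            synthetic.default_config(d_min=4.5, d_max=0.1)

    def test_rejects_interval_not_dividing_day(self):
        with pytest.raises(ValueError):
            synthetic.default_config(interval_minutes=7)

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            synthetic.default_config(sigma_gs=-0.1)

    def test_rejects_nonpositive_preset(self):
        with pytest.raises(ValueError):
            synthetic.SpeciesPreset(
                name="bad", hv=-1.0, gsref=0.2, m=0.1, kplant=1.0,
                vessel_mu=3.5, vessel_sigma=0.3, vessel_density_mm2=80,
                stomatal_density_mm2=300, stomatal_size_um2=260,
                pore_fraction=0.12, allom_c0=1.5, allom_c1=2.0,
                vein_density_mm_mm2=8.0)


class TestSeedDeterminism:
    def test_identical_seed_identical_bytes(self):
        a = synthetic.simulate_campaign(synthetic.default_config(seed=5))
        b = synthetic.simulate_campaign(synthetic.default_config(seed=5))
        for attr in ("met", "gas", "flux", "water_potentials",
                     "tree_meta", "tree_branches"):
            assert _csv_bytes(getattr(a, attr)) == _csv_bytes(
                getattr(b, attr))
        for key in a.anatomy:
            assert _csv_bytes(a.anatomy[key]) == _csv_bytes(b.anatomy[key])
        assert synthetic.truth_to_json(a.truth) == synthetic.truth_to_json(
            b.truth)

    def test_different_seed_differs(self):
        a = synthetic.simulate_campaign(synthetic.default_config(seed=5))
        b = synthetic.simulate_campaign(synthetic.default_config(seed=6))
        assert _csv_bytes(a.flux) != _csv_bytes(b.flux)


class TestDiurnal:
    def test_d_consistent_with_tleaf_rh(self, noisy_campaign):
        """Recomputing D from the stored leaf temperature and RH
        reproduces the stored column."""
        met = noisy_campaign.met
        d = leaf_vpd(met["Tleaf_C"], met["Tair_C"], met["RH_frac"])
        assert np.allclose(d, met["D_kPa"], atol=1e-9)

    def test_d_ramp_covers_declared_range(self, noisy_campaign):
        met = noisy_campaign.met
        assert met["D_kPa"].max() == pytest.approx(4.5, abs=1e-9)
        assert met["D_kPa"].min() >= 0.0

    def test_zero_noise_flux_is_exact_model_inversion(
            self, zero_noise_config, zero_noise_campaign):
        """sigma_Js = 0: gs*D/(C*Hv) equals Js at every timestamp."""
        camp = zero_noise_campaign
        factor = zero_noise_config.constant.js_to_gs
        met = camp.met.set_index("timestamp")
        for tree_id, truth in camp.truth["trees"].items():
            f = camp.flux[camp.flux["tree_id"] == tree_id]
            d = met.loc[f["timestamp"], "D_kPa"].to_numpy()
            gs_true = np.maximum(0.0,
                                 truth["gsref"] - truth["m"] * np.log(d))
            expected = gs_true * d / (factor * truth["hv"])
            assert np.allclose(f["Js_cm_per_h"].to_numpy(), expected,
                               rtol=1e-12)

    @pytest.mark.parametrize("gsref,m,d_star", [
        (0.20, 0.05, np.exp(3.0)),     # hump outside a 4.5 kPa ramp
        (0.24, 0.10, np.exp(1.4)),     # hump inside the ramp
    ])
    def test_noise_free_hump_location(self, gsref, m, d_star):
        """The flux curve (gsref - m lnD)*D peaks at exp(gsref/m - 1);
        cross-checked by numerical maximization."""
        opt = optimize.minimize_scalar(
            lambda d: -(gsref - m * np.log(d)) * d,
            bounds=(0.05, 50.0), method="bounded",
            options={"xatol": 1e-10})
        assert opt.x == pytest.approx(d_star, rel=1e-6)
        if d_star > 4.5:
            # monotone over the ramp: flux increases with D throughout
            d = np.linspace(0.1, 4.5, 200)
            js = (gsref - m * np.log(d)) * d
            assert np.all(np.diff(js) > 0)

    def test_rejects_bad_species(self):
        cfg = synthetic.default_config()
        with pytest.raises(KeyError):
            synthetic.generate_diurnal(cfg, "oak", 0)


class TestAnatomy:
    def test_noiseless_allometry_recovery(self, zero_noise_config):
        tables = synthetic.generate_anatomy(zero_noise_config, "almond")
        br = tables["branches"]
        model = traits.allometry_fit(br["diameter_mm"],
                                     br["leaf_area_cm2"])
        assert model.c0 == pytest.approx(1.5, abs=1e-9)
        assert model.c1 == pytest.approx(2.0, abs=1e-9)

    def test_branch_diameters_within_declared_range(self, noisy_campaign):
        br = noisy_campaign.anatomy["branches"]
        assert br["diameter_mm"].between(6.2, 20.0).all()

    def test_lognormal_vessel_mean_matches_moment_formula(self):
        cfg = synthetic.default_config(
            n_transects=10, transect_area_mm2=1.0, seed=13)
        rng = np.random.default_rng(13)
        draw = rng.lognormal(3.5, 0.3, 500)
        expected_mean = np.exp(3.5 + 0.3 ** 2 / 2)
        se = np.sqrt((np.exp(0.3 ** 2) - 1)
                     * np.exp(2 * 3.5 + 0.3 ** 2) / 500)
        assert abs(draw.mean() - expected_mean) < 3 * se
        # generated transects draw from the same family
        tables = synthetic.generate_anatomy(cfg, "almond")
        d = tables["vessels"]["diameter_um"]
        mu = cfg.species[0].vessel_mu
        assert np.exp(mu - 1) < d.mean() < np.exp(mu + 1)

    def test_single_vessel_transect_downstream_ks(self):
        t = traits.VesselTransect([42.0], 0.8)
        expected = (np.pi * units.WATER_DENSITY_20C
                    / (128 * units.WATER_VISCOSITY_20C * 0.8e-6)
                    * (42e-6) ** 4)
        assert traits.hagen_poiseuille_ks(t) == pytest.approx(expected,
                                                              rel=1e-12)


class TestWaterPotentials:
    def test_drawdown_arithmetic(self):
        cfg = synthetic.default_config()
        rec = synthetic.generate_water_potentials(cfg, "almond", 0,
                                                  0.2, 2.0)
        truth = synthetic.tree_truth(cfg, "almond", 0)
        assert rec["psi_pd_MPa"] - rec["psi_min_MPa"] == pytest.approx(
            0.2 * 2.0 / truth.kplant, rel=1e-12)

    def test_round_trip_recovers_kplant(self, zero_noise_campaign):
        camp = zero_noise_campaign
        for rec in camp.water_potentials.itertuples():
            est = traits.kplant(rec.gs_mol_m2_s, rec.D_kPa,
                                rec.psi_pd_MPa, rec.psi_min_MPa)
            assert est == pytest.approx(
                camp.truth["trees"][rec.tree_id]["kplant"], rel=1e-10)

    def test_large_kplant_limit_no_drawdown(self):
        cfg = synthetic.default_config()
        rec0 = synthetic.generate_water_potentials(cfg, "almond", 0,
                                                   0.0, 2.0)
        assert rec0["psi_min_MPa"] == pytest.approx(rec0["psi_pd_MPa"])

    def test_invariant_psi_ordering(self, noisy_campaign):
        wp = noisy_campaign.water_potentials
        assert (wp["psi_min_MPa"] <= wp["psi_pd_MPa"]).all()
        assert (wp["psi_pd_MPa"] <= 0).all()


class TestTreeTruth:
    def test_deterministic_and_species_anchored(self):
        cfg = synthetic.default_config(seed=3)
        t1 = synthetic.tree_truth(cfg, "olive", 2)
        t2 = synthetic.tree_truth(cfg, "olive", 2)
        assert t1 == t2
        sp = cfg.species[1]
        assert 0.5 * sp.hv < t1.hv < 2.0 * sp.hv

    def test_coordinated_factor_preserves_hump_location(self):
        cfg = synthetic.default_config(seed=3)
        t = synthetic.tree_truth(cfg, "olive", 1)
        sp = cfg.species[1]
        assert t.d_star == pytest.approx(sp.d_star, rel=1e-12)
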