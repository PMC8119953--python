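import numpy as np
import pandas as pd
import pytest

from cdomkit.synthetic import (
    CampaignConfig,
    COMPONENT_NAMES,
    GenerationError,
    IdentifiabilityError,
    KineticsSpec,
    default_kinetics,
    make_component_library,
    simulate_absorbance,
    simulate_campaign,
    simulate_eem,
    simulate_scores,
)


class TestComponentLibrary:
    def test_default_library_well_formed(self, small_library):
        assert len(small_library) == 6
        for comp in small_library:
            assert np.all(comp.excitation_loading >= 0)
            assert np.all(comp.emission_loading >= 0)
            assert np.isclose(np.linalg.norm(comp.excitation_loading), 1.0)
            assert np.isclose(np.linalg.norm(comp.emission_loading), 1.0)
            assert comp.peak_em > comp.peak_ex

    def test_pairwise_congruence_below_limit(self, small_library):
        for i in range(6):
            for j in range(i + 1, 6):
                a, b = small_library[i], small_library[j]
                cong = (
                    float(a.excitation_loading @ b.excitation_loading)
                    * float(a.emission_loading @ b.emission_loading)
                )
                assert cong < 0.9, (a.name, b.name)

    def test_protein_component_bluest_emission(self, small_library):
        by_name = {c.name: c for c in small_library}
        humic_em = [by_name[n].peak_em for n in ("C1", "C2", "C3", "C4")]
        assert by_name["C6"].peak_em < min(humic_em)

    def test_coarse_grid_raises_identifiability_error(self):
        with pytest.raises(IdentifiabilityError):
            make_component_library(np.arange(240.0, 651.0, 150.0),
                                   np.arange(300.0, 601.0, 120.0))


class TestKineticLaws:
    @pytest.mark.parametrize("spec", [
        KineticsSpec("single_exp_decay", {"k": 0.2}),
        KineticsSpec("double_exp_decay", {"f1": 0.6, "k1": 0.5, "k2": 0.05}),
        KineticsSpec("rise_then_fall", {"a": 1.5, "k_rise": 0.8, "k_fall": 0.05}),
        KineticsSpec("saturating_rise", {"a": 1.75, "k": 0.15}),
        KineticsSpec("constant"),
    ])
    def test_day_zero_identity(self, spec):
        assert spec.evaluate(0.0) == pytest.approx(1.0)

    def test_rise_then_fall_shape(self):
        spec = default_kinetics()["PB"]["C5"]
        m = spec.evaluate(np.array([0.0, 3.0, 24.0]))
        assert m[1] > m[0]
        assert m[2] < m[1]

    def test_saturating_rise_monotone_and_bounded(self):
        spec = default_kinetics()["PB"]["C6"]
        t = np.linspace(0, 60, 200)
        m = spec.evaluate(t)
        assert np.all(np.diff(m) > 0)
        assert np.all(m <= 1.0 + spec.params["a"] + 1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticsSpec("single_exp_decay", {"k": -0.1})


class TestSimulateScores:
    def test_pb_humics_strictly_decrease(self, tiny_campaign):
        truth = tiny_campaign.truth.true_scores
        for comp in ("C1", "C2", "C3", "C4"):
            vals = [truth.loc[f"S00_PB_T{d:02d}_R1", comp] for d in (0, 3, 24)]
            assert vals[0] > vals[1] > vals[2]

    def test_dark_changes_order_of_magnitude_smaller(self):
        cfg = CampaignConfig(
            n_stations=2, salinities=(0.1, 31.2),
            treatments=("PB", "MD3.0"),
            timepoints_days={"PB": (0, 24), "MD3.0": (0, 24)},
            replicates={"PB": 1, "MD3.0": 1}, seed=5,
        )
        kin = default_kinetics()
        scores = simulate_scores(cfg, kin)
        for comp in ("C1", "C2", "C3", "C4"):
            pb = scores.query("treatment=='PB' and component==@comp and station==0")
            md = scores.query("treatment=='MD3.0' and component==@comp and station==0")
            pb_change = abs(pb.iloc[1]["score"] / pb.iloc[0]["score"] - 1)
            md_change = abs(md.iloc[1]["score"] / md.iloc[0]["score"] - 1)
            assert md_change <= pb_change / 5.0

    def test_missing_kinetics_rejected(self):
        cfg = CampaignConfig(n_stations=1, salinities=(0.1,),
                             treatments=("PB",),
                             timepoints_days={"PB": (0, 24)},
                             replicates={"PB": 1})
        with pytest.raises(ValueError):
            simulate_scores(cfg, {"PB": {}})

    def test_bad_law_raises_generation_error(self):
        cfg = CampaignConfig(n_stations=1, salinities=(0.1,),
                             treatments=("PB",),
                             timepoints_days={"PB": (0, 24)},
                             replicates={"PB": 1})
        kin = default_kinetics()
        # a strongly rising "decay" violates the humic sign structure
        kin["PB"]["C1"] = KineticsSpec("saturating_rise", {"a": 2.0, "k": 0.5})
        with pytest.raises(GenerationError):
            simulate_scores(cfg, kin)


class TestSimulateAbsorbance:
    def test_precondition_rejects_zero_amplitude(self):
        with pytest.raises(ValueError):
            simulate_absorbance(0.018, 0.0)

    def test_slope_invariant_to_amplitude(self):
        from cdomkit.optics import S275_295, absorbance_to_absorption, fit_spectral_slope
        f1 = fit_spectral_slope(
            absorbance_to_absorption(simulate_absorbance(0.0175, 5.0)), S275_295)
        f2 = fit_spectral_slope(
            absorbance_to_absorption(simulate_absorbance(0.0175, 10.0)), S275_295)
        assert abs(f1.S - f2.S) < 1e-10


class TestSimulateEEM:
    def test_zero_noise_single_component_is_rank_one(self, small_library, small_grids):
        ex, em = small_grids
        scores = np.zeros(6)
        scores[0] = 2.5
        eem = simulate_eem(scores, small_library, ex, em,
                           noise_mult=0.0, noise_add=0.0)
        expected = 2.5 * np.outer(small_library[0].emission_loading,
                                  small_library[0].excitation_loading)
        np.testing.assert_allclose(eem.intensity, expected)

    def test_zero_scores_give_zero_eem(self, small_library, small_grids):
        ex, em = small_grids
        eem = simulate_eem(np.zeros(6), small_library, ex, em,
                           noise_mult=0.0, noise_add=0.0)
        np.testing.assert_array_equal(eem.intensity, 0.0)

    def test_fixed_seed_bit_identical(self, small_library, small_grids):
        ex, em = small_grids
        a = simulate_eem(np.ones(6), small_library, ex, em, seed=11)
        b = simulate_eem(np.ones(6), small_library, ex, em, seed=11)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestSimulateCampaign:
    def test_duplicate_pb_bottles(self, small_grids):
        ex, em = small_grids
        cfg = CampaignConfig(n_stations=2, salinities=(0.1, 13.9),
                             treatments=("PB",),
                             timepoints_days={"PB": (0, 3, 24)},
                             replicates={"PB": 2}, seed=3,
                             ex_grid=ex, em_grid=em)
        camp = simulate_campaign(cfg)
        manifest = camp.dataset.manifest
        per_cell = manifest.groupby(["station", "timepoint_days"]).size()
        assert (per_cell == 2).all()

    def test_seed_determinism_manifest_and_tensor(self, tiny_config_factory):
        a = simulate_campaign(tiny_config_factory())
        b = simulate_campaign(tiny_config_factory())
        ha = pd.util.hash_pandas_object(a.dataset.manifest).sum()
        hb = pd.util.hash_pandas_object(b.dataset.manifest).sum()
        assert ha == hb
        np.testing.assert_array_equal(a.dataset.tensor, b.dataset.tensor)
        assert a.doc.equals(b.doc)

    def test_day_zero_only_schedule(self, small_grids):
        ex, em = small_grids
        cfg = CampaignConfig(n_stations=2, salinities=(0.1, 31.2),
                             treatments=("PB",),
                             timepoints_days={"PB": (0,)},
                             replicates={"PB": 1}, seed=4,
                             ex_grid=ex, em_grid=em)
        camp = simulate_campaign(cfg)
        assert set(camp.dataset.manifest["timepoint_days"]) == {0}
        truth = camp.truth.true_scores
        assert len(truth) == 2

    def test_empty_treatments_rejected(self):
        with pytest.raises(ValueError):
            CampaignConfig(treatments=())

    def test_forward_inverse_consistency(self, noiseless_campaign):
        """With zero noise the masked tensor is exactly trilinear: truth
        scores times library loadings reproduce every observed cell."""
        camp = noiseless_campaign
        ds = camp.dataset
        lib = camp.truth.component_spectra
        B = np.stack([c.emission_loading for c in lib], axis=1)
        C = np.stack([c.excitation_loading for c in lib], axis=1)
        A = camp.truth.true_scores.loc[ds.sample_ids].to_numpy()
        recon = np.einsum("if,jf,kf->ijk", A, B, C)
        obs = np.broadcast_to(ds.mask, ds.tensor.shape)
        np.testing.assert_allclose(ds.tensor[obs], recon[obs], atol=1e-12)
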