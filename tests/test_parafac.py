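import numpy as np
import pandas as pd
import pytest

from cdomkit.parafac import (
    ParafacModel,
    core_consistency,
    detect_outliers,
    explained_variance,
    fit_parafac,
    match_components,
    select_n_components,
    split_half_validate,
    tucker_congruence,
)
from cdomkit.preprocess import EEMDataset


def _dense_dataset(tensor):
    n, j, k = tensor.shape
    return EEMDataset(
        tensor=tensor, mask=np.ones((j, k), bool),
        ex=np.arange(k, dtype=float), em=np.arange(j, dtype=float),
        manifest=pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]}),
    )


def _rank1_dataset(n=8, j=15, k=12, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.5, 2.0, n)
    b = np.exp(-0.5 * ((np.arange(j) - 7) / 3.0) ** 2)
    c = np.exp(-0.5 * ((np.arange(k) - 5) / 2.0) ** 2)
    X = np.einsum("i,j,k->ijk", a, b, c)
    return _dense_dataset(X), a, b / np.linalg.norm(b), c / np.linalg.norm(c)


class TestTuckerCongruence:
    def test_self_congruence(self):
        u = np.array([1.0, 2.0, 0.5])
        assert tucker_congruence(u, u) == pytest.approx(1.0)

    def test_orthogonal_supports(self):
        assert tucker_congruence(np.array([1.0, 0.0]),
                                 np.array([0.0, 1.0])) == 0.0

    def test_scale_invariance(self):
        u = np.array([0.2, 0.5, 0.1])
        assert tucker_congruence(u, 2.0 * u) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tucker_congruence(np.zeros(3), np.ones(3))


class TestFit:
    def test_noiseless_six_component_explains_everything(self, noiseless_campaign):
        ds = noiseless_campaign.dataset
        model = fit_parafac(ds, 6, n_starts=4, tol=1e-10, seed=2)
        assert model.explained_variance >= 100.0 - 1e-6

    def test_rank_one_recovery(self):
        ds, a, b, c = _rank1_dataset()
        model = fit_parafac(ds, 1, n_starts=3, seed=0)
        assert model.explained_variance >= 100.0 - 1e-8
        assert tucker_congruence(model.em_loadings[:, 0], b) >= 1.0 - 1e-8
        assert tucker_congruence(model.ex_loadings[:, 0], c) >= 1.0 - 1e-8

    def test_same_seed_identical_model(self, tiny_campaign):
        ds = tiny_campaign.dataset
        m1 = fit_parafac(ds, 3, n_starts=2, seed=5, max_iter=400)
        m2 = fit_parafac(ds, 3, n_starts=2, seed=5, max_iter=400)
        np.testing.assert_array_equal(m1.scores, m2.scores)
        np.testing.assert_array_equal(m1.em_loadings, m2.em_loadings)

    def test_different_seeds_agree_after_alignment(self, tiny_campaign):
        ds = tiny_campaign.dataset
        m1 = fit_parafac(ds, 6, n_starts=3, seed=5)
        m2 = fit_parafac(ds, 6, n_starts=3, seed=17)
        # ordering convention already aligns components
        for f in range(6):
            assert tucker_congruence(m1.em_loadings[:, f],
                                     m2.em_loadings[:, f]) >= 0.999
            assert tucker_congruence(m1.ex_loadings[:, f],
                                     m2.ex_loadings[:, f]) >= 0.999

    def test_loading_conventions_hold(self, tiny_campaign):
        model = fit_parafac(tiny_campaign.dataset, 6, n_starts=2, seed=1)
        assert np.all(model.scores >= 0)
        assert np.all(model.em_loadings >= 0)
        assert np.all(model.ex_loadings >= 0)
        np.testing.assert_allclose(
            np.linalg.norm(model.em_loadings, axis=0), 1.0, rtol=1e-9)
        np.testing.assert_allclose(
            np.linalg.norm(model.ex_loadings, axis=0), 1.0, rtol=1e-9)
        assert np.all(np.diff(model.em_peaks) <= 0)

    def test_too_few_samples_rejected(self, tiny_campaign):
        with pytest.raises(ValueError):
            fit_parafac(tiny_campaign.dataset, 7)

    def test_masked_cells_are_inert(self, tiny_campaign):
        ds = tiny_campaign.dataset
        ref = fit_parafac(ds, 2, n_starts=2, seed=9, max_iter=300)
        poisoned = ds.subset(np.arange(ds.n_samples))
        poisoned.tensor[:, ~ds.mask] = 1e6
        alt = fit_parafac(poisoned, 2, n_starts=2, seed=9, max_iter=300)
        np.testing.assert_array_equal(ref.scores, alt.scores)
        np.testing.assert_array_equal(ref.em_loadings, alt.em_loadings)
        np.testing.assert_array_equal(ref.ex_loadings, alt.ex_loadings)


class TestExplainedVariance:
    def test_perfect_reconstruction(self, noiseless_campaign):
        ds = noiseless_campaign.dataset
        model = fit_parafac(ds, 6, n_starts=3, tol=1e-10, seed=2)
        assert explained_variance(model, ds) == pytest.approx(100.0, abs=1e-6)

    def test_zero_model_explains_nothing(self, tiny_campaign):
        ds = tiny_campaign.dataset
        F = 2
        model = ParafacModel(
            n_components=F,
            scores=np.zeros((ds.n_samples, F)),
            em_loadings=np.zeros((ds.em.size, F)),
            ex_loadings=np.zeros((ds.ex.size, F)),
            em_grid=ds.em, ex_grid=ds.ex,
            explained_variance=0.0, rss=np.nan, n_iterations=0,
            converged=True, start_seed=0,
        )
        assert explained_variance(model, ds) == pytest.approx(0.0)

    def test_nested_models_never_lose_variance(self, tiny_campaign):
        ds = tiny_campaign.dataset
        evs = [fit_parafac(ds, F, n_starts=3, seed=4).explained_variance
               for F in (1, 2, 3)]
        assert evs[0] <= evs[1] + 1e-6
        assert evs[1] <= evs[2] + 1e-6


class TestSplitHalf:
    def test_duplicated_samples_validate_perfectly(self, tiny_campaign):
        ds = tiny_campaign.dataset
        idx = np.repeat(np.arange(ds.n_samples), 2)
        doubled = ds.subset(idx)
        report = split_half_validate(doubled, 3, n_starts=2, seed=1)
        assert report.validated
        assert report.min_congruence >= 0.98

    def test_too_small_dataset_rejected(self, tiny_campaign):
        with pytest.raises(ValueError):
            split_half_validate(tiny_campaign.dataset, 4)


class TestOutliers:
    def test_identical_samples_share_leverage(self):
        X = np.tile(np.random.default_rng(0).uniform(0, 1, (1, 10, 8)), (6, 1, 1))
        ds = _dense_dataset(X)
        model = fit_parafac(ds, 1, n_starts=2, seed=0, max_iter=200)
        report = detect_outliers(ds, model, leverage_cut=0.5)
        np.testing.assert_allclose(report.leverages, report.leverages[0])
        assert report.flagged == []

    def test_scaled_sample_flagged(self, tiny_campaign):
        ds = tiny_campaign.dataset
        boosted = ds.subset(np.arange(ds.n_samples))
        boosted.tensor[3] *= 100.0
        model = fit_parafac(boosted, 2, n_starts=2, seed=0, max_iter=300)
        report = detect_outliers(boosted, model, leverage_cut=0.5)
        assert np.argmax(report.leverages) == 3
        assert boosted.sample_ids[3] in report.flagged

    def test_leverage_sum_equals_component_count(self, tiny_campaign):
        ds = tiny_campaign.dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=0, max_iter=300)
        report = detect_outliers(ds, model)
        assert report.leverages.sum() == pytest.approx(3.0, abs=1e-6)


class TestMatching:
    def test_model_matches_its_own_library(self, tiny_campaign):
        camp = tiny_campaign
        model = fit_parafac(camp.dataset, 6, n_starts=3, seed=2)
        table = match_components(model, camp.truth.component_spectra,
                                 camp.dataset.em, camp.dataset.ex,
                                 threshold=0.95)
        assert set(table["model_component"]) == set(range(6))
        best = table.groupby("model_component")["match_score"].max()
        assert (best >= 0.95).all()

    def test_impossible_threshold_empty(self, tiny_campaign):
        camp = tiny_campaign
        model = fit_parafac(camp.dataset, 2, n_starts=2, seed=2, max_iter=300)
        table = match_components(model, camp.truth.component_spectra,
                                 camp.dataset.em, camp.dataset.ex,
                                 threshold=1.01)
        assert table.empty

    def test_empty_library_rejected(self, tiny_campaign):
        model = fit_parafac(tiny_campaign.dataset, 2, n_starts=2, seed=2,
                            max_iter=200)
        with pytest.raises(ValueError):
            match_components(model, [], np.arange(3.0), np.arange(3.0))


class TestDiagnostics:
    def test_core_consistency_high_at_true_rank(self, noiseless_campaign):
        ds = noiseless_campaign.dataset
        model = fit_parafac(ds, 6, n_starts=3, tol=1e-10, seed=2)
        assert core_consistency(model, ds) >= 90.0

    def test_select_single_candidate_rank_one(self):
        ds, *_ = _rank1_dataset(n=8)
        selected, diag = select_n_components(ds, [1], n_starts=2,
                                             split_starts=2, seed=0)
        assert selected == 1
        assert diag.loc[0, "validated"]

    def test_pure_noise_has_no_validated_model(self):
        rng = np.random.default_rng(8)
        ds = _dense_dataset(rng.uniform(0, 1, (16, 12, 10)))
        selected, diag = select_n_components(ds, [2], n_starts=2,
                                             split_starts=2, seed=0,
                                             max_iter=400)
        assert selected is None
        assert not diag["validated"].any()
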