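import numpy as np
import pytest

from cdomkit.optics import AbsorbanceSpectrum
from cdomkit.preprocess import (
    EEM,
    GridError,
    StateError,
    assemble_dataset,
    compute_raman_area,
    inner_filter_correct,
    mask_scatter,
    raman_emission,
    raman_normalize,
    subtract_blank,
)
from cdomkit.synthetic import apply_instrument_effects, make_blank_eem, simulate_absorbance

EX = np.arange(240.0, 461.0, 10.0)
EM = np.arange(300.0, 561.0, 5.0)


def _eem(value=1.0, state=(), rng=None):
    inten = np.full((EM.size, EX.size), float(value)) if rng is None \
        else rng.uniform(0.1, 1.0, (EM.size, EX.size))
    return EEM(EX.copy(), EM.copy(), inten, state=state)


def _flat_abs(absorbance, pathlength=0.05):
    grid = np.arange(220.0, 751.0, 1.0)
    return AbsorbanceSpectrum(grid, np.full(grid.size, absorbance), pathlength)


class TestBlankSubtraction:
    def test_blank_equals_sample_gives_zero(self):
        s = _eem(0.7)
        out = subtract_blank(s, _eem(0.7))
        np.testing.assert_array_equal(out.intensity, 0.0)
        assert out.state == ("blank_subtracted",)

    def test_zero_blank_is_identity(self):
        s = _eem(0.7)
        out = subtract_blank(s, _eem(0.0))
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_double_application_rejected(self):
        once = subtract_blank(_eem(1.0), _eem(0.1))
        with pytest.raises(StateError):
            subtract_blank(once, _eem(0.1))

    def test_grid_mismatch_rejected(self):
        other = EEM(EX[:-1], EM, np.ones((EM.size, EX.size - 1)))
        with pytest.raises(GridError):
            subtract_blank(_eem(), other)


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self):
        s = _eem(0.5, state=("blank_subtracted",))
        out = inner_filter_correct(s, _flat_abs(0.0))
        np.testing.assert_allclose(out.intensity, s.intensity)

    def test_known_multiplier(self):
        # A(ex)=A(em)=0.1 per cm -> factor 10^0.1
        s = _eem(1.0, state=("blank_subtracted",))
        out = inner_filter_correct(s, _flat_abs(0.1 * 0.05 * 100.0))
        np.testing.assert_allclose(out.intensity, 10.0 ** 0.1)

    def test_correction_never_decreases_intensity(self):
        rng = np.random.default_rng(0)
        s = _eem(rng=rng)
        s.state = ("blank_subtracted",)
        out = inner_filter_correct(s, _flat_abs(0.02))
        assert np.all(out.intensity >= s.intensity)

    def test_high_absorbance_flagged(self):
        s = _eem(1.0, state=("blank_subtracted",))
        with pytest.warns(UserWarning):
            out = inner_filter_correct(s, _flat_abs(0.8 * 0.05 * 100.0))
        assert out.meta["ife_unreliable"]

    def test_order_enforced(self):
        with pytest.raises(StateError):
            inner_filter_correct(_eem(1.0), _flat_abs(0.0))


class TestRamanArea:
    def test_constant_blank(self):
        # constant c over a 57-nm window integrates to 57c
        blank = _eem(0.3)
        ref = compute_raman_area(blank, ex_line=350.0, em_range=(371.0, 428.0))
        # window clipped to the 5-nm grid: 375..425 spans 50 nm
        assert ref.raman_area == pytest.approx(0.3 * 50.0)

    def test_zero_blank_rejected(self):
        with pytest.raises(ValueError):
            compute_raman_area(_eem(0.0))

    def test_gaussian_band_matches_analytic_integral(self):
        amp, sd = 2.0, 6.0
        blank = make_blank_eem(EX, EM, raman_amplitude=amp, raman_sd=sd)
        ref = compute_raman_area(blank, ex_line=350.0, em_range=(371.0, 428.0))
        analytic = amp * sd * np.sqrt(2 * np.pi)
        assert ref.raman_area == pytest.approx(analytic, rel=0.01)

    def test_missing_ex_line_rejected(self):
        with pytest.raises(GridError):
            compute_raman_area(_eem(1.0), ex_line=351.0)


class TestRamanNormalize:
    def test_unit_area_is_identity(self):
        s = _eem(0.4, state=("blank_subtracted", "ife_corrected"))
        out = raman_normalize(
            s, compute_raman_area(_eem(1.0 / 50.0)))
        np.testing.assert_allclose(out.intensity, s.intensity)
        assert out.state[-1] == "raman_normalized"

    def test_instrument_gain_cancels(self):
        """Two instruments with gains 1 and 3.7 yield identical R.U. EEMs."""
        rng = np.random.default_rng(3)
        true = EEM(EX, EM, rng.uniform(0, 1, (EM.size, EX.size)),
                   state=("blank_subtracted", "ife_corrected", "raman_normalized"))
        blank = make_blank_eem(EX, EM)
        abs_spec = simulate_absorbance(0.018, 5.0)
        results = []
        for gain in (1.0, 3.7):
            raw = apply_instrument_effects(true, blank, abs_spec, gain=gain)
            gained_blank = blank.copy()
            gained_blank.intensity = blank.intensity * gain
            step = subtract_blank(raw, gained_blank)
            step = inner_filter_correct(step, abs_spec)
            step = raman_normalize(step, compute_raman_area(gained_blank))
            results.append(step.intensity)
        np.testing.assert_allclose(results[0], results[1], rtol=1e-10)
        np.testing.assert_allclose(results[0], true.intensity, rtol=1e-9,
                                   atol=1e-12)


class TestScatterMask:
    def _processed(self, value=1.0):
        return _eem(value, state=("blank_subtracted", "ife_corrected",
                                  "raman_normalized"))

    def test_disabled_mask_is_identity(self):
        s = self._processed(0.9)
        out = mask_scatter(s, 0.0, 0.0, 0.0, 0.0, below_diagonal="keep")
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_spike_on_diagonal_masked(self):
        s = self._processed(0.1)
        j = np.where(EM == 350.0)[0][0]
        k = np.where(EX == 350.0)[0][0]
        s.intensity[j, k] = 99.0
        out = mask_scatter(s)
        assert np.isnan(out.intensity[j, k])

    def test_mask_fraction_matches_cell_count_oracle(self):
        out = mask_scatter(self._processed())
        em = EM[:, None]
        ex = EX[None, :]
        ram = raman_emission(EX)[None, :]
        bands = (
            (np.abs(em - ex) <= 10)
            | (np.abs(em - ram) <= 5)
            | (np.abs(em - 2 * ex) <= 10)
            | (np.abs(em - 2 * ram) <= 10)
            | ((em - ex) <= 5)
        )
        assert out.meta["mask_fraction"] == pytest.approx(bands.mean())
        assert np.isnan(out.intensity).sum() == bands.sum()

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            mask_scatter(self._processed(), rayleigh1_width=-1.0)


class TestAssemble:
    def _sample(self, i, state=("blank_subtracted", "ife_corrected",
                                "raman_normalized")):
        e = _eem(float(i + 1), state=state)
        e.meta["sample_id"] = f"s{i}"
        return e

    def test_tensor_first_dimension(self):
        ds = assemble_dataset([self._sample(i) for i in range(5)])
        assert ds.tensor.shape[0] == 5
        assert ds.sample_ids == [f"s{i}" for i in range(5)]

    def test_heterogeneous_state_names_step(self):
        good = self._sample(0)
        bad = self._sample(1, state=("blank_subtracted", "ife_corrected"))
        with pytest.raises(StateError, match="raman_normalized"):
            assemble_dataset([good, bad])

    def test_mask_shared_across_samples(self):
        samples = []
        for i in range(4):
            e = self._sample(i)
            samples.append(mask_scatter(e))
        ds = assemble_dataset(samples)
        assert ds.mask.shape == (EM.size, EX.size)
        assert ds.mask.any() and not ds.mask.all()
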