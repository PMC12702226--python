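"""Single-PLD CBF quantification: closed form, linearity, alpha rescaling."""

import numpy as np
import pytest

from asldyn.quantify import (
    AslAcquisition,
    QuantParams,
    cbf_scaling_factor,
    perfusion_difference,
    quantify_cbf,
    rescale_alpha,
)
from asldyn.volume import GridMismatchError, Volume


def _vol(data):
    return Volume(np.asarray(data, dtype=float))


def _acq(control_arrays, label_arrays, m0):
    return AslAcquisition(
        control_frames=tuple(_vol(c) for c in control_arrays),
        label_frames=tuple(_vol(l) for l in label_arrays),
        m0=_vol(m0),
    )


class TestPerfusionDifference:
    def test_identical_frames_give_zero(self):
        base = np.full((4, 4, 4), 100.0)
        acq = _acq([base, base], [base, base], base)
        assert np.all(perfusion_difference(acq).data == 0.0)

    def test_mean_of_pairwise_differences(self):
        m0 = np.full((3, 3, 3), 50.0)
        acq = _acq([m0, m0], [m0 - 4.0, m0 - 6.0], m0)
        np.testing.assert_allclose(perfusion_difference(acq).data, 5.0)

    def test_noise_averaging_scales_as_sqrt_2_over_n(self, rng):
        # SD(dM) = sigma * sqrt(2/8) for 8 pairs of independent frames
        sigma, n_pairs, n_rep = 3.0, 8, 4000
        m0 = np.zeros((1, 1, 1))
        vals = []
        for _ in range(n_rep):
            ctrl = [m0 + rng.normal(0, sigma, m0.shape) for _ in range(n_pairs)]
            lab = [m0 + rng.normal(0, sigma, m0.shape) for _ in range(n_pairs)]
            vals.append(perfusion_difference(_acq(ctrl, lab, m0)).data[0, 0, 0])
        expected = sigma * np.sqrt(2.0 / n_pairs)
        assert np.std(vals) == pytest.approx(expected, rel=0.06)

    def test_mismatched_frame_counts_rejected(self):
        m0 = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="equal"):
            _acq([m0, m0], [m0], m0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(GridMismatchError):
            AslAcquisition(
                control_frames=(_vol(np.ones((2, 2, 2))),),
                label_frames=(_vol(np.ones((2, 2, 3))),),
                m0=_vol(np.ones((2, 2, 2))),
            )


class TestQuantifyCbf:
    def test_zero_difference_gives_zero_cbf(self):
        m0 = _vol(np.full((4, 4, 4), 200.0))
        out = quantify_cbf(m0.with_data(np.zeros(m0.shape)), m0, QuantParams())
        assert np.all(out.values.data == 0.0)

    def test_closed_form_hand_value(self):
        # dM/M0 = 0.005, lambda=0.9, T1b=1350 ms, tau=1800 ms, PLD=2000 ms,
        # alpha=0.59: independent evaluation of
        # 6000*0.9*0.005*exp(2000/1350) / (2*0.59*1.35*(1-exp(-1800/1350)))
        params = QuantParams(alpha=0.59)
        m0 = _vol(np.full((2, 2, 2), 1000.0))
        dm = m0.with_data(np.full((2, 2, 2), 5.0))
        out = quantify_cbf(dm, m0, params)
        np.testing.assert_allclose(out.values.data, 101.25856144274469, rtol=1e-12)

    def test_inverse_proportionality_in_alpha(self):
        m0 = _vol(np.full((3, 3, 3), 500.0))
        dm = m0.with_data(np.full((3, 3, 3), 2.0))
        lo = quantify_cbf(dm, m0, QuantParams(alpha=0.425))
        hi = quantify_cbf(dm, m0, QuantParams(alpha=0.85))
        np.testing.assert_allclose(lo.values.data, 2.0 * hi.values.data, rtol=1e-14)

    def test_linearity_in_dm_and_inverse_in_m0(self, rng):
        m0 = _vol(np.full((4, 4, 4), 100.0) + rng.uniform(0, 50, (4, 4, 4)))
        dm = m0.with_data(rng.uniform(0, 1, (4, 4, 4)))
        params = QuantParams(alpha=0.59)
        base = quantify_cbf(dm, m0, params, m0_threshold_frac=0.0).values.data
        doubled = quantify_cbf(dm.with_data(2 * dm.data), m0, params, 0.0).values.data
        np.testing.assert_allclose(doubled, 2 * base, rtol=1e-12)
        half_m0 = quantify_cbf(dm, m0.with_data(2 * m0.data), params, 0.0).values.data
        np.testing.assert_allclose(half_m0, base / 2, rtol=1e-12)

    def test_t1b_change_matches_analytic_factor(self):
        m0 = _vol(np.full((2, 2, 2), 1000.0))
        dm = m0.with_data(np.full((2, 2, 2), 3.0))
        p1 = QuantParams(alpha=0.59, t1_blood=1350.0)
        p2 = QuantParams(alpha=0.59, t1_blood=1650.0)
        c1 = quantify_cbf(dm, m0, p1).values.data
        c2 = quantify_cbf(dm, m0, p2).values.data
        t1, t2, pld, tau = 1350.0, 1650.0, 2000.0, 1800.0
        factor = (
            np.exp(pld / t2 - pld / t1)
            * (t1 * (1 - np.exp(-tau / t1)))
            / (t2 * (1 - np.exp(-tau / t2)))
        )
        np.testing.assert_allclose(c2, c1 * factor, rtol=1e-12)

    def test_low_m0_voxels_invalidated(self):
        m0_data = np.full((4, 4, 4), 1000.0)
        m0_data[0, 0, 0] = 1.0  # background-like voxel
        m0 = _vol(m0_data)
        dm = m0.with_data(np.ones((4, 4, 4)))
        out = quantify_cbf(dm, m0, QuantParams())
        assert not out.mask_valid.data[0, 0, 0]
        assert out.values.data[0, 0, 0] == 0.0
        assert out.mask_valid.data[1, 1, 1]

    def test_all_zero_m0_rejected(self):
        m0 = _vol(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="M0"):
            quantify_cbf(m0.with_data(np.ones((3, 3, 3))), m0, QuantParams())

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            QuantParams(alpha=0.0)


class TestRescaleAlpha:
    @pytest.fixture()
    def fitted_map(self, rng):
        m0 = _vol(np.full((4, 4, 4), 800.0))
        dm = m0.with_data(rng.uniform(0, 4, (4, 4, 4)))
        return dm, m0

    def test_identity_at_same_alpha(self, fitted_map):
        dm, m0 = fitted_map
        cbf = quantify_cbf(dm, m0, QuantParams(alpha=0.85))
        same = rescale_alpha(cbf, 0.85)
        np.testing.assert_array_equal(same.values.data, cbf.values.data)

    def test_scalar_factor_085_to_059(self, fitted_map):
        dm, m0 = fitted_map
        cbf = quantify_cbf(dm, m0, QuantParams(alpha=0.85))
        rescaled = rescale_alpha(cbf, 0.59)
        np.testing.assert_allclose(
            rescaled.values.data, cbf.values.data * (0.85 / 0.59), rtol=1e-14
        )
        assert rescaled.params_used.alpha == 0.59

    def test_rescale_equals_direct_fit(self, fitted_map):
        dm, m0 = fitted_map
        via_rescale = rescale_alpha(quantify_cbf(dm, m0, QuantParams(alpha=0.85)), 0.59)
        direct = quantify_cbf(dm, m0, QuantParams(alpha=0.59))
        np.testing.assert_allclose(
            via_rescale.values.data, direct.values.data, rtol=1e-12
        )

    def test_round_trip_is_identity(self, fitted_map):
        dm, m0 = fitted_map
        cbf = quantify_cbf(dm, m0, QuantParams(alpha=0.85))
        back = rescale_alpha(rescale_alpha(cbf, 0.59), 0.85)
        np.testing.assert_allclose(back.values.data, cbf.values.data, atol=1e-12)

    def test_invalid_target_alpha_rejected(self, fitted_map):
        dm, m0 = fitted_map
        cbf = quantify_cbf(dm, m0, QuantParams(alpha=0.85))
        with pytest.raises(ValueError):
            rescale_alpha(cbf, 0.0)


def test_scaling_factor_value():
    # K such that CBF = K * dM/M0; hand value for the alpha=0.59 constants
    k = cbf_scaling_factor(QuantParams(alpha=0.59))
    assert k * 0.005 == pytest.approx(101.25856144274469, rel=1e-12)
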