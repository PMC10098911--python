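"""Depth-resolved scattering estimators: oracle equality, bias correction."""

import warnings

import numpy as np
import pytest

from dermoct.core import DermoctError, OCTVolume
from dermoct.scattering import (
    AScanSegment,
    fit_terminal_mu,
    lateral_smooth,
    modified_dr,
    naive_dr,
    volume_scattering,
)
from dermoct.segmentation import segment_layers

DELTA = 2.53e-3  # mm per axial pixel


def _exp_segment(mu=2.16, n=28, amp=10.0, delta=DELTA):
    I = amp * np.exp(-2.0 * mu * np.arange(n) * delta)
    return AScanSegment(I=I, delta=delta)


def _analytic_tails(mu, seg):
    """Exact tail integrals of C*exp(-2 mu z) from z_i to z_N."""
    n = seg.I.size
    z = np.arange(n) * seg.delta
    zN = z[-1]
    return seg.I * (1.0 - np.exp(-2.0 * mu * (zN - z))) / (2.0 * mu)


class TestLateralSmooth:
    def test_constant_volume_unchanged(self):
        vol = OCTVolume(intensity=np.full((8, 9, 9), 2.0), dz=2.53)
        assert np.allclose(lateral_smooth(vol).intensity, 2.0)

    def test_single_bright_voxel_spreads_to_25(self):
        data = np.zeros((3, 9, 9))
        data[1, 4, 4] = 25.0
        out = lateral_smooth(OCTVolume(intensity=data, dz=2.53)).intensity
        assert out[1, 4, 4] == pytest.approx(1.0)
        assert (out[1] > 0).sum() == 25
        assert np.allclose(out[1, 2:7, 2:7], 1.0)

    def test_mean_preserved_in_interior(self, rng):
        data = rng.random((4, 21, 21))
        vol = OCTVolume(intensity=data, dz=2.53)
        once = lateral_smooth(vol)
        twice = lateral_smooth(once)
        assert not np.allclose(once.intensity, twice.intensity)
        # interior away from truncated edges conserves the mean
        assert once.intensity[:, 6:15, 6:15].mean() == pytest.approx(
            data[:, 2:19, 2:19].mean(), abs=0.02
        )

    def test_window_larger_than_volume_raises(self):
        vol = OCTVolume(intensity=np.ones((4, 3, 3)), dz=2.53)
        with pytest.raises(Exception):
            lateral_smooth(vol, window=5)


class TestNaiveDR:
    def test_matches_brute_force_discrete_sum(self, rng):
        I = rng.random(40) + 0.1
        seg = AScanSegment(I=I, delta=DELTA)
        mu = naive_dr(seg)
        for i in range(39):
            tail = DELTA * sum(I[m] for m in range(i + 1, 40))
            assert mu[i] == pytest.approx(I[i] / (2 * tail), abs=1e-12)
        assert np.isnan(mu[-1])

    def test_recovers_mu_when_fully_attenuated(self):
        seg = _exp_segment(mu=2.16, n=2000)
        mu = naive_dr(seg)
        assert np.nanmax(np.abs(mu[:100] / 2.16 - 1)) < 0.01

    def test_truncated_tail_overestimates_at_depth(self):
        seg = _exp_segment(mu=2.16, n=28)
        mu = naive_dr(seg)
        deepest = mu[~np.isnan(mu)][-1]
        assert deepest > 1.2 * 2.16  # >20% overestimation

    def test_constant_signal_geometric_form(self):
        n = 30
        seg = AScanSegment(I=np.ones(n), delta=DELTA)
        mu = naive_dr(seg)
        for i in range(n - 1):
            assert mu[i] == pytest.approx(1.0 / (2 * DELTA * (n - 1 - i)))
        assert np.all(np.diff(mu[:-1]) > 0)  # grows as the tail shortens


class TestTerminalFit:
    @pytest.mark.parametrize("mu", [2.16, 1.78])
    def test_exact_exponential_recovered(self, mu):
        assert fit_terminal_mu(_exp_segment(mu=mu, n=28)) == pytest.approx(
            mu, abs=1e-6
        )

    def test_flat_signal_raises(self):
        with pytest.raises(DermoctError, match="no attenuation"):
            fit_terminal_mu(AScanSegment(I=np.ones(20), delta=DELTA))

    def test_too_few_samples_raises(self):
        with pytest.raises(DermoctError):
            fit_terminal_mu(AScanSegment(I=np.ones(4) * 2, delta=DELTA))


class TestModifiedDR:
    def test_exact_with_analytic_tail_integrals(self):
        """With exact tail integrals and an exact terminal coefficient the
        correction factor cancels the truncation term identically."""
        mu = 2.16
        seg = _exp_segment(mu=mu, n=28)
        est = modified_dr(seg, mu, tail_integrals=_analytic_tails(mu, seg))
        assert np.nanmax(np.abs(est / mu - 1)) <= 1e-6

    def test_discrete_sums_recover_within_two_percent(self):
        mu = 2.16
        seg = _exp_segment(mu=mu, n=28)
        est = modified_dr(seg, mu)
        assert np.nanmax(np.abs(est / mu - 1)) < 0.02

    def test_converges_to_naive_in_deep_tail_limit(self):
        seg = _exp_segment(mu=2.16, n=2000)
        est_m = modified_dr(seg, 2.16)
        est_n = naive_dr(seg)
        sel = slice(0, 1000)  # well above the terminal region
        rel = np.abs(est_m[sel] - est_n[sel]) / est_n[sel]
        assert np.nanmax(rel) < 0.005

    def test_terminal_misspecification_attenuates_toward_surface(self):
        """A +50% terminal error shrinks monotonically with distance from
        the terminal pixel.  At the small optical depth of a thin cell layer
        the correction factor is nearly linear in the accumulated tail, so
        the attenuation is partial — the error never amplifies, but it does
        not vanish either (which is why the terminal coefficient is fitted
        from pooled data rather than guessed)."""
        mu = 2.16
        seg = _exp_segment(mu=mu, n=28)
        est = modified_dr(seg, 1.5 * mu)
        err = np.abs(est[:-1] / mu - 1.0)
        assert np.all(np.diff(err) > 0)  # decays toward the surface
        assert err[0] < 0.5  # never exceeds the injected terminal error

    def test_bias_smaller_than_naive_in_deep_half(self):
        mu = 2.16
        seg = _exp_segment(mu=mu, n=28)
        est_m = modified_dr(seg, mu)
        est_n = naive_dr(seg)
        deep = slice(14, 27)
        assert np.all(np.abs(est_m[deep] - mu) < np.abs(est_n[deep] - mu))

    def test_outputs_positive_and_finite(self, rng):
        I = np.maximum(rng.random(30), 0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = modified_dr(AScanSegment(I=I, delta=DELTA), 2.0)
        assert np.all(np.isfinite(est))


class TestVolumeScattering:
    def test_noiseless_recovery_within_two_percent(self, flat_phantom):
        _, vol, _ = flat_phantom
        b = segment_layers(vol)
        smap = volume_scattering(vol, b)
        assert smap.mean_mu == pytest.approx(2.16, rel=0.02)
        assert np.all(smap.mu[np.isfinite(smap.mu)] > 0)

    def test_speckled_recovery_within_five_percent(self, speckled_phantom):
        _, vol, _ = speckled_phantom
        b = segment_layers(vol)
        smap = volume_scattering(vol, b)
        assert smap.mean_mu == pytest.approx(2.16, rel=0.05)

    def test_mu_defined_only_in_cell_layer(self, flat_phantom):
        _, vol, truth = flat_phantom
        b = segment_layers(vol)
        smap = volume_scattering(vol, b)
        defined = np.isfinite(smap.mu)
        zz = np.arange(vol.nz)[:, None, None]
        inside = (zz >= truth.cell_top_index) & (zz < truth.cell_bottom_index)
        assert np.all(inside[defined])

    def test_mean_invariant_to_lateral_permutation(self, flat_phantom):
        """Reordering A-scans permutes columns only; with lateral smoothing
        disabled (it mixes neighbours) the volume mean is unchanged."""
        _, vol, _ = flat_phantom
        b = segment_layers(vol)
        smap = volume_scattering(vol, b, smooth_window=1)
        perm = np.random.default_rng(0).permutation(vol.nx)
        vol_p = OCTVolume(
            intensity=vol.intensity[:, perm, :], dz=vol.dz, dx=vol.dx,
            dy=vol.dy, n_tissue=vol.n_tissue,
        )
        from dataclasses import replace

        b_p = replace(
            b,
            cuticle_top=b.cuticle_top[perm],
            cuticle_bottom=b.cuticle_bottom[perm],
            membrane_top=b.membrane_top[perm],
            valid_mask=b.valid_mask[perm],
            cuticle_top_subpix=b.cuticle_top_subpix[perm],
            cuticle_bottom_subpix=b.cuticle_bottom_subpix[perm],
            membrane_top_subpix=b.membrane_top_subpix[perm],
        )
        smap_p = volume_scattering(vol_p, b_p, smooth_window=1)
        assert smap_p.mean_mu == pytest.approx(smap.mean_mu, abs=1e-6)

    def test_per_ascan_terminal_mode_runs(self, flat_phantom):
        _, vol, _ = flat_phantom
        b = segment_layers(vol)
        smap = volume_scattering(vol, b, terminal="per_ascan")
        assert smap.mean_mu == pytest.approx(2.16, rel=0.02)
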