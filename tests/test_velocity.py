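"""Vector-field agreement metrics against brute-force oracles."""

import numpy as np
import pytest

from respgate.containers import VelocityField4D, VesselMask
from respgate.velocity import (
    detect_systolic_frames,
    mean_directional_error,
    mip_map,
    peak_velocity,
    pixelwise_magnitude_correlation,
    rmse_masked,
    velocity_magnitude,
)


def _field(components, venc=150.0):
    components = np.asarray(components, float)
    n_ph = components.shape[4]
    return VelocityField4D(
        components=components,
        voxel_mm=(2.5, 2.5, 2.5),
        venc=venc,
        phase_times=np.arange(n_ph) / n_ph,
    )


def _random_pair(rng, shape=(6, 5, 4), n_ph=3, scale=20.0):
    u = _field(rng.normal(scale=scale, size=(3, *shape, n_ph)))
    v = _field(rng.normal(scale=scale, size=(3, *shape, n_ph)))
    mask = VesselMask(rng.random(shape) > 0.4)
    if not mask.mask.any():
        mask.mask[0, 0, 0] = True
    return u, v, mask


class TestVelocityMagnitude:
    def test_pythagorean_triple(self):
        comps = np.zeros((3, 1, 1, 1, 1))
        comps[0] = 3.0
        comps[1] = 4.0
        assert velocity_magnitude(_field(comps))[0, 0, 0, 0] == 5.0

    def test_zero_field(self):
        assert np.all(velocity_magnitude(_field(np.zeros((3, 2, 2, 2, 2)))) == 0)

    def test_matches_voxel_loop(self):
        rng = np.random.default_rng(0)
        u, _, _ = _random_pair(rng)
        mag = velocity_magnitude(u)
        for idx in np.ndindex(*mag.shape):
            want = np.sqrt(sum(u.components[c][idx] ** 2 for c in range(3)))
            assert mag[idx] == pytest.approx(want, abs=1e-12)


class TestRmseMasked:
    def test_identical_fields_give_zero(self):
        rng = np.random.default_rng(1)
        u, _, mask = _random_pair(rng)
        assert rmse_masked(u, u, mask) == 0.0

    def test_constant_offset(self):
        rng = np.random.default_rng(2)
        u, _, mask = _random_pair(rng)
        comps = u.components.copy()
        comps[0][mask.mask] += 7.0
        v = _field(comps)
        assert rmse_masked(u, v, mask) == pytest.approx(7.0, abs=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        u, v, mask = _random_pair(rng)
        total = []
        for ph in range(u.n_phases):
            acc, cnt = 0.0, 0
            for idx in np.ndindex(*mask.mask.shape):
                if mask.mask[idx]:
                    acc += sum(
                        (u.components[c][idx + (ph,)] - v.components[c][idx + (ph,)]) ** 2
                        for c in range(3)
                    )
                    cnt += 1
            total.append((acc / cnt) ** 0.5)
        assert rmse_masked(u, v, mask) == pytest.approx(np.mean(total), abs=1e-10)

    def test_is_a_metric_on_random_triples(self):
        rng = np.random.default_rng(4)
        u, v, mask = _random_pair(rng)
        w, _, _ = _random_pair(rng)
        duv = rmse_masked(u, v, mask)
        assert duv == pytest.approx(rmse_masked(v, u, mask))
        assert duv <= rmse_masked(u, w, mask) + rmse_masked(w, v, mask) + 1e-12

    def test_shape_mismatch_and_empty_mask_rejected(self):
        rng = np.random.default_rng(5)
        u, v, mask = _random_pair(rng)
        with pytest.raises(ValueError):
            rmse_masked(u, v, VesselMask(np.zeros(mask.mask.shape, bool)))


class TestMeanDirectionalError:
    def test_positive_rescaling_gives_zero(self):
        rng = np.random.default_rng(6)
        u, _, mask = _random_pair(rng)
        v = _field(2.5 * u.components)
        assert mean_directional_error(u, v, mask, [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_gives_two(self):
        rng = np.random.default_rng(7)
        u, _, mask = _random_pair(rng)
        v = _field(-u.components)
        assert mean_directional_error(u, v, mask, [0]) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_fields_give_one_and_match_loop(self):
        shape = (4, 4, 3)
        cu = np.zeros((3, *shape, 2))
        cv = np.zeros((3, *shape, 2))
        cu[0] = 10.0
        cv[1] = 5.0
        u, v = _field(cu), _field(cv)
        mask = VesselMask(np.ones(shape, bool))
        got = mean_directional_error(u, v, mask, [0, 1])
        assert got == pytest.approx(1.0, abs=1e-12)

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(8)
        u, v, mask = _random_pair(rng)
        eps = 0.01 * u.venc
        frames = [0, 2]
        per_frame = []
        for ph in frames:
            vals = []
            for idx in np.ndindex(*mask.mask.shape):
                if not mask.mask[idx]:
                    continue
                a = np.array([u.components[c][idx + (ph,)] for c in range(3)])
                b = np.array([v.components[c][idx + (ph,)] for c in range(3)])
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na > eps and nb > eps:
                    vals.append(1.0 - a @ b / (na * nb))
            per_frame.append(np.mean(vals))
        got = mean_directional_error(u, v, mask, frames)
        assert got == pytest.approx(np.mean(per_frame), abs=1e-10)
        assert 0.0 <= got <= 2.0

    def test_norm_floor_yields_nan_with_warning(self):
        shape = (2, 2, 2)
        u = _field(np.full((3, *shape, 1), 0.01))
        v = _field(np.full((3, *shape, 1), 0.01))
        mask = VesselMask(np.ones(shape, bool))
        with pytest.warns(UserWarning, match="norm floor"):
            out = mean_directional_error(u, v, mask, [0], eps=1.0)
        assert np.isnan(out)


class TestSystolicFrames:
    def test_constant_field_selects_all_frames(self):
        comps = np.ones((3, 3, 3, 3, 5))
        f = _field(comps)
        mask = VesselMask(np.ones((3, 3, 3), bool))
        assert detect_systolic_frames(f, mask).tolist() == [0, 1, 2, 3, 4]

    def test_phantom_frames_follow_cardiac_waveform(self, phantom_pair):
        p, field_a, _, mask, truth = phantom_pair
        got = detect_systolic_frames(field_a, mask)
        want = np.nonzero(truth["h"] >= 0.5 * truth["h"].max())[0]
        assert got.tolist() == want.tolist()

    def test_threshold_one_selects_argmax_only(self, phantom_pair):
        p, field_a, _, mask, truth = phantom_pair
        got = detect_systolic_frames(field_a, mask, threshold_fraction=1.0)
        assert got.tolist() == [int(np.argmax(truth["h"]))]


class TestMipMap:
    def test_single_masked_voxel_per_column(self):
        rng = np.random.default_rng(9)
        velmag = rng.random((3, 3, 4))
        mask = np.zeros((3, 3, 4), bool)
        kz = rng.integers(0, 4, size=(3, 3))
        for i in range(3):
            for j in range(3):
                mask[i, j, kz[i, j]] = True
        mip, mask2d = mip_map(velmag, VesselMask(mask))
        assert mask2d.all()
        for i in range(3):
            for j in range(3):
                assert mip[i, j] == velmag[i, j, kz[i, j]]

    def test_uniform_masked_value(self):
        velmag = np.where(np.arange(4)[None, None, :] < 2, 9.0, 99.0)
        velmag = np.broadcast_to(velmag, (3, 3, 4)).copy()
        mask = np.zeros((3, 3, 4), bool)
        mask[:, :, :2] = True
        mip, mask2d = mip_map(velmag, VesselMask(mask))
        assert np.all(mip[mask2d] == 9.0)

    def test_matches_per_column_loop(self):
        rng = np.random.default_rng(10)
        velmag = rng.random((5, 6, 7))
        mask = rng.random((5, 6, 7)) > 0.5
        mask[0, 0, 0] = True
        mip, mask2d = mip_map(velmag, VesselMask(mask))
        for i in range(5):
            for j in range(6):
                vals = [velmag[i, j, k] for k in range(7) if mask[i, j, k]]
                if vals:
                    assert mask2d[i, j] and mip[i, j] == max(vals)
                else:
                    assert not mask2d[i, j] and np.isnan(mip[i, j])


def oracle_peak_velocity(mip, mask2d, kernel):
    best = (-np.inf, None)
    ny, nx = mip.shape
    for i in range(ny - kernel + 1):
        for j in range(nx - kernel + 1):
            sub_mask = mask2d[i : i + kernel, j : j + kernel]
            if not sub_mask.all():
                continue
            sub = mip[i : i + kernel, j : j + kernel]
            mean = sub.mean()
            if mean > best[0]:
                best = (mean, (i, j), sub.max())
    return best


class TestPeakVelocity:
    def test_uniform_disc_returns_value(self):
        mip = np.full((12, 12), 80.0)
        yy, xx = np.mgrid[:12, :12]
        mask = (yy - 5.5) ** 2 + (xx - 5.5) ** 2 <= 25
        res = peak_velocity(mip, mask, kernel=4)
        assert res.velpeak == 80.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            mip = rng.random((12, 12)) * 100
            mask = rng.random((12, 12)) > 0.3
            mask[2:8, 2:8] = True
            res = peak_velocity(mip, mask, kernel=4)
            mean, origin, vmax = oracle_peak_velocity(mip, mask, 4)
            assert res.kernel_mean == pytest.approx(mean, abs=1e-12)
            assert res.kernel_origin == origin
            assert res.velpeak == pytest.approx(vmax, abs=1e-12)
            assert res.velpeak >= res.kernel_mean

    def test_invariant_to_values_outside_mask(self):
        rng = np.random.default_rng(12)
        mip = rng.random((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[1:7, 2:8] = True
        res1 = peak_velocity(mip, mask, kernel=4)
        mip2 = mip.copy()
        mip2[~mask] = 1e6
        res2 = peak_velocity(mip2, mask, kernel=4)
        assert res1.velpeak == res2.velpeak and res1.kernel_origin == res2.kernel_origin

    def test_no_valid_placement_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[0, :] = True
        with pytest.raises(ValueError, match="smaller kernel"):
            peak_velocity(np.ones((8, 8)), mask, kernel=4)

    def test_phantom_peak_recovered(self, phantom_pair):
        p, field_a, _, mask, truth = phantom_pair
        peak_frame = int(np.argmax(truth["h"]))
        mip, mask2d = mip_map(velocity_magnitude(field_a)[..., peak_frame], mask)
        res = peak_velocity(mip, mask2d, kernel=4)
        # nearest voxel center can miss the exact centerline by half a voxel diagonal
        offset = p.voxel_mm * np.sqrt(2) / 2.0
        tol = truth["peak_velocity_cms"] * (offset / p.radius_mm) ** 2
        assert abs(res.velpeak - truth["peak_velocity_cms"]) <= tol + 1e-9


class TestPixelwiseCorrelation:
    def test_identical_fields(self):
        rng = np.random.default_rng(13)
        u, _, mask = _random_pair(rng)
        res = pixelwise_magnitude_correlation(u, u, mask)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_scaled_magnitude_gives_scaled_slope(self):
        rng = np.random.default_rng(14)
        u, _, mask = _random_pair(rng)
        v = _field(1.5 * u.components, venc=u.venc * 2)
        res = pixelwise_magnitude_correlation(u, v, mask)
        assert res.slope == pytest.approx(1.5)

    def test_matches_normal_equations(self, phantom_pair):
        _, field_a, field_b, mask, _ = phantom_pair
        res = pixelwise_magnitude_correlation(field_a, field_b, mask)
        x = velocity_magnitude(field_a)[mask.mask].ravel()
        y = velocity_magnitude(field_b)[mask.mask].ravel()
        xm = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        assert res.slope == pytest.approx(beta[0], abs=1e-10)
        assert res.intercept == pytest.approx(beta[1], abs=1e-10)


class TestPerturbationCalibration:
    def test_rmse_close_to_sigma_sqrt3(self, phantom_pair):
        _, field_a, field_b, mask, _ = phantom_pair
        got = rmse_masked(field_a, field_b, mask)
        assert got == pytest.approx(2.25 * np.sqrt(3.0), rel=0.05)
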