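"""MLEM, TV descent, level snapping and the POCS driver."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fewview_pocs import (
    Image2D,
    PocsConfig,
    ReconState,
    Sinogram,
    SnapRule,
    build_system_model,
    forward_project,
    make_geometry,
    mlem_reconstruct,
    mlem_update,
    pocs_reconstruct,
    snap_to_levels,
    tv_descent,
    tv_norm,
    tv_subgradient,
)
from fewview_pocs.projector import SystemModel


def toy_model(matrix, image_size, n_views=1, mask=None):
    """SystemModel around an explicit matrix, for scalar/toy MLEM checks."""
    matrix = np.asarray(matrix, dtype=float)
    n_bins = matrix.shape[0] // n_views
    geom = make_geometry(n_views, n_bins, image_size)
    if mask is None:
        mask = np.ones((image_size, image_size), dtype=bool)
    return SystemModel(geometry=geom, method="joseph",
                       matrix=sp.csr_matrix(matrix), support_mask=mask)


def smoothed_tv(x, eps):
    dx = np.zeros_like(x)
    dy = np.zeros_like(x)
    dx[:-1, :] = x[1:, :] - x[:-1, :]
    dy[:, :-1] = x[:, 1:] - x[:, :-1]
    return np.sum(np.sqrt(dx**2 + dy**2 + eps**2))


class TestMlem:
    def test_scalar_system_converges_in_one_step(self):
        model = toy_model([[1.0]], image_size=1)
        state = ReconState(Image2D(np.array([[1.0]]), model.geometry))
        sino = Sinogram(np.array([[2.0]]), model.geometry)
        out = mlem_update(state, sino, model)
        assert out.image.data[0, 0] == pytest.approx(2.0, abs=1e-15)

    def test_consistent_data_is_a_fixed_point(self, geom16, model16, rng):
        n = geom16.image_size
        x = np.where(model16.support_mask, rng.random((n, n)) + 0.5, 0.0)
        sino = forward_project(Image2D(x, geom16), model16)
        state = ReconState(Image2D(x.copy(), geom16))
        out = mlem_update(state, sino, model16)
        np.testing.assert_allclose(out.image.data, x, atol=1e-12)

    def test_poisson_log_likelihood_monotone_on_toy_system(self, rng):
        # 4x4 image, random positive system, inconsistent data
        a = rng.random((12, 16)) + 0.1
        model = toy_model(a, image_size=4, n_views=1)
        p = rng.random(12) * 5 + 0.5
        sino = Sinogram(p.reshape(1, 12), make_geometry(1, 12, 4))
        state = ReconState(Image2D(np.ones((4, 4)), model.geometry))
        ll = []
        for _ in range(20):
            q = a @ state.image.data.ravel()
            ll.append(np.sum(p * np.log(q) - q))
            state = mlem_update(state, sino, model)
        assert np.all(np.diff(ll) >= -1e-10)

    def test_flux_preserved_under_unit_sensitivity(self, rng):
        a = rng.random((16, 16)) + 0.05
        a /= a.sum(axis=0, keepdims=True)  # unit column sums
        model = toy_model(a, image_size=4)
        p = rng.random(16) + 0.2
        sino = Sinogram(p.reshape(1, 16), model.geometry)
        state = ReconState(Image2D(rng.random((4, 4)) + 0.5, model.geometry))
        out = mlem_update(state, sino, model)
        assert out.image.data.sum() == pytest.approx(p.sum(), rel=1e-12)

    def test_nonnegativity_and_mask_freeze(self, geom16, model16):
        n = geom16.image_size
        init = np.where(model16.support_mask, 1.0, 0.0)
        sino = Sinogram(np.abs(np.random.default_rng(0).random(
            (geom16.n_views, geom16.n_bins))) + 0.1, geom16)
        state = ReconState(Image2D(init, geom16))
        for _ in range(5):
            state = mlem_update(state, sino, model16)
        assert np.all(state.image.data >= 0)
        assert np.all(state.image.data[~model16.support_mask] == 0)

    def test_data_discrepancy_non_increasing(self, geom16, model16, rng):
        n = geom16.image_size
        x_true = np.where(model16.support_mask, rng.random((n, n)), 0.0)
        sino = forward_project(Image2D(x_true, geom16), model16)
        sino = Sinogram(np.maximum(sino.data, 1e-6), geom16)
        state = ReconState(Image2D(np.where(model16.support_mask, 1.0, 0.0), geom16))
        errs = []
        for _ in range(15):
            state = mlem_update(state, sino, model16)
            resid = forward_project(state.image, model16).data - sino.data
            errs.append(np.sqrt(np.mean(resid**2)))
        assert errs[-1] < errs[0]
        assert np.all(np.diff(errs) <= 1e-8)


class TestTvNorm:
    def test_constant_image_has_zero_tv(self):
        assert tv_norm(np.full((7, 7), 3.2)) == 0.0

    def test_two_by_two_enumeration(self):
        # terms: (0,0): 0; (0,1): |dx|=1; (1,0): |dy|=1; (1,1): 0
        assert tv_norm(np.array([[0.0, 0.0], [0.0, 1.0]])) == pytest.approx(2.0)

    @given(hnp.arrays(np.float64, (6, 6), elements=st.floats(-5, 5)),
           st.floats(-10, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance(self, img, c):
        assert tv_norm(img + c) == pytest.approx(tv_norm(img), abs=1e-9)


class TestTvSubgradient:
    def test_constant_image_gives_zero_field(self):
        g = tv_subgradient(np.full((5, 5), 1.7), epsilon=1e-8)
        np.testing.assert_array_equal(g, 0.0)

    def test_matches_finite_difference_gradient(self, rng):
        eps = 1e-3
        x = rng.random((8, 8))
        g = tv_subgradient(x, epsilon=eps)
        step = 1e-6
        for i, j in [(0, 0), (3, 4), (7, 7), (2, 0), (0, 5)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += step
            xm[i, j] -= step
            fd = (smoothed_tv(xp, eps) - smoothed_tv(xm, eps)) / (2 * step)
            assert g[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_transpose_equivariance(self, rng):
        x = rng.random((9, 9))
        g = tv_subgradient(x, epsilon=1e-8)
        gt = tv_subgradient(x.T, epsilon=1e-8)
        np.testing.assert_allclose(gt, g.T, atol=1e-12)


class TestTvDescent:
    def geom_image(self, data):
        n = data.shape[0]
        return Image2D(data, make_geometry(1, n, n))

    def test_zero_steps_is_identity(self, rng):
        img = self.geom_image(rng.random((8, 8)))
        out = tv_descent(img, eta=2e-7, steps=0)
        np.testing.assert_array_equal(out.data, img.data)

    def test_constant_image_unchanged(self):
        img = self.geom_image(np.full((8, 8), 0.5))
        out = tv_descent(img, eta=1e-3, steps=100)
        np.testing.assert_allclose(out.data, img.data, atol=1e-12)

    def test_tv_decreases_on_noisy_step_edge(self, rng):
        n = 32
        data = np.zeros((n, n))
        data[:, n // 2:] = 1.0
        data += 0.05 * rng.standard_normal((n, n))
        img = self.geom_image(data)
        before = tv_norm(img)
        out = tv_descent(img, eta=2e-7, steps=5000)
        assert tv_norm(out) < before

    def test_matches_explicit_subgradient_steps(self, rng):
        # the jitted kernel equals the plain numpy update sequence
        x = rng.random((8, 8))
        img = self.geom_image(x.copy())
        out = tv_descent(img, eta=1e-4, steps=3, epsilon=1e-8).data
        ref = x.copy()
        for _ in range(3):
            ref = ref - 1e-4 * tv_subgradient(ref, epsilon=1e-8)
        np.testing.assert_allclose(out, ref, atol=1e-13)


class TestSnapRule:
    @pytest.mark.parametrize("value,expected", [
        (0.6, 0.51), (1.0, 1.01), (1.4, 1.51), (0.2, 0.2), (0.0, 0.0),
        (0.25, 0.25), (0.75, 0.51), (1.25, 1.01), (5.0, 1.51),
    ])
    def test_reference_mapping(self, value, expected):
        geom = make_geometry(1, 1, 1)
        img = Image2D(np.array([[value]]), geom)
        out = snap_to_levels(img, SnapRule())
        assert out.data[0, 0] == expected

    def test_idempotent_and_nonexpansive(self, rng):
        geom = make_geometry(1, 16, 16)
        img = Image2D(rng.random((16, 16)) * 2.0, geom)
        rule = SnapRule()
        once = snap_to_levels(img, rule)
        twice = snap_to_levels(once, rule)
        np.testing.assert_array_equal(once.data, twice.data)
        moved = once.data != img.data
        # snapped pixels stay within their interval's reach of the original
        assert np.all(np.abs(once.data - img.data)[moved] <= 0.74)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            SnapRule(intervals=((0.25, 0.9, 0.51), (0.75, 1.25, 1.01)))

    def test_zero_level_rejected(self):
        with pytest.raises(ValueError):
            SnapRule(intervals=((0.25, 0.75, 0.0),))


class TestPocsDriver:
    def make_problem(self, rng, n=16):
        geom = make_geometry(4, 20, n)
        model = build_system_model(geom)
        x = np.where(model.support_mask, rng.random((n, n)) + 0.2, 0.0)
        sino = forward_project(Image2D(x, geom), model)
        return geom, model, sino

    def test_all_priors_disabled_equals_plain_mlem(self, rng):
        _, model, sino = self.make_problem(rng)
        cfg = PocsConfig(n_iterations=7, tv_steps=0, snap_rule=None)
        a = pocs_reconstruct(sino, model, cfg)
        b = mlem_reconstruct(sino, model, 7)
        np.testing.assert_array_equal(a.image.data, b.image.data)
        assert a.count == b.count == 7

    def test_snap_period_beyond_iterations_is_tv_method(self, rng):
        _, model, sino = self.make_problem(rng)
        tv_cfg = PocsConfig(n_iterations=5, tv_steps=20, tv_eta=1e-6,
                            snap_rule=None)
        pocs_cfg = PocsConfig(n_iterations=5, tv_steps=20, tv_eta=1e-6,
                              snap_period=1000, snap_rule=SnapRule())
        a = pocs_reconstruct(sino, model, tv_cfg)
        b = pocs_reconstruct(sino, model, pocs_cfg)
        np.testing.assert_array_equal(a.image.data, b.image.data)

    def test_terminating_on_a_snap_warns(self):
        with pytest.warns(UserWarning):
            PocsConfig(n_iterations=200, snap_period=100)

    def test_history_records_schedule(self, rng):
        _, model, sino = self.make_problem(rng)
        cfg = PocsConfig(n_iterations=7, tv_steps=5, tv_eta=1e-7,
                         snap_period=3, record_history=True)
        state = pocs_reconstruct(sino, model, cfg)
        assert len(state.history) == 7
        snapped = [h["snapped"] for h in state.history]
        assert snapped == [False, False, True, False, False, True, False]
        assert all(h["data_rmse"] >= 0 and h["tv"] >= 0 for h in state.history)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PocsConfig(n_iterations=0)
        with pytest.raises(ValueError):
            PocsConfig(tv_eta=-1.0)
        with pytest.raises(ValueError):
            PocsConfig(tv_steps=-1)
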