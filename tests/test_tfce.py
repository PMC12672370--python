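"""Mass-univariate GLM, TFCE enhancement and permutation FWE control."""

import numpy as np
import pytest

from cyclebrain.hormones import TEMPLATES, simulate_cycle, sqrt_transform
from cyclebrain.phantom import (
    SessionStack,
    make_lattice_geometry,
    make_phantom_mask,
)
from cyclebrain.tfce import (
    MasswiseGlmTfce,
    apply_absolute_threshold,
    fit_masswise_glm,
    permutation_fwe,
    tfce_enhance,
)


@pytest.fixture(scope="module")
def small_geom():
    return make_phantom_mask((10, 10, 10), 2.0)


@pytest.fixture(scope="module")
def typical_hormones():
    return simulate_cycle(TEMPLATES("typical", seed=5), np.arange(1, 26))


def _stack(geom, hormones, data):
    return SessionStack(hormones.individual_id, hormones.day, data, geom)


def _flood_fill_components(binary_vol, connectivity26=True):
    """Exhaustive BFS connected-component labeling (independent oracle)."""
    shape = binary_vol.shape
    labels = np.zeros(shape, dtype=int)
    current = 0
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and (connectivity26 or abs(i) + abs(j) + abs(k) == 1)
    ]
    for idx in np.argwhere(binary_vol):
        idx = tuple(idx)
        if labels[idx]:
            continue
        current += 1
        queue = [idx]
        labels[idx] = current
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and binary_vol[nx, ny, nz]
                    and not labels[nx, ny, nz]
                ):
                    labels[nx, ny, nz] = current
                    queue.append((nx, ny, nz))
    return labels, current


class TestTfceEnhance:
    def test_zero_map_stays_zero(self, small_geom):
        out = tfce_enhance(np.zeros(small_geom.n_locations), small_geom)
        assert np.all(out == 0)

    def test_plateau_closed_form(self):
        geom = make_phantom_mask((16, 16, 16), 2.0)
        mask_idx = np.argwhere(geom.mask)
        center = mask_idx.mean(axis=0).astype(int)
        plateau = np.all(np.abs(mask_idx - center) <= 1, axis=1)
        assert plateau.sum() == 27
        h0 = 2.0
        t = np.zeros(geom.n_locations)
        t[plateau] = h0
        out = tfce_enhance(t, geom, n_steps=100)
        expected = 27**0.5 * h0**3 / 3.0  # e^E * integral h^H dh
        rel = abs(out[plateau][0] - expected) / expected
        assert rel < 0.02

    def test_riemann_refinement_converges(self, small_geom, rng):
        from scipy.ndimage import gaussian_filter

        vol = gaussian_filter(rng.standard_normal(small_geom.shape), 1.5)
        t = np.abs(vol[small_geom.mask]) * 3.0
        coarse = tfce_enhance(t, small_geom, n_steps=100)
        fine = tfce_enhance(t, small_geom, n_steps=10_000)
        denom = np.abs(fine).max()
        assert np.abs(coarse - fine).max() / denom < 0.01

    def test_doubling_steps_changes_little(self, small_geom, rng):
        from scipy.ndimage import gaussian_filter

        vol = gaussian_filter(rng.standard_normal(small_geom.shape), 1.5)
        t = np.abs(vol[small_geom.mask]) * 3.0
        a = tfce_enhance(t, small_geom, n_steps=1000)
        b = tfce_enhance(t, small_geom, n_steps=2000)
        assert np.abs(a - b).max() / np.abs(b).max() < 0.01

    def test_single_threshold_equals_cluster_size_times_dh(self, rng):
        """H=0, E=1 single-step TFCE against the flood-fill oracle."""
        geom_shape = (6, 6, 6)
        full = make_phantom_mask((8, 8, 8), 1.0)
        for _ in range(5):
            binary = rng.random(geom_shape) > 0.6
            vol = np.zeros((8, 8, 8), dtype=bool)
            vol[1:7, 1:7, 1:7] = binary
            t = np.where(vol, 1.0, 0.0)[full.mask]
            out = tfce_enhance(t, full, E=1.0, H=0.0, n_steps=1)
            labels, _ = _flood_fill_components(vol & full.mask)
            sizes = np.bincount(labels.ravel())
            expected = np.where(
                labels[full.mask] > 0, sizes[labels[full.mask]] * 1.0, 0.0
            )
            np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_monotone_in_statistic_scale(self, small_geom, rng):
        t = np.abs(rng.standard_normal(small_geom.n_locations))
        a = tfce_enhance(t, small_geom, n_steps=50)
        b = tfce_enhance(1.5 * t, small_geom, n_steps=50)
        assert np.all(b >= a - 1e-12)

    def test_graph_connectivity_matches_grid_labeling(self, rng):
        """Lattice-graph extents agree with grid component sizes."""
        geom = make_lattice_geometry(8, 8)
        binary2d = rng.random((8, 8)) > 0.5
        t = binary2d.ravel().astype(float)
        out = tfce_enhance(t, geom, E=1.0, H=0.0, n_steps=1)
        from scipy.ndimage import label

        labels, _ = label(binary2d)  # 4-connectivity, matches lattice edges
        sizes = np.bincount(labels.ravel())
        expected = np.where(
            labels.ravel() > 0, sizes[labels.ravel()] * 1.0, 0.0
        )
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_invalid_steps_rejected(self, small_geom):
        with pytest.raises(ValueError):
            tfce_enhance(np.ones(small_geom.n_locations), small_geom, n_steps=0)


class TestAbsoluteThreshold:
    def test_boundary_inclusive_at_cutoff(self, small_geom, typical_hormones):
        V = small_geom.n_locations
        data = np.full((25, V), 0.5)
        data[:, 0] = 0.05   # excluded
        data[:, 1] = 0.10   # retained (>= rule)
        stack = _stack(small_geom, typical_hormones, data)
        keep = apply_absolute_threshold([stack], small_geom, cutoff=0.1)
        assert not keep[0]
        assert keep[1]
        assert keep[2:].all()

    def test_all_below_cutoff_rejected(self, small_geom, typical_hormones):
        data = np.full((25, small_geom.n_locations), 0.01)
        stack = _stack(small_geom, typical_hormones, data)
        with pytest.raises(ValueError):
            apply_absolute_threshold([stack], small_geom)


class TestMasswiseGlm:
    def test_planted_voxel_has_maximal_t(self, small_geom, typical_hormones, rng):
        V = small_geom.n_locations
        data = np.clip(0.4 + 0.02 * rng.standard_normal((25, V)), 0, None)
        z = sqrt_transform(typical_hormones.progesterone)
        z = (z - z.mean()) / z.std()
        data[:, 123] += 0.1 * z
        stack = _stack(small_geom, typical_hormones, data)
        t_map = fit_masswise_glm([stack], [typical_hormones],
                                 predictor="progesterone")
        assert np.argmax(np.abs(t_map)) == 123
        # per-voxel OLS oracle at the planted voxel
        from scipy.stats import linregress

        x = sqrt_transform(typical_hormones.progesterone)
        ref = linregress(x, data[:, 123])
        t_ref = ref.slope / ref.stderr
        assert t_map[123] == pytest.approx(t_ref, rel=1e-9)

    def test_orthogonalized_response_gives_zero_t(self, small_geom, typical_hormones, rng):
        V = small_geom.n_locations
        x = sqrt_transform(typical_hormones.progesterone)
        xc = x - x.mean()
        y = rng.standard_normal(25)
        y = y - y.mean()
        y -= (y @ xc) / (xc @ xc) * xc
        data = np.full((25, V), 0.4)
        data[:, 0] += 0.01 * y
        stack = _stack(small_geom, typical_hormones, data)
        t_map = fit_masswise_glm([stack], [typical_hormones],
                                 predictor="progesterone")
        assert abs(t_map[0]) < 1e-8

    def test_per_individual_scope_returns_map_per_id(self, study):
        t_maps = fit_masswise_glm(
            study["stacks"], study["hormones"], scope="per_individual",
            predictor="estradiol",
        )
        assert set(t_maps) == {s.individual_id for s in study["stacks"]}

    def test_constant_predictor_rejected(self, small_geom, typical_hormones):
        from cyclebrain.hormones import HormoneSeries, compute_ratio

        n = 25
        e = np.full(n, 200.0)
        p = np.full(n, 5.0)
        flat = HormoneSeries(
            "typical", typical_hormones.day, e, p, compute_ratio(p, e),
            np.array(["follicular"] * n, dtype=object),
        )
        data = np.full((n, small_geom.n_locations), 0.4)
        stack = _stack(small_geom, flat, data)
        with pytest.raises(ValueError):
            fit_masswise_glm([stack], [flat], predictor="progesterone")


class TestPermutationFwe:
    def test_deterministic_given_seed(self, small_geom, typical_hormones, rng):
        V = small_geom.n_locations
        data = np.clip(0.4 + 0.02 * rng.standard_normal((25, V)), 0, None)
        stack = _stack(small_geom, typical_hormones, data)
        kwargs = dict(predictor="progesterone", n_perm=120, seed=3, n_steps=20)
        a = permutation_fwe([stack], [typical_hormones], **kwargs)
        b = permutation_fwe([stack], [typical_hormones], **kwargs)
        np.testing.assert_array_equal(a.fwe_p_pos, b.fwe_p_pos)
        np.testing.assert_array_equal(a.null_max_neg, b.null_max_neg)

    def test_fwe_p_bounds_and_monotonicity(self, small_geom, typical_hormones, rng):
        V = small_geom.n_locations
        data = np.clip(0.4 + 0.02 * rng.standard_normal((25, V)), 0, None)
        stack = _stack(small_geom, typical_hormones, data)
        res = permutation_fwe(
            [stack], [typical_hormones], predictor="progesterone",
            n_perm=150, seed=1, n_steps=20,
        )
        assert np.all(res.fwe_p_pos >= 1.0 / 151)
        assert np.all(res.fwe_p_pos <= 1.0)
        order = np.argsort(res.tfce_pos)
        assert np.all(np.diff(res.fwe_p_pos[order]) <= 1e-12)

    def test_strongly_planted_voxel_significant(self, small_geom, typical_hormones, rng):
        V = small_geom.n_locations
        data = np.clip(0.4 + 0.01 * rng.standard_normal((25, V)), 0, None)
        z = sqrt_transform(typical_hormones.progesterone)
        z = (z - z.mean()) / z.std()
        data[:, 200] += 0.1 * z
        stack = _stack(small_geom, typical_hormones, data)
        res = permutation_fwe(
            [stack], [typical_hormones], predictor="progesterone",
            n_perm=200, seed=2, n_steps=50,
        )
        assert res.fwe_p_pos[200] < 0.01

    def test_too_few_permutations_rejected(self, small_geom, typical_hormones):
        data = np.full((25, small_geom.n_locations), 0.4)
        stack = _stack(small_geom, typical_hormones, data)
        with pytest.raises(ValueError):
            permutation_fwe([stack], [typical_hormones], n_perm=50)


class TestEstimator:
    def test_fit_applies_gm_threshold_and_exposes_maps(self, study):
        est = MasswiseGlmTfce(
            predictor="progesterone", n_perm=100, n_steps=20, seed=0
        ).fit(study["stacks"], study["hormones"])
        assert est.location_mask_.sum() == est.t_map_.size
        assert est.fwe_p_pos_.shape == est.t_map_.shape
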