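"""SVD decomposition: centering, identities, selection, thresholding."""

import numpy as np
import pytest

from cyclebrain.decomposition import (
    SpatioTemporalPattern,
    SpatioTemporalSVD,
    concatenate_and_center,
    select_components,
    standardize_temporal,
    svd_decompose,
    threshold_spatial,
)


def _cm(X, n_blocks=1, centering="per_individual"):
    rows = X.shape[0] // n_blocks
    stacks = [
        (f"ind{i}", X[i * rows : (i + 1) * rows]) for i in range(n_blocks)
    ]
    return concatenate_and_center(stacks, centering)


class TestConcatenateAndCenter:
    def test_per_individual_block_means_zero(self, rng):
        X = rng.standard_normal((6, 5)) + 3.0
        cm = _cm(X, n_blocks=2)
        assert cm.X.shape == (6, 5)
        for _, sl in cm.blocks:
            np.testing.assert_allclose(cm.X[sl].mean(axis=0), 0, atol=1e-10)

    def test_single_block_global_equals_per_individual(self, rng):
        X = rng.standard_normal((4, 7))
        a = _cm(X, centering="global").X
        b = _cm(X, centering="per_individual").X
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_geometry_mismatch_rejected(self, study):
        from dataclasses import replace

        from cyclebrain.phantom import make_phantom_mask

        stacks = study["stacks"]
        other_geom = make_phantom_mask((24, 24, 24), 3.0)
        bad = replace(stacks[1], geometry=other_geom)
        with pytest.raises(ValueError, match="geometry"):
            concatenate_and_center([stacks[0], bad])

    def test_duplicate_individual_rejected(self, rng):
        X = rng.standard_normal((3, 4))
        with pytest.raises(ValueError, match="duplicate"):
            concatenate_and_center([("a", X), ("a", X)])

    def test_column_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            concatenate_and_center(
                [("a", rng.standard_normal((3, 4))), ("b", rng.standard_normal((3, 5)))]
            )


class TestSvdDecompose:
    def test_rank_one_matrix(self):
        a = np.array([1.0, -2.0, 3.0, 0.5])
        s = np.array([3.0, 4.0, 0.0, 0.0, 12.0])
        X = np.outer(a, s / np.linalg.norm(s))
        cm = _cm(X, centering="global")
        patterns = svd_decompose(cm)
        assert patterns[0].variance_fraction == pytest.approx(1.0, abs=1e-10)
        cos = abs(patterns[0].spatial @ (s / np.linalg.norm(s)))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_two_component_fractions_match_loading_norms(self, rng):
        # orthogonal loadings with norm ratio 2:1 -> sigma^2 ratio 4:1
        n, v = 8, 20
        u1 = np.array([1, -1, 1, -1, 1, -1, 1, -1.0]) / np.sqrt(8)
        u2 = np.array([1, 1, -1, -1, 1, 1, -1, -1.0]) / np.sqrt(8)
        q, _ = np.linalg.qr(rng.standard_normal((v, 2)))
        X = 2.0 * np.outer(u1, q[:, 0]) + 1.0 * np.outer(u2, q[:, 1])
        from cyclebrain.decomposition import ConcatMatrix

        patterns = svd_decompose(
            ConcatMatrix(X=X, blocks=[("a", slice(0, n))], centering="global")
        )
        np.testing.assert_allclose(
            [p.variance_fraction for p in patterns[:2]], [0.8, 0.2], atol=1e-10
        )

    def test_sigma_squared_matches_gram_eigenvalues(self, rng):
        for _ in range(5):
            X = rng.standard_normal((20, 50))
            patterns = svd_decompose(
                _cm(X - X.mean(axis=0), centering="global")
            )
            sig2 = np.array([p.singular_value**2 for p in patterns])
            gram_eigs = np.sort(np.linalg.eigvalsh((X - X.mean(0)).T @ (X - X.mean(0))))[
                ::-1
            ][: sig2.size]
            np.testing.assert_allclose(sig2, np.clip(gram_eigs, 0, None), atol=1e-8)

    def test_fractions_sum_to_one_and_reconstruction(self, rng):
        X = rng.standard_normal((10, 30))
        cm = _cm(X, n_blocks=2)
        patterns = svd_decompose(cm)
        assert sum(p.variance_fraction for p in patterns) == pytest.approx(
            1.0, abs=1e-10
        )
        recon = sum(
            p.singular_value * np.outer(p.temporal, p.spatial) for p in patterns
        )
        rel = np.linalg.norm(recon - cm.X) / np.linalg.norm(cm.X)
        assert rel < 1e-8

    def test_orthonormality_and_sign_convention(self, rng):
        X = rng.standard_normal((8, 15))
        patterns = svd_decompose(_cm(X))
        V = np.stack([p.spatial for p in patterns])
        U = np.stack([p.temporal for p in patterns])
        np.testing.assert_allclose(V @ V.T, np.eye(len(patterns)), atol=1e-8)
        np.testing.assert_allclose(U @ U.T, np.eye(len(patterns)), atol=1e-8)
        for p in patterns:
            assert p.spatial[np.argmax(np.abs(p.spatial))] > 0

    def test_stack_order_permutation_leaves_spatial_patterns(self, rng):
        Xa, Xb = rng.standard_normal((5, 12)), rng.standard_normal((6, 12))
        p1 = svd_decompose(concatenate_and_center([("a", Xa), ("b", Xb)]))
        p2 = svd_decompose(concatenate_and_center([("b", Xb), ("a", Xa)]))
        for q1, q2 in zip(p1[:5], p2[:5]):
            cos = abs(q1.spatial @ q2.spatial)
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_non_finite_rejected(self):
        X = np.ones((3, 4))
        X[0, 0] = np.nan
        from cyclebrain.decomposition import ConcatMatrix

        with pytest.raises(ValueError):
            svd_decompose(ConcatMatrix(X, [("a", slice(0, 3))], "global"))


def _fake_patterns(fractions):
    out = []
    for i, f in enumerate(fractions):
        out.append(
            SpatioTemporalPattern(
                index=i + 1,
                spatial=np.eye(len(fractions))[i],
                temporal=np.eye(len(fractions))[i],
                singular_value=np.sqrt(f),
                variance_fraction=f,
                temporal_std=np.zeros(len(fractions)),
            )
        )
    return out


class TestSelectComponents:
    def test_ten_percent_rule_after_rounding(self):
        # the 9.7% component still counts as 10% after rounding
        kept = select_components(_fake_patterns([0.477, 0.204, 0.097, 0.04]))
        assert len(kept) == 3

    def test_dominant_component_only(self):
        assert len(select_components(_fake_patterns([0.95, 0.05]))) == 1

    def test_boundary_fraction_retained(self):
        kept = select_components(_fake_patterns([0.095, 0.905][::-1]))
        assert len(kept) == 2

    def test_top_component_always_retained_with_warning(self):
        patterns = _fake_patterns([0.94, 0.03, 0.03])
        with pytest.warns(UserWarning):
            kept = select_components(patterns, min_fraction=0.99)
        assert len(kept) == 1 and kept[0].index == 1


class TestThresholdSpatial:
    def test_subthreshold_zeroed_passthrough_and_clip(self):
        w = np.array([0.005, -0.05, 0.15, -0.3, 0.02])
        out = threshold_spatial(w)
        np.testing.assert_allclose(out, [0.0, -0.05, 0.10, -0.10, 0.02])

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            threshold_spatial(np.array([0.1]), low=0.2, high=0.1)


class TestStandardizeTemporal:
    def test_single_block_example(self):
        out = standardize_temporal(
            np.array([1.0, 2.0, 3.0]), [("a", slice(0, 3))]
        )
        np.testing.assert_allclose(out, [-1, 0, 1])

    def test_blocks_independent(self, rng):
        u = rng.standard_normal(9)
        blocks = [("a", slice(0, 4)), ("b", slice(4, 9))]
        out = standardize_temporal(u, blocks)
        for _, sl in blocks:
            assert abs(out[sl].mean()) < 1e-12
            assert out[sl].std(ddof=1) == pytest.approx(1.0)

    def test_constant_block_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_temporal(np.ones(4), [("a", slice(0, 4))])


class TestEstimatorInterface:
    def test_transform_projects_onto_retained_patterns(self, study):
        model = SpatioTemporalSVD().fit(study["stacks"])
        X = study["stacks"][0].data
        proj = model.transform(X)
        assert proj.shape == (X.shape[0], len(model.retained_))

    def test_get_params_round_trip(self):
        model = SpatioTemporalSVD(centering="global", min_fraction=0.2)
        params = model.get_params()
        assert params == {"centering": "global", "min_fraction": 0.2}
        clone = SpatioTemporalSVD(**params)
        assert clone.centering == "global"
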