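"""Landmark I/O, centroid size, GPA and allometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingclines import (
    LandmarkConfiguration,
    allometry_regression,
    centroid_size,
    compare_allometry_slopes,
    gpa,
    parse_tps,
    procrustes_distance,
    wireframe_delta,
    write_tps,
)
from wingclines.morphometrics import (
    AllometryModel,
    DegenerateConfigurationError,
    ProcrustesResult,
    TPSParseError,
)


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------


class TestTps:
    def test_basic_block(self, tmp_path):
        p = tmp_path / "t.tps"
        p.write_text("LM=3\n0 0\n1 0\n0 1\nID=s1\n")
        configs = parse_tps(p)
        assert len(configs) == 1
        assert configs[0].specimen_id == "s1"
        np.testing.assert_array_equal(configs[0].coords, [[0, 0], [1, 0], [0, 1]])

    def test_scale_applied(self, tmp_path):
        p = tmp_path / "t.tps"
        p.write_text("LM=1\n2 2\nSCALE=0.5\n")
        (cfg,) = parse_tps(p)
        np.testing.assert_allclose(cfg.coords, [[1.0, 1.0]])

    def test_roundtrip(self, tmp_path, small_landmarks):
        configs, _ = small_landmarks
        fw = [c for c in configs if c.wing == "forewing"][:5]
        p = tmp_path / "fw.tps"
        write_tps(fw, p)
        back = parse_tps(p)
        assert [c.specimen_id for c in back] == [c.specimen_id for c in fw]
        for a, b in zip(fw, back):
            np.testing.assert_allclose(a.coords, b.coords, atol=5e-7)

    @pytest.mark.parametrize(
        "text",
        [
            "LM=3\n0 0\n1 0\nID=s1\n",   # count mismatch
            "0 0\n1 0\n",                # missing LM line
            "LM=2\n0 0\nnot numbers\n",  # bad coordinate line
        ],
    )
    def test_malformed_rejected(self, tmp_path, text):
        p = tmp_path / "bad.tps"
        p.write_text(text)
        with pytest.raises((TPSParseError, ValueError)):
            parse_tps(p)


# ---------------------------------------------------------------------------
# Centroid size
# ---------------------------------------------------------------------------


class TestCentroidSize:
    def test_unit_square(self):
        cs = centroid_size(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert cs == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_right_triangle(self):
        # centroid (1, 4/3); summed squared distances 50/3
        cs = centroid_size(np.array([[0, 0], [3, 0], [0, 4]], float))
        assert cs == pytest.approx(np.sqrt(50.0 / 3.0), abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(c=st.floats(min_value=-50, max_value=50).filter(lambda v: abs(v) > 1e-6))
    def test_homogeneity(self, c):
        coords = np.array([[0.0, 0.0], [2.0, 1.0], [1.0, 3.0], [-1.0, 0.5]])
        assert centroid_size(c * coords) == pytest.approx(
            abs(c) * centroid_size(coords), rel=1e-12
        )

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.ones((5, 2)))


# ---------------------------------------------------------------------------
# GPA and Procrustes distance
# ---------------------------------------------------------------------------


def _similarity(coords, rng):
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    scale = rng.uniform(0.3, 3.0)
    shift = rng.uniform(-10, 10, size=2)
    return coords @ rot.T * scale + shift


class TestGpa:
    def test_similarity_invariance(self, rng):
        base = np.array(
            [[0, 0], [2, 0.3], [3, 1.5], [2.2, 2.8], [0.6, 2.4], [-0.5, 1.2]], float
        )
        copies = np.stack([_similarity(base, rng) for _ in range(8)])
        res = gpa(copies)
        assert res.converged
        flat = res.flat()
        for i in range(8):
            for j in range(i + 1, 8):
                assert np.linalg.norm(flat[i] - flat[j]) < 1e-8

    def test_rotation_matches_closed_form(self, rng):
        # Independent oracle: with landmarks as complex numbers the
        # optimal rotation is e^{i theta}, theta = arg(sum conj(zb) za).
        a = rng.normal(size=(3, 2))
        b = rng.normal(size=(3, 2))

        def unit_complex(x):
            c = x - x.mean(0)
            c = c / np.sqrt((c**2).sum())
            return c[:, 0] + 1j * c[:, 1]

        za, zb = unit_complex(a), unit_complex(b)
        theta = np.angle(np.sum(np.conj(zb) * za))
        expected = np.sqrt(np.sum(np.abs(zb * np.exp(1j * theta) - za) ** 2))
        assert procrustes_distance(a, b) == pytest.approx(expected, abs=1e-10)

    def test_consensus_is_mean_of_aligned(self, small_landmarks):
        configs, _ = small_landmarks
        res = gpa([c for c in configs if c.wing == "hindwing"])
        mean_aligned = res.aligned.mean(axis=0)
        np.testing.assert_allclose(mean_aligned, res.consensus, atol=1e-6)

    def test_centred_output(self, small_landmarks):
        configs, _ = small_landmarks
        res = gpa([c for c in configs if c.wing == "forewing"])
        np.testing.assert_allclose(res.consensus.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(res.centroid_sizes > 0)

    def test_mixed_wings_rejected(self, small_landmarks):
        configs, _ = small_landmarks
        with pytest.raises(ValueError, match="mixed wing"):
            gpa(configs[:4])

    def test_mirrored_side_comparable(self, small_landmarks):
        configs, _ = small_landmarks
        left = next(c for c in configs if c.wing == "forewing")
        right = LandmarkConfiguration(
            specimen_id="r",
            wing="forewing",
            coords=left.coords * np.array([-1.0, 1.0]),
            side="right",
        )
        # A reflected wing is not similar under rotation alone ...
        assert procrustes_distance(left.coords, right.coords) > 0.05
        # ... but explicit mirroring restores comparability, and gpa
        # applies it automatically for side == "right".
        assert procrustes_distance(left.coords, right.mirrored().coords) < 1e-12
        res = gpa([left, right])
        assert np.linalg.norm(res.flat()[0] - res.flat()[1]) < 1e-8


class TestProcrustesDistance:
    def test_identity_and_rotation_zero(self, rng):
        a = rng.normal(size=(5, 2))
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert procrustes_distance(a, _similarity(a, rng)) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_grid_search_oracle(self):
        a = np.array([[0, 0], [1, 0], [0, 1]], float)
        b = np.array([[0, 0], [2, 0.5], [0.2, 1.4]], float)

        def unit(x):
            c = x - x.mean(0)
            return c / np.sqrt((c**2).sum())

        ua, ub = unit(a), unit(b)
        thetas = np.linspace(0, 2 * np.pi, 200001)
        best = min(
            np.sqrt(
                (
                    (
                        ub
                        @ np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]]).T
                        - ua
                    )
                    ** 2
                ).sum()
            )
            for t in thetas
        )
        assert procrustes_distance(a, b) == pytest.approx(best, abs=1e-6)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            procrustes_distance(np.zeros((3, 2)), np.zeros((4, 2)))


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------


def _noiseless_proc(n=30, k=6, seed=5):
    rng = np.random.default_rng(seed)
    consensus = rng.normal(size=(k, 2))
    consensus -= consensus.mean(0)
    consensus /= np.sqrt((consensus**2).sum())
    v = rng.normal(size=2 * k)
    v /= np.linalg.norm(v)
    log_cs = rng.uniform(0.5, 1.5, size=n)
    aligned = consensus.reshape(-1) + np.outer(log_cs, v) * 0.1
    return ProcrustesResult(
        aligned=aligned.reshape(n, k, 2),
        consensus=consensus,
        centroid_sizes=np.exp(log_cs),
        log_cs=log_cs,
        iterations=1,
        converged=True,
    )


class TestAllometry:
    def test_noiseless_construction_explains_all_variance(self):
        model = allometry_regression(_noiseless_proc(), n_perm=49, seed=0)
        assert model.pct_variance_explained == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(model.residual_shapes, 0.0, atol=1e-10)

    def test_residual_shapes_centred(self, small_landmarks):
        configs, _ = small_landmarks
        proc = gpa([c for c in configs if c.wing == "forewing"])
        model = allometry_regression(proc, n_perm=49, seed=1)
        np.testing.assert_allclose(
            model.residual_shapes.mean(axis=0), 0.0, atol=1e-10
        )
        assert 0.0 <= model.pct_variance_explained <= 100.0

    def test_constant_size_rejected(self):
        proc = _noiseless_proc()
        proc.log_cs[:] = 1.0
        with pytest.raises(ValueError, match="constant"):
            allometry_regression(proc, n_perm=9, seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            allometry_regression(_noiseless_proc(), n_perm=9)


def _score_model(slope, n, rng, se_target=0.14):
    x = rng.normal(0.95, 0.1, size=n)
    sigma = se_target * 0.1 * np.sqrt(n)
    scores = slope * (x - x.mean()) + rng.normal(0, sigma, size=n)
    return AllometryModel(
        coefficients=np.zeros(4),
        intercept=np.zeros(4),
        pct_variance_explained=0.0,
        permutation_p=1.0,
        regression_scores=scores,
        residual_shapes=np.zeros((n, 4)),
        slope=slope,
        slope_se=se_target,
        log_cs=x,
        n_perm=0,
        seed=0,
    )


class TestCompareSlopes:
    def test_identical_datasets(self):
        rng = np.random.default_rng(2)
        m = _score_model(1.5, 100, rng)
        f, p = compare_allometry_slopes(m, m)
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_distinct_slopes_detected(self):
        # Slopes and SEs at the scale observed for fore- vs hindwing
        # allometry (1.31 vs 2.25, SE 0.14) are separable at n=600.
        rng = np.random.default_rng(3)
        a = _score_model(1.31, 600, rng)
        b = _score_model(2.25, 600, rng)
        f, p = compare_allometry_slopes(a, b)
        assert p < 0.001

    def test_equal_slopes_rarely_flagged(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            a = _score_model(1.5, 150, rng)
            b = _score_model(1.5, 150, rng)
            _, p = compare_allometry_slopes(a, b)
            hits += p >= 0.05
        assert hits >= 0.9 * n_rep


class TestWireframe:
    def test_zero_value_returns_consensus(self):
        cons = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        d = np.full(6, 0.1)
        np.testing.assert_array_equal(wireframe_delta(cons, d, 0.0), cons)

    def test_linear_symmetric_displacement(self):
        cons = np.zeros((3, 2))
        d = np.arange(6.0)
        plus = wireframe_delta(cons, d, 0.5)
        minus = wireframe_delta(cons, d, -0.5)
        np.testing.assert_allclose(plus, -minus)
        assert np.linalg.norm(wireframe_delta(cons, d, 2.0)) == pytest.approx(
            2.0 * np.linalg.norm(d)
        )
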