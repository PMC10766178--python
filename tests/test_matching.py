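"""Feature matrices, correspondence, and the core-anchored similarity score."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

import lfpmatch as lm
from lfpmatch.config import Config
from lfpmatch.errors import (
    DegenerateGeometryError,
    LfpError,
    NoFeaturesError,
    NoOverlapError,
)
from lfpmatch.matching import extract_features, match_minutiae
from lfpmatch.ridges import CorePoint, Minutia, MinutiaSet


def mset(points, core=(0.0, 0.0), types=None, shape=(256, 256)):
    items = tuple(
        Minutia(float(x), float(y), (types or ["termination"] * len(points))[i])
        for i, (x, y) in enumerate(points)
    )
    cp = CorePoint(a=core[0], b=core[1]) if core is not None else None
    return MinutiaSet(items, core=cp, image_shape=shape)


class TestBuildFeatureMatrix:
    def test_m_equals_point_count(self):
        Z = lm.build_feature_matrix(mset([(10, 0), (0, 10), (20, 20), (5, 30), (30, 5)]))
        assert Z.m == 5 and Z.coords.shape == (5, 2)

    def test_pore_only_set_rejected(self):
        ms = mset([(10, 0), (0, 10)], types=["pore", "pore"])
        with pytest.raises(NoFeaturesError):
            lm.build_feature_matrix(ms)

    def test_canonical_ordering_is_permutation_invariant(self):
        pts = [(10, 3), (4, 17), (25, 25), (7, 30)]
        a = lm.build_feature_matrix(mset(pts))
        b = lm.build_feature_matrix(mset(list(reversed(pts))))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_all_points_inside_r_min_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            lm.build_feature_matrix(mset([(1, 0), (0, 2)]), r_min=3.0)

    def test_centroid_fallback_flagged_when_no_core(self):
        ms = mset([(10, 0), (0, 10), (30, 30)], core=None)
        Z = lm.build_feature_matrix(ms)
        assert Z.core_is_fallback


class TestCorrespondence:
    def test_identity_on_equal_matrices(self):
        Z = lm.build_feature_matrix(mset([(10, 0), (0, 20), (15, 15)]))
        corr = lm.establish_correspondence(Z, Z)
        assert corr.pairs == tuple((i, i) for i in range(Z.m))
        assert corr.unpaired_sample == () and corr.unpaired_control == ()

    def test_distant_extra_control_point_stays_unpaired(self):
        Z = lm.build_feature_matrix(mset([(10, 0), (0, 20)]))
        X = lm.build_feature_matrix(mset([(10, 0), (0, 20), (200, 200)]))
        corr = lm.establish_correspondence(Z, X)
        assert len(corr.pairs) == 2
        assert len(corr.unpaired_control) == 1

    def test_no_overlap_raises(self):
        Z = lm.build_feature_matrix(mset([(10, 0)]))
        X = lm.build_feature_matrix(mset([(200, 200)]))
        with pytest.raises(NoOverlapError):
            lm.establish_correspondence(Z, X, tol_r=5, tol_phi=0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_jittered_points_match_optimal_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        r = rng.uniform(20, 100, n)
        phi = rng.uniform(-np.pi, np.pi, n)
        control = np.column_stack([r * np.cos(phi), r * np.sin(phi)]) + 128
        sample = control + rng.uniform(-2, 2, (n, 2))
        core = CorePoint(a=128.0, b=128.0)
        Z = lm.FeatureMatrix(sample, core=core)
        X = lm.FeatureMatrix(control, core=core)
        corr = lm.establish_correspondence(Z, X, tol_r=5, tol_phi=0.3)
        assert len(corr.pairs) == n
        # oracle: optimal assignment on the same polar-distance cost
        rz, pz = Z.polar()
        rx, px = X.polar()
        dr = rz[:, None] - rx[None, :]
        dphi = np.angle(np.exp(1j * (pz[:, None] - px[None, :])))
        cost = np.hypot(dr, 0.5 * (rz[:, None] + rx[None, :]) * dphi)
        ri, ci = linear_sum_assignment(cost)
        assert set(corr.pairs) == set(zip(ri.tolist(), ci.tolist()))


class TestSimilarityScore:
    def test_self_match_is_exactly_one(self):
        Z = lm.build_feature_matrix(mset([(10, 0), (0, 20), (15, 15), (30, 5)]))
        res = lm.similarity_score(Z, Z, lm.Correspondence.identity(Z.m))
        assert res.P == 1.0
        assert res.percent == 100.0

    def test_hand_computed_example(self):
        # core (0,0); control points (1,0),(0,2); sample points (2,0),(0,2):
        # rho = (4, 1) -> terms (0.25, 1) -> P = 0.625
        core = CorePoint(a=0.0, b=0.0)
        Z = lm.FeatureMatrix(np.array([[2.0, 0.0], [0.0, 2.0]]), core=core)
        X = lm.FeatureMatrix(np.array([[1.0, 0.0], [0.0, 2.0]]), core=core)
        res = lm.similarity_score(Z, X, lm.Correspondence(((0, 0), (1, 1))), )
        assert res.per_point_terms == (0.25, 1.0)
        assert res.P == pytest.approx(0.625)

    def test_rotation_about_core_leaves_score_unchanged(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, (8, 2))
        core = CorePoint(a=0.0, b=0.0)
        X = lm.FeatureMatrix(pts + 100, core=CorePoint(a=100.0, b=100.0))
        base = lm.similarity_score(
            lm.FeatureMatrix(pts, core=core), X, lm.Correspondence.identity(8)
        ).P
        for ang in (0.3, 1.2, np.pi):
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            rot = pts @ R.T
            P = lm.similarity_score(
                lm.FeatureMatrix(rot, core=core), X, lm.Correspondence.identity(8)
            ).P
            assert abs(P - base) < 1e-12

    def test_translation_of_sample_with_its_core_leaves_score_unchanged(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-40, 40, (6, 2))
        X = lm.FeatureMatrix(pts + 200, core=CorePoint(a=200.0, b=200.0))
        base = lm.similarity_score(
            lm.FeatureMatrix(pts, core=CorePoint(a=0.0, b=0.0)),
            X,
            lm.Correspondence.identity(6),
        ).P
        shifted = lm.FeatureMatrix(pts + (33.5, -12.25), core=CorePoint(a=33.5, b=-12.25))
        P = lm.similarity_score(shifted, X, lm.Correspondence.identity(6)).P
        assert abs(P - base) < 1e-12

    @pytest.mark.parametrize("s", [1.0, math.sqrt(2), 2.0])
    def test_radial_scaling_matches_closed_form(self, s):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-50, 50, (10, 2))
        core = CorePoint(a=0.0, b=0.0)
        X = lm.FeatureMatrix(pts, core=core)
        Z = lm.FeatureMatrix(pts * s, core=core)
        P = lm.similarity_score(Z, X, lm.Correspondence.identity(10)).P
        assert P == pytest.approx(1.0 / (abs(s**2 - 1.0) + 1.0), rel=1e-12)

    def test_terms_bounded_and_P_is_their_mean(self):
        rng = np.random.default_rng(3)
        core = CorePoint(a=0.0, b=0.0)
        Z = lm.FeatureMatrix(rng.uniform(-60, 60, (12, 2)), core=core)
        X = lm.FeatureMatrix(rng.uniform(-60, 60, (12, 2)), core=core)
        res = lm.similarity_score(Z, X, lm.Correspondence.identity(12))
        assert all(0 < t <= 1 for t in res.per_point_terms)
        assert res.P == pytest.approx(np.mean(res.per_point_terms), abs=1e-15)
        assert 0 < res.P <= 1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 15))
def test_score_algebra_properties(seed, n):
    """0 < P <= 1, P is the exact mean of the terms, self-match is exact."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(5, 80, (n, 2)) * rng.choice([-1, 1], (n, 2))
    core = CorePoint(a=0.0, b=0.0)
    Z = lm.FeatureMatrix(pts, core=core)
    X = lm.FeatureMatrix(rng.uniform(5, 80, (n, 2)), core=core)
    res = lm.similarity_score(Z, X, lm.Correspondence.identity(n))
    assert 0 < res.P <= 1
    assert res.P == pytest.approx(float(np.mean(res.per_point_terms)), abs=1e-15)
    assert lm.similarity_score(Z, Z, lm.Correspondence.identity(n)).P == 1.0


class TestCompareImages:
    def test_identical_image_scores_one(self, synth_pair):
        cfg = dataclasses.replace(Config(), sample_modality="inked_control")
        res = lm.compare_images(synth_pair.control, synth_pair.control, cfg)
        assert res.P == 1.0
        assert res.correspondence.unpaired_sample == ()

    def test_genuine_pairs_outscore_impostors(self):
        genuine, impostor = [], []
        feats = []
        for seed in range(8):
            pair = lm.generate_pair(lm.SynthParams(seed=seed))
            ms_c, _ = extract_features(pair.control, "inked_control")
            ms_s, _ = extract_features(pair.sample, "fluorescent_sample")
            feats.append((ms_s, ms_c))

        def score(s, c):
            try:
                return match_minutiae(s, c).P
            except LfpError:
                return 0.0

        for i in range(8):
            genuine.append(score(feats[i][0], feats[i][1]))
            impostor.append(score(feats[i][0], feats[(i + 1) % 8][1]))
        assert np.mean(genuine) > np.mean(impostor)

    def test_unreadable_file_error_names_path(self, tmp_path):
        from lfpmatch.reportio import read_image

        bad = tmp_path / "missing.png"
        with pytest.raises(LfpError, match="missing.png"):
            read_image(bad)
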