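"""Reliability, similarity, homogeneity, robustness and permutation tests."""

import numpy as np
import pandas as pd
import pytest

from dcorconn import dcor_core as dc
from dcorconn import evaluation as ev
from dcorconn.parcellation import Parcellation


def _stack_from_values(values_by_key, roi_ids=None):
    """Build a SubjectSessionStack from raw R x R arrays."""
    stack = ev.SubjectSessionStack()
    for (p, s, m), vals in values_by_key.items():
        mat = dc.ConnectivityMatrix(vals, measure=m, roi_ids=roi_ids or ())
        stack.add(p, s, m, mat)
    return stack


def _random_symmetric(rng, R):
    a = rng.standard_normal((R, R))
    a = (a + a.T) / 2
    np.fill_diagonal(a, np.nan)
    return a


class TestICC:
    def test_perfect_agreement(self, rng):
        u = rng.standard_normal(20)
        assert ev.icc(u, u.copy()) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        assert abs(ev.icc(rng.standard_normal(10000), rng.standard_normal(10000))) < 0.05

    @pytest.mark.parametrize("form, row", [("icc1", 0), ("icc2", 1), ("icc3", 2)])
    def test_matches_anova_oracle(self, form, row):
        """Six-pair worked table agrees with pingouin's ANOVA decomposition.

        Rows 0-2 of pingouin's table are the single-measure forms
        ICC(1,1), ICC(A,1) and ICC(C,1).
        """
        pingouin = pytest.importorskip("pingouin")
        u = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        w = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        df = pd.DataFrame({
            "target": list(range(6)) * 2,
            "rater": [1] * 6 + [2] * 6,
            "score": np.concatenate([u, w]),
        })
        table = pingouin.intraclass_corr(df, targets="target", raters="rater",
                                         ratings="score")
        expected = float(table["ICC"].iloc[row])
        assert ev.icc(u, w, form) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ev.icc(np.ones(5), np.ones(5))


class TestReliabilityWithin:
    def test_duplicated_sessions_give_unit_icc(self, rng):
        R = 5
        vals = {}
        for p in range(4):
            m = _random_symmetric(rng, R)
            vals[(p, 1, "pcor")] = m
            vals[(p, 2, "pcor")] = m.copy()
        stack = _stack_from_values(vals)
        s = ev.reliability_within(stack, "pcor")
        assert np.allclose(s.values, 1.0)
        regional = ev.reliability_within(stack, "pcor", regional=True)
        assert regional.shape == (4, R)
        assert np.allclose(regional.values, 1.0)

    def test_shuffled_second_session_breaks_reliability(self, rng):
        R = 40
        vals = {}
        for p in range(6):
            m1 = _random_symmetric(rng, R)
            m2 = _random_symmetric(rng, R)
            vals[(p, 1, "pcor")], vals[(p, 2, "pcor")] = m1, m2
        s = ev.reliability_within(_stack_from_values(vals), "pcor")
        assert abs(s.mean()) < 0.15

    def test_missing_session_raises(self, rng):
        stack = _stack_from_values({(0, 1, "pcor"): _random_symmetric(rng, 4)})
        with pytest.raises(KeyError, match="missing"):
            ev.reliability_within(stack, "pcor")


class TestPerConnectionICC:
    def test_duplicated_sessions(self, rng):
        R = 4
        vals = {}
        for p in range(5):
            m = _random_symmetric(rng, R)
            vals[(p, 1, "pcor")], vals[(p, 2, "pcor")] = m, m.copy()
        out = ev.per_connection_icc(_stack_from_values(vals), "pcor")
        i, j = np.tril_indices(R, k=-1)
        assert np.allclose(out[i, j], 1.0)
        assert np.allclose(out, out.T, equal_nan=True)

    def test_degenerate_connection_flagged(self, rng):
        R = 3
        vals = {}
        for p in range(4):
            m = _random_symmetric(rng, R)
            m[1, 0] = m[0, 1] = 0.5  # identical across participants and sessions
            vals[(p, 1, "pcor")], vals[(p, 2, "pcor")] = m, m.copy()
        with pytest.warns(RuntimeWarning, match="zero variance"):
            out = ev.per_connection_icc(_stack_from_values(vals), "pcor")
        assert np.isnan(out[1, 0])

    def test_planted_reliability_ordering(self):
        """A connection with stable participant differences out-ranks pure noise."""
        rng = np.random.default_rng(17)
        R, P = 3, 30
        vals = {}
        trait = 2.0 * rng.standard_normal(P)
        for p in range(P):
            for s in (1, 2):
                m = np.full((R, R), np.nan)
                m[1, 0] = m[0, 1] = trait[p] + 0.2 * rng.standard_normal()
                m[2, 0] = m[0, 2] = rng.standard_normal()
                m[2, 1] = m[1, 2] = rng.standard_normal()
                vals[(p, s, "pcor")] = m
        out = ev.per_connection_icc(_stack_from_values(vals), "pcor")
        assert out[1, 0] > max(out[2, 0], out[2, 1])


class TestBetweenParticipantSimilarity:
    def test_identical_participants(self, rng):
        R = 5
        m = _random_symmetric(rng, R)
        vals = {(p, 1, "pcor"): m.copy() for p in range(4)}
        s = ev.between_participant_similarity(_stack_from_values(vals), "pcor")
        assert np.allclose(s.values, 1.0)

    def test_permuted_participant_is_least_similar(self, rng):
        R = 12
        base = _random_symmetric(rng, R)
        vals = {}
        for p in range(5):
            m = base + 0.1 * _random_symmetric(rng, R)
            vals[(p, 1, "pcor")] = m
        i, j = np.tril_indices(R, k=-1)
        odd = base.copy()
        perm = rng.permutation(i.size)
        odd[i, j] = base[i, j][perm]
        odd[j, i] = odd[i, j]
        vals[(5, 1, "pcor")] = odd
        s = ev.between_participant_similarity(_stack_from_values(vals), "pcor")
        assert s.idxmin() == 5

    def test_attenuation_matches_variance_ratio(self):
        """Shared + idiosyncratic model: similarity ~ 1/sqrt(1 + sigma^2)."""
        rng = np.random.default_rng(23)
        R, P, sigma = 30, 60, 0.8
        shared = _random_symmetric(rng, R)
        vals = {}
        for p in range(P):
            vals[(p, 1, "pcor")] = shared + sigma * _random_symmetric(rng, R)
        s = ev.between_participant_similarity(_stack_from_values(vals), "pcor",
                                              leave_one_out=True)
        i, j = np.tril_indices(R, k=-1)
        var_t = shared[i, j].var()
        # idiosyncratic part has variance sigma^2 * var of the symmetrised noise
        var_e = sigma**2 * 0.5
        expected = 1.0 / np.sqrt(1.0 + var_e / var_t)
        assert s.mean() == pytest.approx(expected, abs=0.05)

    def test_needs_three_participants(self, rng):
        vals = {(p, 1, "pcor"): _random_symmetric(rng, 4) for p in range(2)}
        with pytest.raises(ValueError, match="3 participants"):
            ev.between_participant_similarity(_stack_from_values(vals), "pcor")


class TestHomogeneity:
    def test_single_shared_pattern_is_100(self, rng):
        pattern = rng.standard_normal(9)
        conn = np.tile(pattern, (6, 1)) * rng.uniform(0.5, 2.0, size=(6, 1))
        assert ev.roi_homogeneity(conn) == pytest.approx(100.0)

    def test_two_orthogonal_patterns_split_evenly(self):
        """Equal-variance orthogonal halves -> first PC explains exactly 50%."""
        p1 = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 1.0, 1.0, -1.0, -1.0])
        conn = np.vstack([np.tile(p1, (4, 1)), np.tile(p2, (4, 1))])
        assert ev.roi_homogeneity(conn) == pytest.approx(50.0, abs=1e-9)

    def test_row_mean_invariance(self, rng):
        conn = rng.standard_normal((8, 10))
        shifted = conn.copy()
        shifted[3] += 17.0
        assert ev.roi_homogeneity(shifted) == pytest.approx(ev.roi_homogeneity(conn))

    def test_profile_on_homogeneous_blocks(self, rng):
        ts = rng.standard_normal((100, 4))
        blocks = {r: np.tile(ts[:, r][:, None], (1, 5)) + 0.05 * rng.standard_normal((100, 5))
                  for r in range(4)}
        prof = ev.homogeneity_profile(blocks)
        assert np.all(prof.values > 90.0)


class TestCrossParcellation:
    def _grid_parcellations(self):
        labels_a = np.zeros((8, 4, 1), dtype=np.int32)
        labels_b = np.zeros((8, 4, 1), dtype=np.int32)
        for k in range(4):  # A: 4 ROIs of 8 voxels; B: each split in two
            labels_a[2 * k : 2 * k + 2, :, 0] = k + 1
            labels_b[2 * k, :, 0] = 2 * k + 1
            labels_b[2 * k + 1, :, 0] = 2 * k + 2
        return Parcellation(labels_a), Parcellation(labels_b)

    def test_identical_parcellations_give_one(self, rng):
        pA, _ = self._grid_parcellations()
        m = dc.ConnectivityMatrix(_random_symmetric(rng, 4), "pcor", roi_ids=(1, 2, 3, 4))
        assert ev.cross_parcellation_robustness(m, pA, m, pA) == pytest.approx(1.0)

    def test_nested_parcellation_inherits_structure(self, rng):
        pA, pB = self._grid_parcellations()
        mA_vals = _random_symmetric(rng, 4)
        mA = dc.ConnectivityMatrix(mA_vals, "pcor", roi_ids=(1, 2, 3, 4))
        # B inherits the parent pair values exactly
        vals_b = np.full((8, 8), np.nan)
        for i in range(8):
            for j in range(8):
                if i // 2 != j // 2:
                    vals_b[i, j] = mA_vals[i // 2, j // 2]
                elif i != j:
                    vals_b[i, j] = 0.123
        mB = dc.ConnectivityMatrix(vals_b, "pcor", roi_ids=tuple(range(1, 9)))
        nested = ev.cross_parcellation_robustness(mA, pA, mB, pB)
        assert nested == pytest.approx(1.0)
        # scrambling B destroys the correspondence
        i, j = np.tril_indices(8, k=-1)
        scr = vals_b.copy()
        perm = rng.permutation(i.size)
        scr[i, j] = vals_b[i, j][perm]
        scr[j, i] = scr[i, j]
        scrambled = ev.cross_parcellation_robustness(
            mA, pA, dc.ConnectivityMatrix(scr, "pcor", roi_ids=tuple(range(1, 9))), pB
        )
        assert scrambled < nested - 0.3

    def test_grid_mismatch(self, rng):
        pA, _ = self._grid_parcellations()
        pC = Parcellation(np.ones((2, 2, 2), dtype=np.int32))
        m = dc.ConnectivityMatrix(_random_symmetric(rng, 4), "pcor", roi_ids=(1, 2, 3, 4))
        with pytest.raises(ValueError, match="grids"):
            ev.cross_parcellation_robustness(m, pA, m, pC)


class TestSwapPermutationTest:
    def test_identical_measures_give_p_one(self, rng):
        v1, v2 = rng.standard_normal((2, 50))
        p, obs = ev.swap_permutation_test(v1, v1, v2, v2, n_perm=200, seed=0)
        assert obs == 0.0
        assert p == 1.0

    def test_seed_determinism(self, rng):
        a, b, c, d = rng.standard_normal((4, 80))
        out1 = ev.swap_permutation_test(a, b, c, d, n_perm=300, seed=5)
        out2 = ev.swap_permutation_test(a, b, c, d, n_perm=300, seed=5)
        assert out1 == out2

    def test_planted_reliability_gap_detected(self):
        rng = np.random.default_rng(31)
        L = 1000
        t = rng.standard_normal(L)
        d1, d2 = t + 0.5 * rng.standard_normal((2, L))   # reliable measure
        p1, p2 = t + 2.5 * rng.standard_normal((2, L))   # noisy measure
        p, obs = ev.swap_permutation_test(p1, d1, p2, d2, n_perm=500, seed=1)
        assert obs > 0
        assert p < 0.05

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            ev.swap_permutation_test(np.ones(5), np.ones(5), np.ones(5), np.ones(4))


class TestMotionAssociation:
    def _centroids(self, R, rng):
        return {r: rng.uniform(0, 100, size=3) for r in range(R)}

    def test_independent_motion_near_zero(self, rng):
        R, P = 10, 40
        vals = {(p, 1, "pcor"): _random_symmetric(rng, R) for p in range(P)}
        stack = _stack_from_values(vals)
        motion = {p: float(rng.uniform(0.1, 1.0)) for p in range(P)}
        mean_corr, _ = ev.motion_association(stack, motion, self._centroids(R, rng), "pcor")
        assert abs(mean_corr) < 0.1

    def test_planted_short_distance_artefact(self):
        """Motion inflating nearby connections yields negative distance dependence."""
        rng = np.random.default_rng(41)
        R, P = 12, 50
        centroids = {r: rng.uniform(0, 120, size=3) for r in range(R)}
        cent = np.stack([centroids[r] for r in range(R)])
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=2)
        gain = np.exp(-d / 40.0)
        motion = rng.uniform(0.0, 1.0, size=P)
        vals = {}
        for p in range(P):
            m = gain * motion[p] + 0.1 * _random_symmetric(rng, R)
            np.fill_diagonal(m, np.nan)
            vals[(p, 1, "pcor")] = m
        stack = _stack_from_values(vals)
        mean_corr, dist_dep = ev.motion_association(
            stack, dict(enumerate(motion)), centroids, "pcor")
        assert mean_corr > 0.3
        assert dist_dep < 0

    def test_motion_scale_invariance(self, rng):
        R, P = 6, 20
        vals = {(p, 1, "pcor"): _random_symmetric(rng, R) for p in range(P)}
        stack = _stack_from_values(vals)
        cent = self._centroids(R, rng)
        motion = {p: float(rng.uniform(0.1, 1.0)) for p in range(P)}
        doubled = {p: 2 * v for p, v in motion.items()}
        assert ev.motion_association(stack, motion, cent, "pcor") == pytest.approx(
            ev.motion_association(stack, doubled, cent, "pcor")
        )

    def test_constant_motion_raises(self, rng):
        vals = {(p, 1, "pcor"): _random_symmetric(rng, 4) for p in range(5)}
        stack = _stack_from_values(vals)
        with pytest.raises(ValueError, match="constant motion"):
            ev.motion_association(stack, {p: 1.0 for p in range(5)},
                                  self._centroids(4, rng), "pcor")


class TestStructureFunction:
    def test_self_similarity(self, rng):
        m = dc.ConnectivityMatrix(np.abs(_random_symmetric(rng, 6)), "mvdcor")
        assert ev.structure_function_similarity(m, m) == pytest.approx(1.0)

    def test_scrambled_near_zero(self, rng):
        R = 30
        fc_vals = np.abs(_random_symmetric(rng, R))
        i, j = np.tril_indices(R, k=-1)
        sc_vals = fc_vals.copy()
        perm = rng.permutation(i.size)
        sc_vals[i, j] = fc_vals[i, j][perm]
        sc_vals[j, i] = sc_vals[i, j]
        fc = dc.ConnectivityMatrix(fc_vals, "mvdcor")
        sc = dc.ConnectivityMatrix(sc_vals, "mvdcor")
        assert abs(ev.structure_function_similarity(fc, sc)) < 0.15

    def test_backbone_weight_sweep_is_monotone(self):
        """Similarity grows with the weight of the shared backbone."""
        rng = np.random.default_rng(53)
        R = 20
        backbone = np.abs(_random_symmetric(rng, R))
        noise_f, noise_s = np.abs(_random_symmetric(rng, R)), np.abs(_random_symmetric(rng, R))
        sims = []
        for w in (0.2, 0.6, 1.0):
            fc = dc.ConnectivityMatrix(w * backbone + 0.5 * noise_f, "pcor")
            sc = dc.ConnectivityMatrix(w * backbone + 0.5 * noise_s, "pcor")
            sims.append(ev.structure_function_similarity(fc, sc))
        assert sims[0] < sims[1] < sims[2]

    def test_positive_only_mode(self, rng):
        R = 10
        fv, sv = _random_symmetric(rng, R), _random_symmetric(rng, R)
        fc = dc.ConnectivityMatrix(fv, "pcor")
        sc = dc.ConnectivityMatrix(sv, "pcor")
        val = ev.structure_function_similarity(fc, sc, mode="positive_only")
        assert -1.0 <= val <= 1.0
        with pytest.raises(ValueError, match="mode"):
            ev.structure_function_similarity(fc, sc, mode="negative_only")


class TestStructuralCovariance:
    def test_identical_gm_blocks(self, rng):
        g = rng.standard_normal((30, 6))
        m = ev.structural_covariance({1: g, 2: g.copy()}, "mvdcor")
        assert m.values[1, 0] == pytest.approx(1.0, abs=1e-10)

    def test_planted_two_module_structure(self):
        rng = np.random.default_rng(61)
        P, v = 80, 8
        t1, t2 = rng.standard_normal((2, P))
        mk = lambda t: t[:, None] + 0.4 * rng.standard_normal((P, v))
        blocks = {1: mk(t1), 2: mk(t1), 3: mk(t2), 4: mk(t2)}
        for measure in ("pcor", "mvdcor"):
            m = ev.structural_covariance(blocks, measure).values
            within = abs(m[1, 0]) + abs(m[3, 2])
            between = abs(m[2, 0]) + abs(m[3, 0]) + abs(m[2, 1]) + abs(m[3, 1])
            assert within / 2 > between / 4

    def test_too_few_participants(self, rng):
        with pytest.raises(ValueError, match="5 participants"):
            ev.structural_covariance({1: rng.standard_normal((4, 3)),
                                      2: rng.standard_normal((4, 3))}, "pcor")

    def test_zero_weakest_matches_truncation_count(self, rng):
        m = dc.ConnectivityMatrix(np.abs(_random_symmetric(rng, 8)) + 0.01, "pcor")
        out = ev.zero_weakest(m, 5)
        assert (out.lower_triangle() == 0).sum() == 5
        # the surviving entries are untouched
        keep = out.lower_triangle() != 0
        assert np.allclose(out.lower_triangle()[keep], m.lower_triangle()[keep])


def test_statistics_invariant_to_roi_relabeling(rng):
    """Simultaneous row/column permutation leaves matrix-level metrics unchanged."""
    R, P = 7, 5
    perm = rng.permutation(R)
    vals, vals_p = {}, {}
    for p in range(P):
        for s in (1, 2):
            m = _random_symmetric(rng, R)
            vals[(p, s, "pcor")] = m
            vals_p[(p, s, "pcor")] = m[np.ix_(perm, perm)]
    s1 = ev.reliability_within(_stack_from_values(vals), "pcor")
    s2 = ev.reliability_within(_stack_from_values(vals_p), "pcor")
    assert np.allclose(s1.values, s2.values)
    b1 = ev.between_participant_similarity(_stack_from_values(vals), "pcor")
    b2 = ev.between_participant_similarity(_stack_from_values(vals_p), "pcor")
    assert np.allclose(b1.values, b2.values)
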