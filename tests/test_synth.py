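"""Generator: atlas structure, coupling templates, MVAR simulation,
leadfields, sensor projection and cohort assembly."""

import numpy as np
import pytest

from pdcnet import synth



class TestAtlas:
    def test_has_28_unique_labels_in_homotopic_pairs(self, atlas):
        assert atlas.n_regions == 28
        assert len(set(atlas.labels)) == 28
        pairs = atlas.homotope_pairs
        assert len(pairs) == 14
        # perfect matching: every region appears exactly once
        seen = [i for p in pairs for i in p]
        assert sorted(seen) == list(range(28))

    def test_flip_permutation_is_involution(self, atlas):
        perm = atlas.flip_permutation()
        assert np.array_equal(perm[perm], np.arange(28))
        assert atlas.homotope("M1-L") == "M1-R"
        assert atlas.homotope("pSTS-R") == "pSTS-L"


class TestCohortTemplate:
    def test_hc_template_is_exactly_hemisphere_symmetric(self, atlas):
        g = synth.build_cohort_template("HC", seed=1)
        weights = {(s, t): w for s, t, _, w in g.edges}
        for (s, t), w in weights.items():
            mirrored = (atlas.homotope(s), atlas.homotope(t))
            assert mirrored in weights
            assert weights[mirrored] == w  # equal to machine precision

    def test_stroke_pre_reduces_affected_sma_outflow(self):
        hc = synth.build_cohort_template("HC", seed=1)
        pre = synth.build_cohort_template("stroke_pre", "left", seed=1)
        assert pre.out_strength("SMA-L") < hc.out_strength("SMA-L")
        assert pre.out_strength("vPM-R") < hc.out_strength("vPM-R")
        assert pre.out_strength("INS-L") > hc.out_strength("INS-L")
        assert pre.out_strength("dorsalA6-L") > hc.out_strength("dorsalA6-L")

    def test_stroke_post_increases_unaffected_m1_and_affected_pog(self):
        pre = synth.build_cohort_template("stroke_pre", "left", seed=1)
        post = synth.build_cohort_template("stroke_post", "left", seed=1)
        assert post.out_strength("M1-R") > pre.out_strength("M1-R")
        assert post.out_strength("PoG-L") > pre.out_strength("PoG-L")

    def test_right_lesion_mirrors_the_affected_side(self):
        hc = synth.build_cohort_template("HC", seed=1)
        pre = synth.build_cohort_template("stroke_pre", "right", seed=1)
        assert pre.out_strength("SMA-R") < hc.out_strength("SMA-R")
        assert pre.out_strength("INS-R") > hc.out_strength("INS-R")

    @pytest.mark.parametrize("condition,side", [
        ("HC", "none"), ("stroke_pre", "left"), ("stroke_pre", "right"),
        ("stroke_post", "left"), ("stroke_post", "right"),
    ])
    def test_every_template_is_stable(self, condition, side):
        g = synth.build_cohort_template(condition, side, seed=3)
        assert g.spectral_radius() < 1.0

    def test_no_self_loops_and_finite_weights(self):
        g = synth.build_cohort_template("HC", seed=5)
        for s, t, _, w in g.edges:
            assert s != t
            assert np.isfinite(w) and w > 0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            synth.build_cohort_template("bogus")
        with pytest.raises(ValueError):
            synth.build_cohort_template("HC", "left")
        with pytest.raises(ValueError):
            synth.build_cohort_template("stroke_pre", "none")


class TestSimulateMvar:
    def test_same_seed_gives_bit_identical_output(self):
        g = synth.build_cohort_template("HC", seed=1)
        a = synth.simulate_mvar(g, duration_s=20, seed=9)
        b = synth.simulate_mvar(g, duration_s=20, seed=9)
        assert np.array_equal(a.data, b.data)
        assert a.data.shape == (28, 10000)

    def test_zero_cross_coupling_gives_uncorrelated_regions(self):
        # two independent AR(1) processes: cross-correlation vanishes
        A = np.zeros((1, 2, 2))
        A[0] = np.diag([0.5, -0.4])
        out = synth.simulate_mvar(A, duration_s=120, seed=2).data
        r = np.corrcoef(out)[0, 1]
        assert abs(r) < 0.05

    def test_known_ar2_coefficients_recovered_by_least_squares(self):
        # independent oracle: direct normal-equations solve on the lagged
        # design, no pdcnet estimator involved
        A = np.zeros((2, 2, 2))
        A[0] = [[0.6, 0.2], [0.0, 0.5]]
        A[1] = [[-0.3, 0.0], [0.1, -0.2]]
        x = synth.simulate_mvar(A, duration_s=200, fs=500, seed=4).data
        n = x.shape[1]
        Y = x[:, 2:].T
        X = np.hstack([x[:, 1:n - 1].T, x[:, :n - 2].T])
        B = np.linalg.solve(X.T @ X, X.T @ Y)
        A_hat = np.stack([B[:2].T, B[2:].T])
        assert np.max(np.abs(A_hat - A)) < 0.05

    def test_unstable_template_rejected(self):
        A = np.zeros((1, 2, 2))
        A[0] = np.eye(2) * 1.01
        with pytest.raises(ValueError, match="unstable"):
            synth.simulate_mvar(A, duration_s=10, seed=0)

    def test_non_positive_duration_rejected(self):
        g = synth.build_cohort_template("HC", seed=1)
        with pytest.raises(ValueError):
            synth.simulate_mvar(g, duration_s=0, seed=0)


class TestLeadField:
    def test_shape_rank_and_unit_columns(self, atlas):
        lf = synth.make_leadfield(64, atlas, seed=7)
        assert lf.gain.shape == (64, 28)
        assert np.linalg.matrix_rank(lf.gain) == 28
        np.testing.assert_allclose(np.linalg.norm(lf.gain, axis=0), 1.0,
                                   atol=1e-12)

    def test_seeds_give_different_gains(self, atlas):
        a = synth.make_leadfield(64, atlas, seed=1)
        b = synth.make_leadfield(64, atlas, seed=2)
        assert not np.allclose(a.gain, b.gain)

    def test_too_few_sensors_rejected(self, atlas):
        with pytest.raises(ValueError):
            synth.make_leadfield(27, atlas)


class TestProjectToSensors:
    def test_infinite_snr_is_exact_forward_projection(self, atlas):
        g = synth.build_cohort_template("HC", seed=1)
        src = synth.simulate_mvar(g, duration_s=10, seed=3)
        lf = synth.make_leadfield(64, atlas, seed=7)
        rec = synth.project_to_sensors(src, lf, np.inf, seed=0)
        np.testing.assert_array_equal(rec.data, lf.gain @ src.data)

    def test_zero_db_snr_within_half_decibel(self, atlas):
        g = synth.build_cohort_template("HC", seed=1)
        src = synth.simulate_mvar(g, duration_s=60, seed=3)
        lf = synth.make_leadfield(64, atlas, seed=7)
        rec = synth.project_to_sensors(src, lf, 0.0, seed=5)
        clean = lf.gain @ src.data
        noise = rec.data - clean
        snr = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        assert abs(snr) < 0.5

    def test_dimension_mismatch_rejected(self, atlas):
        g = synth.build_cohort_template("HC", seed=1)
        src = synth.simulate_mvar(g, duration_s=10, seed=3)
        bad = synth.make_leadfield(64, atlas, seed=7)
        bad.gain = bad.gain[:, :20]
        with pytest.raises(ValueError):
            synth.project_to_sensors(src, bad, 10.0, seed=0)


class TestGenerateCohort:
    def test_hc_only_cohort(self):
        recs, truth, _ = synth.generate_cohort(
            4, ("HC",), seed=3, duration_s=20)
        assert len(recs) == 4
        assert all(r.lesion_side == "none" for r in recs)
        assert len(truth) == 4

    def test_stroke_sessions_are_paired_with_mixed_lesion_sides(self):
        recs, truth, _ = synth.generate_cohort(
            4, ("stroke_pre", "stroke_post"), seed=3, duration_s=20)
        assert len(recs) == 8
        pre = {r.subject_id for r in recs if r.session == "pre"}
        post = {r.subject_id for r in recs if r.session == "post"}
        assert pre == post
        sides = {r.subject_id: r.lesion_side for r in recs}
        assert set(sides.values()) == {"left", "right"}

    def test_paired_sessions_share_subject_jitter(self):
        recs, truth, _ = synth.generate_cohort(
            2, ("stroke_pre", "stroke_post"), seed=3, duration_s=20)
        g_pre = truth[("ST001", "pre")]
        g_post = truth[("ST001", "post")]
        # an edge untouched by the post-intervention factors is identical
        post_sources = {"M1-R", "PoG-L"}  # left-lesion subject
        for (s, t, b, w_pre) in g_pre.edges:
            if s in post_sources:
                continue
            w_post = [w for ss, tt, _, w in g_post.edges
                      if ss == s and tt == t]
            assert w_post and w_post[0] == pytest.approx(w_pre)

    def test_same_seed_reproduces_cohort_exactly(self):
        a, _, _ = synth.generate_cohort(2, ("HC",), seed=9, duration_s=20)
        b, _, _ = synth.generate_cohort(2, ("HC",), seed=9, duration_s=20)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_empty_conditions_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_cohort(2, (), seed=0)
        with pytest.raises(ValueError):
            synth.generate_cohort(0, ("HC",), seed=0)
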