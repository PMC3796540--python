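import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqvote import (
    RawTrajectory,
    SequencePattern,
    SyntheticSpec,
    fit_class_prototype,
    generate_synthetic_pair_dataset,
    normalize_size,
    preprocess,
    read_trajectories,
    resample_arclength,
    summed_cost,
    write_trajectories,
)


def traj(points, sid="s", cls="A"):
    return RawTrajectory(sid, cls, np.asarray(points, dtype=float))


class TestReadWrite:
    def test_long_csv_basic(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "sample_id,class,point_index,x0,x1\n"
            "s1,A,1,0,0\n"
            "s1,A,2,1,1\n"
        )
        out = read_trajectories(p, "long_csv")
        assert len(out) == 1
        assert out[0].class_id == "A"
        np.testing.assert_array_equal(out[0].points, [[0, 0], [1, 1]])

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("")
        assert read_trajectories(p, "long_csv") == []

    def test_two_samples_lengths(self, tmp_path):
        p = tmp_path / "t.csv"
        rows = ["sample_id,class,point_index,x0,x1"]
        rows += [f"a,A,{i},{i},0" for i in range(1, 4)]
        rows += [f"b,B,{i},{i},1" for i in range(1, 6)]
        p.write_text("\n".join(rows))
        out = read_trajectories(p, "long_csv")
        assert [t.length for t in out] == [3, 5]

    def test_unparseable_line_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,class,point_index,x0\ns1,A,1,0\ns1,A,2,oops\n")
        with pytest.raises(ValueError, match="line 3"):
            read_trajectories(p, "long_csv")

    def test_roundtrip(self, tmp_path):
        trajs = [traj([[0, 1], [2, 3.5]], "a", "X"), traj([[9, 9]], "b", "Y")]
        p = tmp_path / "rt.csv"
        write_trajectories(trajs, p)
        back = read_trajectories(p, "long_csv")
        for orig, rec in zip(trajs, back):
            assert (orig.sample_id, orig.class_id) == (rec.sample_id, rec.class_id)
            np.testing.assert_allclose(orig.points, rec.points)

    def test_uci_pendigits_orig(self, tmp_path):
        p = tmp_path / "d.tra"
        p.write_text(
            ".VERSION 1.0\n"
            ".COMMENT digits\n"
            '.SEGMENT DIGIT 0 ? "8"\n'
            ".PEN_DOWN\n"
            "10 20\n"
            "11 21\n"
            ".PEN_UP\n"
            ".PEN_DOWN\n"
            "12 22\n"
            ".PEN_UP\n"
            '.SEGMENT DIGIT 1 ? "3"\n'
            ".PEN_DOWN\n"
            "5 5\n"
            "6 6\n"
            ".PEN_UP\n"
        )
        out = read_trajectories(p, "uci_pendigits_orig")
        assert [t.class_id for t in out] == ["8", "3"]
        assert [t.length for t in out] == [3, 2]
        np.testing.assert_array_equal(out[0].points[0], [10, 20])


class TestNormalizeSize:
    def test_square_bbox_maps_to_unit_square(self):
        out = normalize_size(traj([[0, 0], [2, 2]]))
        np.testing.assert_allclose(out.points, [[0, 0], [1, 1]])

    def test_single_point_to_center(self):
        out = normalize_size(traj([[37.0, -4.0]]))
        np.testing.assert_allclose(out.points, [[0.5, 0.5]])

    def test_aspect_preserving_centering(self):
        # extent (4, 2), scale 1/4, narrow axis centered: y in [0.25, 0.75]
        out = normalize_size(traj([[0, 0], [4, 2]]))
        np.testing.assert_allclose(out.points, [[0, 0.25], [1, 0.75]])

    def test_per_axis_variant(self):
        out = normalize_size(traj([[0, 0], [4, 2]]), aspect_preserving=False)
        np.testing.assert_allclose(out.points, [[0, 0], [1, 1]])

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=1, max_size=12))
    @settings(deadline=None, max_examples=40)
    def test_idempotent(self, pts):
        once = normalize_size(traj(pts))
        twice = normalize_size(once)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-12)


class TestResample:
    def test_segment_uniform(self):
        out = resample_arclength(traj([[0, 0], [1, 0]]), 3)
        np.testing.assert_allclose(out.points, [[0, 0], [0.5, 0], [1, 0]])

    def test_idempotent_on_uniform_line(self):
        pts = np.column_stack([np.linspace(0, 1, 5), np.zeros(5)])
        out = resample_arclength(traj(pts), 5)
        np.testing.assert_allclose(out.points, pts, atol=1e-12)

    def test_polyline_arclengths(self):
        # path (0,0)->(1,0)->(1,1), total length 2; targets at 0,.5,1,1.5,2
        out = resample_arclength(traj([[0, 0], [1, 0], [1, 1]]), 5)
        np.testing.assert_allclose(
            out.points, [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1]]
        )

    def test_endpoints_bitwise(self):
        pts = np.array([[0.123, 4.56], [7.8, 9.01], [3.3, 2.2]])
        out = resample_arclength(traj(pts), 7)
        assert out.n_points == 7
        assert np.array_equal(out.points[0], pts[0])
        assert np.array_equal(out.points[-1], pts[-1])

    def test_degenerate_zero_length(self):
        out = resample_arclength(traj([[2, 2], [2, 2]]), 4)
        np.testing.assert_array_equal(out.points, np.full((4, 2), 2.0))

    @given(st.integers(2, 30), st.integers(2, 9))
    @settings(deadline=None, max_examples=30)
    def test_output_length_always_T(self, L, T):
        rng = np.random.default_rng(L * 100 + T)
        out = resample_arclength(traj(rng.random((L, 2))), T)
        assert out.n_points == T


class TestSynthetic:
    def test_zero_noise_equals_template(self):
        spec = SyntheticSpec(n_points=8, dim=2, noise_scale=0.0,
                             n_train=3, n_test=2, seed=5)
        train, test = generate_synthetic_pair_dataset(spec)
        t0, t1 = spec.resolved_templates()
        for s in train + test:
            np.testing.assert_allclose(s.points, t0 if s.class_id == "0" else t1)

    def test_seed_reproducibility(self):
        spec = SyntheticSpec(n_points=6, n_train=4, n_test=4, seed=11,
                             outlier_points=(1, 3), outlier_prob=0.5,
                             outlier_scale=1.0)
        a_train, a_test = generate_synthetic_pair_dataset(spec)
        b_train, b_test = generate_synthetic_pair_dataset(spec)
        for a, b in zip(a_train + a_test, b_train + b_test):
            assert np.array_equal(a.points, b.points)

    def test_confusable_segment_forces_identical_templates(self):
        spec = SyntheticSpec(n_points=10, confusable_segment=(3, 7),
                             n_train=1, n_test=1)
        t0, t1 = spec.resolved_templates()
        np.testing.assert_array_equal(t0[3:7], t1[3:7])
        assert not np.allclose(t0[0], t1[0])

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_points=5, confusable_segment=(2, 9),
                          n_train=1, n_test=1)
        with pytest.raises(ValueError):
            SyntheticSpec(n_points=5, outlier_points=(7,), n_train=1, n_test=1)

    def test_fully_confusable_data_gives_chance_accuracy(self):
        # both templates identical everywhere: no classifier can beat chance.
        spec = SyntheticSpec(n_points=6, dim=2, noise_scale=0.1,
                             confusable_segment=(0, 6), n_train=50,
                             n_test=1000, seed=7)
        train, test = generate_synthetic_pair_dataset(spec)
        protos = {c: fit_class_prototype([s for s in train if s.class_id == c], c)
                  for c in ("0", "1")}
        hits = 0
        for s in test:
            d0 = summed_cost(s, protos["0"])
            d1 = summed_cost(s, protos["1"])
            decided = "0" if d0 <= d1 else "1"
            hits += decided == s.class_id
        acc = hits / len(test)
        # 3-sigma binomial band around 0.5 at n = 2000
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / len(test))


def test_preprocess_pipeline_shapes():
    rng = np.random.default_rng(0)
    out = preprocess(traj(rng.random((23, 2)) * 40), n_points=49)
    assert out.n_points == 49
    assert out.points.min() >= 0 and out.points.max() <= 1
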