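import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from madet.nets import (
    LayerSpec,
    NetworkSpec,
    TrainConfig,
    binary_cross_entropy,
    build_basic_cnn,
    build_final_cnn,
    count_parameters,
    leaky_relu,
    load_net,
    output_shapes,
    predict_proba,
    save_net,
    train,
)
from madet.patches import MA, NON_MA, PatchRecord


def blob_patch(rng, side=15, dark=True):
    """A flat patch, optionally with a dark central blob (separable classes)."""
    px = np.full((side, side, 3), 140.0, dtype=np.float32)
    px += rng.normal(0, 3, px.shape)
    if dark:
        yy, xx = np.mgrid[:side, :side] - side // 2
        dip = 70 * np.exp(-(yy**2 + xx**2) / (2 * 2.5**2))
        px -= dip[..., None]
    return np.clip(px, 0, 255).astype(np.float32)


def blob_dataset(rng, n_per_class=100, side=15):
    recs = [
        PatchRecord((0, 0), MA, "a", pixels=blob_patch(rng, side, dark=True))
        for _ in range(n_per_class)
    ]
    recs += [
        PatchRecord((0, 0), NON_MA, "a", pixels=blob_patch(rng, side, dark=False))
        for _ in range(n_per_class)
    ]
    return recs


class TestActivationsAndLoss:
    def test_leaky_relu_point_values(self):
        assert leaky_relu(3.0) == 3.0
        assert np.isclose(leaky_relu(-2.0, a=0.01), -0.02)
        assert leaky_relu(0.0) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        arrays(np.float64, (4, 5), elements=st.floats(-100, 100)),
        st.floats(0.001, 0.5),
    )
    def test_leaky_relu_matches_piecewise_closed_form(self, x, a):
        expected = np.where(x >= 0, x, a * x)
        np.testing.assert_allclose(leaky_relu(x, a), expected)

    def test_cross_entropy_closed_form_and_symmetry(self):
        assert np.isclose(binary_cross_entropy(1, 0.5), np.log(2), atol=1e-12)
        assert binary_cross_entropy(1, 1.0) < 1e-6
        assert np.isclose(
            binary_cross_entropy(0, 0.5), binary_cross_entropy(1, 0.5)
        )

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 1), st.floats(0.001, 0.999))
    def test_cross_entropy_nonnegative(self, t, p):
        assert binary_cross_entropy(t, p) >= 0

    def test_cross_entropy_rejects_out_of_range_probability(self):
        with pytest.raises(ValueError):
            binary_cross_entropy(1, 1.5)


class TestArchitectures:
    def test_basic_net_layer_structure(self):
        spec = build_basic_cnn(101)
        convs = [l for l in spec.layers if l.op == "convolution"]
        pools = [l for l in spec.layers if l.op == "max_pool"]
        fcs = [l for l in spec.layers if l.op == "fully_connected"]
        assert [l.kernel_side for l in convs] == [7, 5, 3]
        assert all(l.n_units == 16 for l in convs)
        assert len(pools) == 3 and all(l.dropout_p == 0.25 for l in pools)
        assert [l.n_units for l in fcs] == [200, 100, 2]
        assert spec.layers[-1].op == "softmax"

    def test_final_net_layer_structure_and_dropout_placement(self):
        spec = build_final_cnn(101)
        convs = [l for l in spec.layers if l.op == "convolution"]
        pools = [l for l in spec.layers if l.op == "max_pool"]
        fcs = [l for l in spec.layers if l.op == "fully_connected"]
        assert [l.kernel_side for l in convs] == [7, 5, 3, 2, 2]
        assert len(pools) == 5
        assert [l.dropout_p for l in pools] == [0.25, 0.0, 0.25, 0.0, 0.0]
        assert [l.n_units for l in fcs] == [100, 2]

    @pytest.mark.parametrize(
        "builder,side,expected",
        [
            # hand-propagated: valid conv s-k+1, pool floor((s-2)/2)+1
            (
                build_basic_cnn,
                101,
                [(16, 95, 95), (16, 47, 47), (16, 43, 43), (16, 21, 21),
                 (16, 19, 19), (16, 9, 9), (200,), (100,), (2,), (2,)],
            ),
            (
                build_basic_cnn,
                25,
                [(16, 19, 19), (16, 9, 9), (16, 5, 5), (16, 2, 2),
                 (16, 2, 2), (16, 1, 1), (200,), (100,), (2,), (2,)],
            ),
            (
                build_final_cnn,
                101,
                [(16, 101, 101), (16, 50, 50), (16, 46, 46), (16, 23, 23),
                 (16, 21, 21), (16, 10, 10), (16, 9, 9), (16, 4, 4),
                 (16, 3, 3), (16, 1, 1), (100,), (2,), (2,)],
            ),
        ],
    )
    def test_shape_propagation_matches_hand_table(self, builder, side, expected):
        assert output_shapes(builder(side)) == expected

    def test_final_net_spatial_size_stays_positive_at_101(self):
        shapes = output_shapes(build_final_cnn(101))
        assert all(s[-1] >= 1 for s in shapes if len(s) == 3)

    def test_basic_net_parameter_count_frozen_regression(self):
        # conv1 16*(3*49)+16=2368; conv2 16*(16*25)+16=6416;
        # conv3 16*(16*9)+16=2320; fc1 (16*9*9)*200+200=259400;
        # fc2 200*100+100=20100; fc3 100*2+2=202  -> total 290806
        assert count_parameters(build_basic_cnn(101)) == 290806

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(
                (3, 8, 8),
                [
                    LayerSpec("convolution", n_units=4, kernel_side=9),
                    LayerSpec("softmax", n_units=2),
                ],
            )

    def test_yaml_round_trip(self):
        spec = build_final_cnn(25)
        again = NetworkSpec.from_yaml(spec.to_yaml())
        assert again == spec


class TestTraining:
    def test_loss_decreases_on_separable_classes(self, rng):
        recs = blob_dataset(rng)
        net = train(build_basic_cnn(15), recs, TrainConfig(epochs=5, seed=0))
        assert len(net.training_log) == 5
        assert net.training_log[-1] < net.training_log[0]

    def test_reaches_95_percent_training_accuracy(self, rng):
        recs = blob_dataset(rng)
        net = train(build_basic_cnn(15), recs, TrainConfig(epochs=5, seed=0))
        X = np.stack([r.pixels for r in recs])
        y = np.array([r.label for r in recs])
        acc = ((predict_proba(net, X) > 0.5) == y).mean()
        assert acc >= 0.95

    def test_single_epoch_logs_one_entry(self, rng):
        recs = blob_dataset(rng, n_per_class=20)
        net = train(build_basic_cnn(15), recs, TrainConfig(epochs=1, seed=0))
        assert len(net.training_log) == 1

    def test_single_class_input_rejected(self, rng):
        recs = [
            PatchRecord((0, 0), MA, "a", pixels=blob_patch(rng)) for _ in range(10)
        ]
        with pytest.raises(ValueError):
            train(build_basic_cnn(15), recs, TrainConfig(epochs=1))

    def test_training_is_deterministic_given_seed(self, rng):
        recs = blob_dataset(rng, n_per_class=20)
        X = np.stack([r.pixels for r in recs])
        a = train(build_basic_cnn(15), recs, TrainConfig(epochs=2, seed=5))
        b = train(build_basic_cnn(15), recs, TrainConfig(epochs=2, seed=5))
        np.testing.assert_array_equal(predict_proba(a, X), predict_proba(b, X))

    def test_maxout_variant_trains(self, rng):
        recs = blob_dataset(rng, n_per_class=20)
        spec = build_basic_cnn(15, activation="maxout")
        net = train(spec, recs, TrainConfig(epochs=1, seed=0))
        p = predict_proba(net, np.stack([r.pixels for r in recs]))
        assert np.all((p >= 0) & (p <= 1))


class TestPrediction:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        rng = np.random.default_rng(77)
        recs = blob_dataset(rng, n_per_class=30)
        return train(build_basic_cnn(15), recs, TrainConfig(epochs=2, seed=0)), recs

    def test_probabilities_in_unit_interval(self, fitted):
        net, recs = fitted
        p = predict_proba(net, np.stack([r.pixels for r in recs]))
        assert np.all((p >= 0) & (p <= 1))

    def test_duplicated_patch_gets_identical_probability(self, fitted):
        net, recs = fitted
        X = np.stack([recs[0].pixels, recs[0].pixels])
        p = predict_proba(net, X)
        assert p[0] == p[1]

    def test_shape_mismatch_rejected(self, fitted):
        net, _ = fitted
        with pytest.raises(ValueError):
            predict_proba(net, np.zeros((1, 11, 11, 3), dtype=np.float32))

    def test_save_load_round_trip_preserves_predictions(self, fitted, tmp_path):
        net, recs = fitted
        X = np.stack([r.pixels for r in recs[:8]])
        save_net(net, tmp_path / "net")
        again = load_net(tmp_path / "net")
        np.testing.assert_array_equal(predict_proba(net, X), predict_proba(again, X))
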