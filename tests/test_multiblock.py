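import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbsig.data import DataError
from mbsig.multiblock import (
    ConfusionCounts,
    MultiblockSPLSDA,
    balanced_error_rate,
    fit_block_splsda,
    make_design,
    soft_threshold_keep,
)
from mbsig.plsda import fit_plsda


class TestSoftThreshold:
    def test_hand_checkable_example(self):
        out = soft_threshold_keep(np.array([3.0, -2.0, 1.0]), 2)
        np.testing.assert_allclose(out, np.array([2.0, -1.0, 0.0]) / np.sqrt(5))

    def test_keep_all_is_normalization_only(self, rng):
        w = rng.normal(size=7)
        out = soft_threshold_keep(w, 7)
        np.testing.assert_allclose(out, w / np.linalg.norm(w))

    def test_tie_at_threshold_resolves_to_lowest_index(self):
        out = soft_threshold_keep(np.array([2.0, 2.0, 1.0]), 1)
        assert np.count_nonzero(out) == 1
        assert out[0] != 0

    def test_keep_below_one_rejected(self):
        with pytest.raises(DataError):
            soft_threshold_keep(np.ones(3), 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=30).filter(
            lambda v: any(x != 0 for x in v)
        ),
        st.data(),
    )
    def test_cardinality_norm_and_sign_contract(self, values, data):
        w = np.array(values)
        keep = data.draw(st.integers(1, len(values)))
        out = soft_threshold_keep(w, keep)
        assert np.count_nonzero(out) == min(keep, np.count_nonzero(w) or keep)
        assert np.linalg.norm(out) == pytest.approx(1.0)
        nz = out != 0
        assert np.all(np.sign(out[nz & (w != 0)]) == np.sign(w[nz & (w != 0)]))


class TestDesign:
    def test_full_design_shape_and_symmetry(self):
        D = make_design(["a", "b"])
        assert D.shape == (3, 3)
        np.testing.assert_array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_outcome_disconnection_rejected(self):
        with pytest.raises(DataError, match="outcome"):
            make_design(["a", "b"], to_outcome=0.0)


class TestFitEquivalenceAndContracts:
    def test_single_block_full_keepx_matches_plsda(self, rng):
        """With one block, keepX = all and one component, the multiblock
        objective degenerates to PLS-DA: scores and weights agree up to sign
        within 1e-8."""
        for _ in range(5):
            X = rng.normal(size=(20, 15))
            X -= X.mean(0)
            y = np.array([0] * 12 + [1] * 8)
            single = fit_plsda(X, y, 1)
            multi = fit_block_splsda(y, {"b": X}, keepx=15, n_components=1,
                                     scale=False)
            t1, t2 = single.scores[:, 0], multi.scores["b"][:, 0]
            s = np.sign(t1 @ t2)
            np.testing.assert_allclose(t1, s * t2, atol=1e-8)
            np.testing.assert_allclose(
                single.x_weights[:, 0], s * multi.weights["b"][:, 0], atol=1e-8
            )

    def test_sparsity_contract_exact_nonzero_counts(self, rng):
        y = np.array([0] * 12 + [1] * 8)
        for _ in range(10):
            p1, p2 = rng.integers(5, 40, size=2)
            k1 = int(rng.integers(1, p1 + 1))
            k2 = int(rng.integers(1, p2 + 1))
            H = int(rng.integers(1, 3))
            m = fit_block_splsda(
                y,
                {"a": rng.normal(size=(20, p1)), "b": rng.normal(size=(20, p2))},
                keepx={"a": k1, "b": k2},
                n_components=H,
            )
            for h in range(H):
                assert np.count_nonzero(m.weights["a"][:, h]) == k1
                assert np.count_nonzero(m.weights["b"][:, h]) == k2

    def test_duplicated_block_gets_symmetric_weights(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.array([0] * 10 + [1] * 10)
        m = fit_block_splsda(
            y, {"a": X, "b": X.copy()}, keepx=10, n_components=1
        )
        wa, wb = m.weights["a"][:, 0], m.weights["b"][:, 0]
        s = np.sign(wa @ wb)
        np.testing.assert_allclose(wa, s * wb, atol=1e-6)

    def test_objective_is_nondecreasing_with_full_keepx(self, rng):
        X1 = rng.normal(size=(20, 12))
        X2 = rng.normal(size=(20, 8))
        y = np.array([0] * 12 + [1] * 8)
        model = MultiblockSPLSDA(
            y, {"a": X1, "b": X2}, n_components=1, track_objective=True
        )
        model.fit()
        trace = np.array(model.objective_trace[0])
        assert trace.size >= 1
        assert np.all(np.diff(trace) >= -1e-8)

    def test_all_zero_block_rejected(self):
        y = np.array([0, 0, 1, 1])
        with pytest.raises(DataError, match="all-zero"):
            fit_block_splsda(y, {"a": np.zeros((4, 3))})


class TestPrediction:
    @pytest.fixture()
    def separable_fit(self, rng):
        from mbsig.simulate import SimulationSpec, generate_dataset
        from mbsig.preprocess import total_intensity_normalize

        ds, _ = generate_dataset(SimulationSpec(seed=3, effect_size=3.0))
        y = ds.y()
        nmr = total_intensity_normalize(ds.block("nmr"))
        blocks = {"nmr": nmr.matrix, "lipid": ds.block("lipid").matrix}
        fids = {"nmr": nmr.feature_ids, "lipid": ds.block("lipid").feature_ids}
        model = fit_block_splsda(
            y, blocks, keepx={"nmr": 10, "lipid": 2}, n_components=1,
            feature_ids=fids,
        )
        return model, blocks, y

    def test_training_ber_zero_on_separable_fit(self, separable_fit):
        model, blocks, y = separable_fit
        pred = model.predict(blocks)["aggregate"]
        cc = ConfusionCounts.from_predictions(y, pred)
        assert balanced_error_rate(cc) == 0.0

    def test_sample_at_centroid_classified_to_it(self, separable_fit):
        model, blocks, y = separable_fit
        # invert the projection is unnecessary: feed back a training sample
        # whose scores are closest to each centroid
        scores = model.transform(blocks)
        for name in model.block_names:
            cent = model.centroids[name]
            for k, cls in enumerate(model.classes):
                j = np.argmin(np.abs(scores[name][:, 0] - cent[k, 0]))
                single = {n: blocks[n][j] for n in blocks}
                pred = model.predict(single)
                if abs(scores[name][j, 0] - cent[k, 0]) < 1e-6:
                    assert pred["per_block"][name][0] == cls

    def test_shuffled_feature_columns_align_by_id(self, separable_fit, rng):
        model, blocks, y = separable_fit
        base = model.predict(blocks)["aggregate"]
        shuffled = {}
        for name in blocks:
            ids = model.feature_ids[name]
            perm = rng.permutation(len(ids))
            shuffled[name] = pd.DataFrame(
                blocks[name][:, perm], columns=[ids[i] for i in perm]
            )
        pred = model.predict(shuffled)["aggregate"]
        np.testing.assert_array_equal(base, pred)

    def test_missing_features_named_in_error(self, separable_fit):
        model, blocks, _ = separable_fit
        bad = {
            "nmr": pd.DataFrame(
                blocks["nmr"][:, :-1], columns=model.feature_ids["nmr"][:-1]
            ),
            "lipid": blocks["lipid"],
        }
        with pytest.raises(DataError, match="missing feature ids"):
            model.predict(bad)

    def test_block_rescaling_leaves_predictions_unchanged(self, separable_fit):
        model, blocks, y = separable_fit
        base = model.predict(blocks)["aggregate"]
        scaled_blocks = {"nmr": blocks["nmr"] * 37.5, "lipid": blocks["lipid"]}
        refit = fit_block_splsda(
            y, scaled_blocks, keepx={"nmr": 10, "lipid": 2}, n_components=1,
            feature_ids=model.feature_ids,
        )
        pred = refit.predict(scaled_blocks)["aggregate"]
        np.testing.assert_array_equal(base, pred)

    def test_label_swap_flips_centroids_not_ber(self, separable_fit):
        model, blocks, y = separable_fit
        swapped = fit_block_splsda(
            y.max() - y, blocks,
            keepx={"nmr": 10, "lipid": 2}, n_components=1,
            feature_ids=model.feature_ids,
        )
        pred_a = model.predict(blocks)["aggregate"]
        pred_b = swapped.predict(blocks)["aggregate"]
        cc_a = ConfusionCounts.from_predictions(y, pred_a)
        cc_b = ConfusionCounts.from_predictions(y.max() - y, pred_b)
        assert balanced_error_rate(cc_a) == balanced_error_rate(cc_b)


class TestBalancedErrorRate:
    @pytest.mark.parametrize(
        "totals,errors,expected",
        [
            ({"A": 12, "B": 8}, {"A": 3, "B": 2}, 0.25),
            ({"A": 12, "B": 8}, {"A": 0, "B": 0}, 0.0),
            ({"A": 12, "B": 8}, {"A": 0, "B": 8}, 0.5),
        ],
    )
    def test_printed_style_confusions(self, totals, errors, expected):
        assert balanced_error_rate(ConfusionCounts(totals, errors)) == expected

    def test_errors_cannot_exceed_totals(self):
        with pytest.raises(DataError):
            ConfusionCounts({"A": 3}, {"A": 4})

    def test_empty_class_rejected(self):
        with pytest.raises(DataError, match="empty"):
            balanced_error_rate(ConfusionCounts({"A": 5, "B": 0}, {"A": 1, "B": 0}))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 30), st.data())
    def test_ber_bounds_and_symmetry(self, na, nb, data):
        ea = data.draw(st.integers(0, na))
        eb = data.draw(st.integers(0, nb))
        ber = balanced_error_rate(
            ConfusionCounts({"A": na, "B": nb}, {"A": ea, "B": eb})
        )
        assert 0.0 <= ber <= 1.0
        flipped = balanced_error_rate(
            ConfusionCounts({"A": nb, "B": na}, {"A": eb, "B": ea})
        )
        assert ber == pytest.approx(flipped)


def test_model_serialization_roundtrip(tmp_path, rng):
    from mbsig.multiblock import MultiblockSPLSDAResults

    X1 = rng.normal(size=(20, 12))
    X2 = rng.normal(size=(20, 8))
    y = np.array([0] * 12 + [1] * 8)
    model = fit_block_splsda(y, {"a": X1, "b": X2},
                             keepx={"a": 4, "b": 3}, n_components=2)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = MultiblockSPLSDAResults.load(path)
    pred_a = model.predict({"a": X1, "b": X2})
    pred_b = loaded.predict({"a": X1, "b": X2})
    np.testing.assert_array_equal(pred_a["aggregate"], pred_b["aggregate"])
    for name in ("a", "b"):
        np.testing.assert_allclose(pred_a["scores"][name],
                                   pred_b["scores"][name])
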