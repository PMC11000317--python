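from itertools import combinations

import numpy as np
import pytest

from mbsig.data import DataError
from mbsig.evaluation import (
    clustered_image_map,
    repeated_cv_auc_bias,
    roc_auc_with_p,
)


def brute_force_rank_p(x, y):
    """Exact permutation p-value of the rank-sum statistic by enumerating
    every assignment of the pooled ranks to the first sample."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    idx = range(len(pooled))
    stats_all = [
        sum(ranks[list(comb)]) for comb in combinations(idx, n1)
    ]
    mean = np.mean(stats_all)
    extreme = sum(
        1 for s in stats_all if abs(s - mean) >= abs(obs - mean) - 1e-9
    )
    return extreme / len(stats_all)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array(["NoDecline"] * 3 + ["Decline"] * 3)
        r = roc_auc_with_p(scores, labels)
        assert r["auc"] == 1.0

    def test_identical_scores_give_half_and_p_one(self):
        scores = np.ones(8)
        labels = np.array(["NoDecline"] * 5 + ["Decline"] * 3)
        r = roc_auc_with_p(scores, labels)
        assert r["auc"] == 0.5
        assert r["p_value"] == 1.0

    def test_two_vs_two_enumeration(self):
        """Scores (1,2) vs (3,4): AUC 1 and exact two-sided p = 1/3."""
        r = roc_auc_with_p(
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array(["NoDecline", "NoDecline", "Decline", "Decline"]),
        )
        assert r["auc"] == 1.0
        assert r["p_value"] == pytest.approx(1 / 3)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=14)
        labels = np.array(["Decline"] * 6 + ["NoDecline"] * 8)
        c = roc_auc_with_p(scores, labels)["curve"]
        assert (c.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (c.iloc[-1][["fpr", "tpr"]] == 1).all()
        assert (c["fpr"].diff().dropna() >= 0).all()
        assert (c["tpr"].diff().dropna() >= 0).all()

    def test_negated_scores_complement_auc(self, rng):
        scores = rng.normal(size=20)
        labels = np.array(["Decline"] * 8 + ["NoDecline"] * 12)
        a = roc_auc_with_p(scores, labels)["auc"]
        b = roc_auc_with_p(-scores, labels)["auc"]
        assert a + b == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (2, 7)])
    def test_p_matches_brute_force_enumeration(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.5
        labels = np.array(["Decline"] * n1 + ["NoDecline"] * n2)
        r = roc_auc_with_p(np.concatenate([x, y]), labels)
        assert r["p_value"] == pytest.approx(brute_force_rank_p(x, y))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc_with_p(np.arange(4.0), np.array(["Decline"] * 4))


@pytest.fixture(scope="module")
def bias_table():
    from mbsig import MultiBlockDataset, SimulationSpec, generate_dataset
    from mbsig.preprocess import total_intensity_normalize

    ds, _ = generate_dataset(SimulationSpec(seed=3, effect_size=2.0))
    ds = MultiBlockDataset(
        ds.samples,
        [total_intensity_normalize(ds.block("nmr")), ds.block("lipid")],
    )
    return repeated_cv_auc_bias(
        ds, keepx={"nmr": 10, "lipid": 2}, n_components=1,
        repeats=10, folds=2, seed=0,
    )


class TestCvAucBias:
    def test_bias_is_cv_minus_apparent(self, bias_table):
        for _, row in bias_table.iterrows():
            assert row["bias"] == pytest.approx(
                row["cv_auc"] - row["apparent_auc"]
            )

    def test_exactly_twenty_heldout_values(self, bias_table):
        assert (bias_table["n_cv_values"] == 20).all()

    def test_null_data_cv_auc_near_chance(self):
        from mbsig import MultiBlockDataset, SimulationSpec, generate_dataset
        from mbsig.preprocess import total_intensity_normalize

        aucs = []
        for seed in range(8):
            ds, _ = generate_dataset(
                SimulationSpec(seed=seed, effect_size=0.0, p_lipid=40)
            )
            ds = MultiBlockDataset(
                ds.samples,
                [total_intensity_normalize(ds.block("nmr")),
                 ds.block("lipid")],
            )
            t = repeated_cv_auc_bias(
                ds, keepx={"nmr": 10, "lipid": 2}, repeats=3, folds=2,
                seed=seed,
            )
            aucs.append(t["cv_auc"].mean())
        assert 0.3 <= np.mean(aucs) <= 0.7


class TestClusteredImageMap:
    def test_shape_and_permutation_contract(self, rng):
        X = rng.normal(size=(20, 12))
        labels = ["Decline"] * 8 + ["NoDecline"] * 12
        cim = clustered_image_map(X, labels)
        assert cim.matrix.shape == (20, 12)
        assert sorted(cim.row_order) == list(range(20))
        assert sorted(cim.col_order) == list(range(12))

    def test_separable_classes_form_pure_clusters(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(5)
        X = np.vstack([
            rng.normal(0, 0.3, size=(12, 6)),
            rng.normal(5, 0.3, size=(8, 6)),
        ])
        labels = np.array(["NoDecline"] * 12 + ["Decline"] * 8)
        cim = clustered_image_map(X, labels)
        two = fcluster(cim.row_linkage, 2, criterion="maxclust")
        for k in (1, 2):
            members = labels[two == k]
            assert len(set(members)) == 1

    def test_duplicated_column_leaves_are_adjacent(self, rng):
        X = rng.normal(size=(10, 5))
        X = np.hstack([X, X[:, [2]]])  # column 5 duplicates column 2
        cim = clustered_image_map(X, ["Decline"] * 5 + ["NoDecline"] * 5)
        pos = {j: i for i, j in enumerate(cim.col_order)}
        assert abs(pos[2] - pos[5]) == 1

    def test_fewer_than_two_features_rejected(self, rng):
        with pytest.raises(DataError):
            clustered_image_map(rng.normal(size=(5, 1)), ["a"] * 5)
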