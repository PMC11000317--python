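


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scipy.stats import hypergeom, rankdata

from mbsig.clinical import baseline_table, fisher_exact, mann_whitney_u
from mbsig.data import DataError, SampleTable

# printed 2x2 baseline rows: (name, [[k_nodecline, rest], [k_decline, rest]])
TABLE1_ROWS = {
    "hypertension": ([[5, 7], [5, 3]], 0.650),
    "asthma_copd": ([[0, 12], [1, 7]], 0.400),
    "diabetes": ([[2, 10], [1, 7]], 1.000),
    "ischemic_heart_disease": ([[1, 11], [2, 6]], 0.537),
    "cdr_score_0": ([[4, 8], [4, 4]], 0.648),
    "fried_robust": ([[6, 5], [2, 4]], 0.620),
}


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by direct enumeration of all 2x2 tables with the
    observed margins (point-probability rule)."""
    table = np.asarray(table)
    r1, r2 = table.sum(axis=1)
    c1 = table[:, 0].sum()
    n = table.sum()
    obs = hypergeom.pmf(table[0, 0], n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom.pmf(k, n, r1, c1)
        if p <= obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


class TestFisherExact:
    @pytest.mark.parametrize("name", sorted(TABLE1_ROWS))
    def test_printed_baseline_rows(self, name):
        table, expected = TABLE1_ROWS[name]
        assert fisher_exact(table) == pytest.approx(expected, abs=5e-4)

    def test_zero_margin_degenerates_to_one(self):
        assert fisher_exact([[0, 12], [0, 8]]) == 1.0

    def test_invariant_to_transpose_and_swaps(self, rng):
        t = rng.integers(0, 10, size=(2, 2))
        p = fisher_exact(t)
        assert fisher_exact(t.T) == pytest.approx(p)
        assert fisher_exact(t[::-1]) == pytest.approx(p)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4).filter(
        lambda v: sum(v) > 0
    ))
    def test_matches_enumeration_oracle(self, cells):
        table = np.array(cells).reshape(2, 2)
        assert fisher_exact(table) == pytest.approx(
            fisher_enumeration_oracle(table), abs=1e-10
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[1, -1], [2, 3]])

    def test_rxc_exact_matches_2x2_rule(self):
        t = [[3, 5], [4, 2], [1, 5]]
        p = fisher_exact(t, exact_rxc=True)
        assert 0.0 < p <= 1.0
        # collapsing to 2x2 must agree with the 2x2 path
        t2 = [[3, 5], [5, 7]]
        assert fisher_exact(t2) == pytest.approx(
            fisher_exact(np.array(t2), exact_rxc=True), abs=1e-9
        )


class TestMannWhitney:
    def test_two_vs_two_enumeration(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        vals = [1.0, 2.0, 5.5]
        _, p = mann_whitney_u(vals, vals)
        assert p == 1.0

    def test_label_symmetry(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=6)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(y, x)
        assert p1 == pytest.approx(p2)

    def test_tied_data_matches_permutation_oracle(self, rng):
        x = np.round(rng.normal(size=15), 1)
        y = np.round(rng.normal(0.6, 1, size=12), 1)
        _, p = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        obs = ranks[:15].sum()
        mean = ranks.sum() * 15 / 27
        count = 0
        n_perm = 20000
        prng = np.random.default_rng(0)
        for _ in range(n_perm):
            perm = prng.permutation(ranks)
            if abs(perm[:15].sum() - mean) >= abs(obs - mean) - 1e-9:
                count += 1
        assert p == pytest.approx(count / n_perm, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])


class TestBaselineTable:
    def _table(self):
        ids = [f"S{i:02d}" for i in range(1, 21)]
        group = pd.Series(["NoDecline"] * 12 + ["Decline"] * 8, index=ids)
        rng = np.random.default_rng(4)
        cov = pd.DataFrame(
            {
                "age": rng.normal(77, 5, 20).round(1),
                "diabetes": [True] * 2 + [False] * 10 + [True] + [False] * 7,
                "education": (["primary"] * 5 + ["secondary"] * 6 +
                              ["high school"] * 3 + ["university"] * 6),
                "spbb": rng.normal(10, 1.5, 20).round(0),
            },
            index=pd.Index(ids),
        )
        cov.loc["S03", "spbb"] = np.nan
        return SampleTable(ids, group=group, covariates=cov)

    def test_layout_and_missing_value_accounting(self):
        df = baseline_table(self._table())
        assert list(df.columns[:3]) == ["covariate", "N", "overall"]
        assert set(df["covariate"]) == {"age", "diabetes", "education", "spbb"}
        assert int(df.set_index("covariate").loc["spbb", "N"]) == 19
        assert int(df.set_index("covariate").loc["age", "N"]) == 20

    def test_binary_covariate_matches_direct_fisher(self):
        df = baseline_table(self._table()).set_index("covariate")
        # diabetes counts: 2/12 no-decline, 1/8 decline
        assert df.loc["diabetes", "p_value"] == pytest.approx(
            fisher_exact([[2, 10], [1, 7]])
        )
        assert df.loc["diabetes", "p_value"] == pytest.approx(1.000, abs=5e-4)

    def test_single_level_covariate_skipped_with_note(self):
        t = self._table()
        t.covariates["cohort"] = "MAPT"
        df = baseline_table(t).set_index("covariate")
        assert np.isnan(df.loc["cohort", "p_value"])
        assert "skipped" in df.loc["cohort", "note"]

    def test_group_labels_required(self):
        t = self._table()
        t.group = None
        with pytest.raises(DataError):
            baseline_table(t)
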