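"""ICC(A,1), Cronbach alpha, McDonald omega: oracles and recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qole.reliability import (corrected_summary_correlations, cronbach_alpha,
                              icc_a1, internal_consistency_table,
                              mcdonald_omega)
from qole.scoring import DOMAINS


def icc_a1_oracle(x):
    """Two-way ANOVA by definition: sums of squares from first principles."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))


class TestIccA1:
    def test_identical_columns_give_one(self):
        m = np.array([[1.0, 1.0], [4.0, 4.0], [9.0, 9.0]])
        icc, dec = icc_a1(m)
        assert icc == pytest.approx(1.0)
        assert dec.ms_error == pytest.approx(0.0)

    def test_small_matrix_matches_oracle(self):
        m = np.array([[1, 2], [3, 3], [5, 6], [7, 7]], dtype=float)
        icc, _ = icc_a1(m)
        assert icc == pytest.approx(icc_a1_oracle(m), abs=1e-10)

    def test_column_swap_invariance(self):
        m = np.array([[1, 2], [3, 3], [5, 6], [7, 7]], dtype=float)
        assert icc_a1(m)[0] == pytest.approx(icc_a1(m[:, ::-1])[0], abs=1e-12)

    def test_oracle_on_100_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            k = int(rng.integers(2, 5))
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            assert icc_a1(m)[0] == pytest.approx(icc_a1_oracle(m), abs=1e-10)

    def test_matches_pingouin(self, rng):
        """Cross-check against an independent ICC implementation (ICC2 =
        single-rater absolute agreement)."""
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "y": m.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="y").set_index("Type")
        assert icc_a1(m)[0] == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-6)

    def test_constant_matrix_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            icc, _ = icc_a1(np.full((4, 2), 7.0))
        assert np.isnan(icc)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc_a1(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            icc_a1(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


class TestCronbachAlpha:
    def test_equicorrelated_closed_form(self, rng):
        """Three items with pairwise correlation 0.5 give standardized 0.75."""
        f = rng.normal(size=20000)
        x = np.column_stack([f + rng.normal(size=f.size, scale=1.0)
                             for _ in range(3)])
        # construct exact correlation instead: use the closed form on a
        # population matrix via the internal helper path
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        from qole.reliability import _standardized_alpha
        assert _standardized_alpha(corr) == pytest.approx(0.75)
        res = cronbach_alpha(x)
        assert res.alpha_standardized == pytest.approx(0.75, abs=0.02)

    def test_duplicated_item_gives_one(self):
        col = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        res = cronbach_alpha(np.column_stack([col, col, col]))
        assert res.alpha_raw == pytest.approx(1.0)
        assert res.alpha_standardized == pytest.approx(1.0)

    def test_if_deleted_matches_subset_recompute(self, rng):
        x = rng.normal(size=(20, 4)) + rng.normal(size=(20, 1))
        res = cronbach_alpha(pd.DataFrame(x, columns=list("abcd")))
        for col in "abcd":
            rest = [c for c in "abcd" if c != col]
            sub = cronbach_alpha(pd.DataFrame(x, columns=list("abcd"))[rest])
            assert res.alpha_if_deleted[col] == pytest.approx(
                sub.alpha_standardized, abs=1e-12)

    def test_raw_equals_standardized_for_equal_variances(self, rng):
        x = rng.normal(size=(200, 5)) + rng.normal(size=(200, 1))
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        res = cronbach_alpha(z)
        assert res.alpha_raw == pytest.approx(res.alpha_standardized, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = pd.DataFrame(rng.normal(size=(50, 4)) + rng.normal(size=(50, 1)))
        ref = pingouin.cronbach_alpha(data=x)[0]
        assert cronbach_alpha(x).alpha_raw == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_item_warns(self):
        x = np.column_stack([np.arange(5.0), np.ones(5), np.arange(5.0) * 2])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cronbach_alpha(x)
        assert res.dropped_items == ["1"]


class TestMcdonaldOmega:
    def test_closed_form_on_exact_matrix(self):
        lam = np.array([0.8, 0.8, 0.8])
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        res = mcdonald_omega(None, corr=corr)
        assert res.omega == pytest.approx(5.76 / 6.84, abs=1e-6)
        assert not res.heywood

    def test_tau_equivalence_coincides_with_alpha(self, rng):
        lam = np.array([0.7] * 4)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        from qole.reliability import _standardized_alpha
        res = mcdonald_omega(None, corr=corr)
        assert res.omega == pytest.approx(_standardized_alpha(corr), abs=1e-6)

    def test_parameter_recovery_at_n5000(self, rng):
        lam = np.array([0.9, 0.7, 0.5, 0.6])
        truth = lam.sum() ** 2 / (lam.sum() ** 2 + (1 - lam ** 2).sum())
        f = rng.normal(size=5000)
        x = lam * f[:, None] + np.sqrt(1 - lam ** 2) * rng.normal(size=(5000, 4))
        res = mcdonald_omega(x)
        assert res.omega == pytest.approx(truth, abs=0.03)

    def test_heywood_clipping(self):
        # two near-duplicate items force |loading| -> 1
        corr = np.array([[1.0, 0.99, 0.3], [0.99, 1.0, 0.3], [0.3, 0.3, 1.0]])
        res = mcdonald_omega(None, corr=corr)
        assert (res.uniquenesses >= 0).all()
        assert 0 <= res.omega <= 1

    def test_needs_three_items(self, rng):
        with pytest.raises(ValueError):
            mcdonald_omega(rng.normal(size=(30, 2)))


class TestPanelHelpers:
    def test_corrected_summary_excludes_domain(self, panel, schema):
        from qole.reliability import corrected_summary_score
        base = panel[panel["visit"] == "baseline"]
        corr_gen = corrected_summary_score(base, schema, "GEN", "SEX")
        manual = base[["FIS", "FUN", "SOC", "FAT"]].mean(axis=1).where(
            base[["FIS", "FUN", "SOC", "FAT"]].notna().all(axis=1))
        pd.testing.assert_series_equal(corr_gen, manual, check_names=False)

    def test_toi_pairs_skip_non_constituents(self, panel, schema):
        table = corrected_summary_correlations(panel, schema)
        toi = table[table["summary"] == "TOI"]
        assert set(toi["domain"]) == {"FIS", "FUN", "MDSS"}

    def test_rank_identical_domain_gives_r1(self, schema):
        idx = [f"p{i}" for i in range(30)]
        vals = np.linspace(10, 90, 30)
        panel = pd.DataFrame({
            "patient_id": idx, "visit": "baseline",
            "FIS": vals, "FUN": vals, "SOC": vals, "SEX": vals,
            "FAT": vals, "MDSS": vals, "GEN": vals, "ALL": vals, "TOI": vals,
        })
        table = corrected_summary_correlations(panel, schema).set_index(
            ["domain", "summary"])
        assert table.loc[("FIS", "GEN"), "r"] == pytest.approx(1.0)

    def test_internal_consistency_on_cohort(self, cohort, schema, panel):
        table = internal_consistency_table(cohort, schema, panel).set_index("score")
        for d in DOMAINS:
            assert 0.5 < table.loc[d, "alpha_standardized"] <= 1.0
            if d != "SOC":  # two-item domain: single-factor omega unidentified
                assert 0.5 < table.loc[d, "omega"] <= 1.0
        assert np.isnan(table.loc["SOC", "omega"])
        assert {"GEN", "ALL", "TOI"} <= set(table.index)
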