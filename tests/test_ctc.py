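"""ΔCq preprocessing, positivity calling, cohort tables, Fisher, ΔΔCT."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rai2ctbp import ctc, synthetic


def _ref(mean=8.0, sd=1.5, gmax=12.0, gene="AR"):
    return {
        gene: ctc.HealthyReference(
            gene=gene, mean_dcq=mean, sd_dcq=sd, max_dcq=gmax, n_donors=10
        )
    }


def _samples(rows):
    df = pd.DataFrame(rows)
    for col in ("missing_flag", "imputed_flag", "censored_flag"):
        if col not in df:
            df[col] = False
    df.loc[df["dcq"].isna(), "missing_flag"] = True
    return df


class TestPreprocess:
    def test_missing_replaced_by_gene_max_plus_two(self):
        df = _samples(
            [{"sample_id": "s1", "cohort": "C", "gene": "AR", "dcq": np.nan}]
        )
        out = ctc.preprocess_dcq(df, _ref(gmax=12.0))
        assert out.loc[0, "dcq"] == 14.0
        assert out.loc[0, "imputed_flag"]
        assert not out.loc[0, "censored_flag"]

    def test_above_mean_plus_sd_censored(self):
        df = _samples(
            [{"sample_id": "s1", "cohort": "C", "gene": "AR", "dcq": 9.6}]
        )
        out = ctc.preprocess_dcq(df, _ref(mean=8.0, sd=1.5, gmax=12.0))
        assert out.loc[0, "dcq"] == 14.0
        assert out.loc[0, "censored_flag"]

    def test_exactly_at_threshold_unchanged(self):
        df = _samples(
            [{"sample_id": "s1", "cohort": "C", "gene": "AR", "dcq": 9.5}]
        )
        out = ctc.preprocess_dcq(df, _ref(mean=8.0, sd=1.5))
        assert out.loc[0, "dcq"] == 9.5
        assert not out.loc[0, "censored_flag"]

    def test_idempotent(self):
        df = _samples(
            [
                {"sample_id": "s1", "cohort": "C", "gene": "AR", "dcq": np.nan},
                {"sample_id": "s2", "cohort": "C", "gene": "AR", "dcq": 11.0},
                {"sample_id": "s3", "cohort": "C", "gene": "AR", "dcq": 7.0},
            ]
        )
        once = ctc.preprocess_dcq(df, _ref())
        twice = ctc.preprocess_dcq(once, _ref())
        pd.testing.assert_frame_equal(once, twice)

    def test_gene_without_reference_raises(self):
        df = _samples(
            [{"sample_id": "s1", "cohort": "C", "gene": "KRT19", "dcq": 5.0}]
        )
        with pytest.raises(KeyError, match="KRT19"):
            ctc.preprocess_dcq(df, _ref(gene="AR"))


class TestPositivityAndStatus:
    @pytest.mark.parametrize(
        "dcq,expected",
        [(7.9, True), (8.0, False), (14.0, False)],
        ids=["below-mean", "at-mean-strict", "imputed-sentinel"],
    )
    def test_strict_threshold(self, dcq, expected):
        df = _samples(
            [
                {"sample_id": "s1", "cohort": "C", "gene": "AR", "dcq": dcq},
                {"sample_id": "s1", "cohort": "C", "gene": "KRT19", "dcq": 20.0},
            ]
        )
        refs = {**_ref(), **_ref(mean=9.0, gene="KRT19")}
        pos = ctc.call_gene_positivity(df, refs)
        assert bool(pos.loc[0, "AR"]) is expected

    @pytest.mark.parametrize(
        "ar,krt,rai2,expected",
        [
            (True, False, False, True),
            (False, False, True, False),
            (True, True, False, True),
            (False, False, False, False),
        ],
    )
    def test_ctc_or_rule(self, ar, krt, rai2, expected):
        pos = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "cohort": ["C"],
                "AR": [ar],
                "KRT19": [krt],
                "RAI2": [rai2],
            }
        )
        out = ctc.call_ctc_status(pos)
        assert bool(out.loc[0, "ctc_positive"]) is expected
        assert bool(out.loc[0, "RAI2"]) is rai2  # carried through untouched

    def test_missing_marker_column_raises(self):
        pos = pd.DataFrame({"sample_id": ["s1"], "cohort": ["C"], "AR": [True]})
        with pytest.raises(KeyError, match="KRT19"):
            ctc.call_ctc_status(pos)


class TestCohortFrequency:
    @staticmethod
    def _statuses(cohort, n_pos, n_total, rai2_pos=0):
        rows = []
        for i in range(n_total):
            ctc_pos = i < n_pos
            rows.append(
                {
                    "sample_id": f"{cohort}-{i}",
                    "cohort": cohort,
                    "AR": ctc_pos,
                    "KRT19": False,
                    "RAI2": ctc_pos and i < rai2_pos,
                    "ctc_positive": ctc_pos,
                }
            )
        return pd.DataFrame(rows)

    def test_printed_crpc_rate(self):
        tbl = ctc.cohort_frequency_table(self._statuses("CRPC", 19, 27))
        assert tbl.iloc[0]["percent"] == 70

    def test_printed_avpc_rate(self):
        tbl = ctc.cohort_frequency_table(self._statuses("AVPC", 52, 57))
        assert tbl.iloc[0]["percent"] == 91

    def test_zero_events(self):
        tbl = ctc.cohort_frequency_table(self._statuses("HSPC", 0, 15))
        assert tbl.iloc[0]["n_event"] == 0
        assert tbl.iloc[0]["percent"] == 0

    def test_rai2_uses_ctc_positive_denominator(self):
        st = self._statuses("CRPC", 19, 27, rai2_pos=17)
        tbl = ctc.cohort_frequency_table(st, event="RAI2", denominator="ctc_positive")
        assert tbl.iloc[0]["n_total"] == 19
        assert tbl.iloc[0]["n_event"] == 17
        assert tbl.iloc[0]["percent"] == 89  # the reported CRPC RAI2 rate

    def test_invariant_under_reordering(self):
        st = self._statuses("CRPC", 19, 27)
        shuffled = st.sample(frac=1.0, random_state=0)
        a = ctc.cohort_frequency_table(st)
        b = ctc.cohort_frequency_table(shuffled)
        pd.testing.assert_frame_equal(a, b)


def _fisher_enumeration_oracle(table):
    """Independent brute-force two-sided Fisher p via exact rational pmf."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert ctc.fisher_exact([[1, 1], [1, 1]]).p_two_sided == pytest.approx(1.0)

    def test_diagonal_five(self):
        res = ctc.fisher_exact([[5, 0], [0, 5]])
        assert res.p_two_sided == pytest.approx(2 / 252, rel=1e-9)

    def test_printed_cohort_table_matches_enumeration(self):
        table = [[19, 8], [52, 5]]
        res = ctc.fisher_exact(table)
        assert res.p_two_sided == pytest.approx(
            _fisher_enumeration_oracle(table), rel=1e-9
        )

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum() == 0:
                continue
            ours = ctc.fisher_exact(t).p_two_sided
            theirs = sps.fisher_exact(t)[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)

    def test_all_small_margin_tables_match_oracle(self):
        # exhaustive over all 2x2 tables with every entry <= 5 (margins <= 10)
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d == 0:
                continue
            ours = ctc.fisher_exact([[a, b], [c, d]]).p_two_sided
            oracle = _fisher_enumeration_oracle([[a, b], [c, d]])
            assert ours == pytest.approx(oracle, rel=1e-7), (a, b, c, d)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            ctc.fisher_exact([[1, -1], [0, 2]])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ctc.fisher_exact([[0, 0], [0, 0]])


class TestDdct:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((20, 15, 22, 17), 1.0),  # ΔΔCT = 0
            ((20, 15, 22, 16), 2.0),  # ΔΔCT = -1
            ((24, 18, 26, 18), 4.0),  # ΔΔCT = -2
        ],
    )
    def test_fold_changes(self, args, expected):
        assert ctc.ddct_fold_change(*args) == pytest.approx(expected)


class TestPipelineRecovery:
    def test_noise_free_calls_equal_ground_truth(self, qpcr_noise_free):
        ds, _ = qpcr_noise_free
        refs = ctc.healthy_reference(ds.healthy, observed=ds.samples)
        pre = ctc.preprocess_dcq(ds, refs)
        pos = ctc.call_gene_positivity(pre, refs)
        called = pos.melt(
            id_vars=["sample_id", "cohort"], var_name="gene", value_name="called"
        )
        merged = called.merge(ds.truth, on=["sample_id", "cohort", "gene"])
        assert (merged["called"] == merged["true_positive"]).all()
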