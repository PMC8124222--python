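import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from rrbsdmf.diffmeth import (
    BOTH_HYPER,
    BOTH_HYPO,
    DISCORDANT,
    HYPER,
    HYPO,
    call_dmfs,
    concordance_summary,
    fisher_exact_margin_family,
    fisher_exact_two_sided,
    intersect_common,
)
from rrbsdmf.methylation import FRAGMENT_COLUMNS

from oracles import fisher_enumeration, fisher_enumeration_family


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((10, 0, 0, 10), 2 / 184756),
            ((3, 1, 1, 3), 34 / 70),
        ],
    )
    def test_enumeration_examples(self, table, expected):
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("table", [(5, 5, 0, 0), (0, 3, 0, 7), (4, 0, 6, 0)])
    def test_degenerate_margin_is_one(self, table):
        assert fisher_exact_two_sided(*table) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_matches_integer_enumeration_oracle(self, table):
        expected = fisher_enumeration(*table)
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_cross_check_against_scipy(self, table):
        """Independent library cross-check; scipy uses exact tie comparison,
        so agreement is asserted at the tie tolerance scale."""
        ours = fisher_exact_two_sided(*table)
        theirs = scipy.stats.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
        assert ours == pytest.approx(min(theirs, 1.0), rel=1e-6, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_symmetries(self, table):
        m1, u1, m2, u2 = table
        p = fisher_exact_two_sided(m1, u1, m2, u2)
        assert 0 < p <= 1
        assert fisher_exact_two_sided(m2, u2, m1, u1) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_two_sided(u1, m1, u2, m2) == pytest.approx(p, rel=1e-12)

    def test_margin_family_agrees_with_scalar(self):
        r1, r2, c1 = 17, 23, 12
        family = fisher_exact_margin_family(r1, r2, c1)
        k_min = max(0, c1 - r2)
        for j, p in enumerate(family):
            k = k_min + j
            assert fisher_exact_two_sided(k, r1 - k, c1 - k, r2 - (c1 - k)) == p
        expected = fisher_enumeration_family(r1, r2, c1)
        np.testing.assert_allclose(family, expected, rtol=1e-10)


def frag_table(rows):
    """rows: (fragment_id, contig, start, end, M, U, passes)"""
    records = []
    for fid, contig, start, end, m, u, passes in rows:
        total = m + u
        records.append(
            (fid, contig, start, end, 2, 2 if passes else 0, m, u, m / total, passes)
        )
    return pd.DataFrame(records, columns=FRAGMENT_COLUMNS)


class TestCallDmfs:
    def test_identical_counts_not_significant(self):
        a = frag_table([("c:0-100", "c", 0, 100, 30, 30, True)])
        b = frag_table([("c:0-100", "c", 0, 100, 30, 30, True)])
        out = call_dmfs(a, b)
        assert out.iloc[0]["p_value"] == 1.0 and not out.iloc[0]["significant"]

    def test_large_difference_significant_with_direction(self):
        a = frag_table([("c:0-100", "c", 0, 100, 70, 30, True)])
        b = frag_table([("c:0-100", "c", 0, 100, 40, 60, True)])
        out = call_dmfs(a, b)
        row = out.iloc[0]
        assert row["n_tests"] == 1
        assert row["diff"] == pytest.approx(-0.30)
        assert row["p_value"] == pytest.approx(fisher_enumeration(70, 30, 40, 60), rel=1e-10)
        assert bool(row["significant"]) and row["direction"] == HYPO

    def test_bonferroni_threshold_arithmetic(self):
        rows_a, rows_b = [], []
        for i in range(100):
            fid = f"c:{i * 200}-{i * 200 + 100}"
            rows_a.append((fid, "c", i * 200, i * 200 + 100, 20, 20, True))
            rows_b.append((fid, "c", i * 200, i * 200 + 100, 20, 20, True))
        out = call_dmfs(frag_table(rows_a), frag_table(rows_b), alpha=0.01)
        assert (out["n_tests"] == 100).all()
        assert out["p_threshold"].iloc[0] == pytest.approx(1e-4)

    def test_family_excludes_fragments_failing_either_sample(self):
        a = frag_table(
            [("c:0-100", "c", 0, 100, 70, 30, True), ("c:200-300", "c", 200, 300, 5, 5, True)]
        )
        b = frag_table(
            [("c:0-100", "c", 0, 100, 10, 90, True), ("c:200-300", "c", 200, 300, 5, 5, False)]
        )
        out = call_dmfs(a, b)
        assert list(out["fragment_id"]) == ["c:0-100"] and out.iloc[0]["n_tests"] == 1

    def test_empty_test_set_warns(self):
        a = frag_table([("c:0-100", "c", 0, 100, 5, 5, False)])
        b = frag_table([("c:0-100", "c", 0, 100, 5, 5, False)])
        with pytest.warns(UserWarning):
            out = call_dmfs(a, b)
        assert out.empty

    def test_label_swap_negates_diff_and_flips_direction(self):
        a = frag_table([("c:0-100", "c", 0, 100, 80, 20, True)])
        b = frag_table([("c:0-100", "c", 0, 100, 30, 70, True)])
        fwd = call_dmfs(a, b).iloc[0]
        rev = call_dmfs(b, a).iloc[0]
        assert fwd["diff"] == pytest.approx(-rev["diff"])
        assert fwd["p_value"] == rev["p_value"]
        assert {fwd["direction"], rev["direction"]} == {HYPER, HYPO}

    def test_shrinking_alpha_never_adds_dmfs(self):
        rng = np.random.default_rng(5)
        rows_a, rows_b = [], []
        for i in range(80):
            fid = f"c:{i * 200}-{i * 200 + 100}"
            ma, mb = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            rows_a.append((fid, "c", i * 200, i * 200 + 100, ma, 60 - ma, True))
            rows_b.append((fid, "c", i * 200, i * 200 + 100, mb, 60 - mb, True))
        a, b = frag_table(rows_a), frag_table(rows_b)
        sets = []
        for alpha in (0.2, 0.05, 0.01, 0.001):
            out = call_dmfs(a, b, alpha=alpha)
            sets.append(set(out.loc[out["significant"], "fragment_id"]))
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger


def dmf_row(fid, start, direction, significant=True):
    return {
        "fragment_id": fid,
        "contig": "c",
        "start": start,
        "end": start + 100,
        "M1": 10, "U1": 10, "M2": 10, "U2": 10,
        "level1": 0.5, "level2": 0.5,
        "diff": 0.5 if direction == HYPER else -0.5,
        "p_value": 1e-8,
        "n_tests": 10,
        "p_threshold": 1e-3,
        "significant": significant,
        "direction": direction,
    }


class TestIntersectCommon:
    def test_disjoint_sets_empty(self):
        d1 = pd.DataFrame([dmf_row("c:0-100", 0, HYPER)])
        d2 = pd.DataFrame([dmf_row("c:200-300", 200, HYPER)])
        assert intersect_common(d1, d2).empty

    def test_shared_hyper_fragment(self):
        d1 = pd.DataFrame([dmf_row("c:0-100", 0, HYPER)])
        d2 = pd.DataFrame([dmf_row("c:0-100", 0, HYPER)])
        out = intersect_common(d1, d2)
        assert list(out["concordance"]) == [BOTH_HYPER]

    def test_discordant_and_symmetry(self):
        d1 = pd.DataFrame([dmf_row("c:0-100", 0, HYPER), dmf_row("c:200-300", 200, HYPO)])
        d2 = pd.DataFrame([dmf_row("c:0-100", 0, HYPO), dmf_row("c:200-300", 200, HYPO)])
        out12 = intersect_common(d1, d2)
        out21 = intersect_common(d2, d1)
        assert list(out12["concordance"]) == [DISCORDANT, BOTH_HYPO]
        assert list(out21["concordance"]) == list(out12["concordance"])

    def test_non_significant_rows_never_common(self):
        d1 = pd.DataFrame([dmf_row("c:0-100", 0, HYPER, significant=False)])
        d2 = pd.DataFrame([dmf_row("c:0-100", 0, HYPER)])
        assert intersect_common(d1, d2).empty


class TestConcordanceSummary:
    def test_published_partition_arithmetic(self):
        summary = concordance_summary((737, 1, 45))
        assert summary["both_hyper"]["percent"] == 94.1
        assert summary["discordant"]["percent"] == 5.7
        assert summary["both_hypo"]["percent"] == 0.1
        assert summary["total"]["count"] == 783

    def test_all_one_class(self):
        summary = concordance_summary((10, 0, 0))
        assert summary["both_hyper"]["percent"] == 100.0
        assert summary["both_hypo"]["percent"] == 0.0

    def test_thirds_round_to_one_decimal(self):
        summary = concordance_summary((1, 1, 1))
        assert all(summary[k]["percent"] == 33.3 for k in (BOTH_HYPER, BOTH_HYPO, DISCORDANT))

    def test_half_up_rounding(self):
        # 1/16 = 6.25% rounds half-up to 6.3 (banker's rounding would give 6.2)
        summary = concordance_summary((1, 15, 0))
        assert summary["both_hyper"]["percent"] == 6.3

    def test_empty_input_all_zero(self):
        summary = concordance_summary((0, 0, 0))
        assert summary["total"]["count"] == 0
        assert summary["both_hyper"]["percent"] == 0.0

    def test_counts_from_dataframe(self):
        frame = pd.DataFrame({"concordance": [BOTH_HYPER, BOTH_HYPER, DISCORDANT]})
        summary = concordance_summary(frame)
        assert summary["both_hyper"]["count"] == 2
        assert summary["discordant"]["percent"] == 33.3
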