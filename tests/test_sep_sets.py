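import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import TIMES7, make_sep, standardized
from sepkit.sep_sets import (
    SEPQuery,
    SEPSet,
    analyze_2_seps,
    distances_between_within,
    get_sep,
    peak_matrix,
    sep_set_summary,
)
from sepkit.sep_sets import PeakMatrix


def random_set(label, k, seed, n_times=7):
    rng = np.random.default_rng(seed)
    times = tuple(range(0, 10 * n_times, 10))
    members = [
        make_sep(f"{label}{i}", "AA", "D", "S" * (n_times - 1),
                 standardized(rng.uniform(0, 10, n_times)), times)
        for i in range(k)
    ]
    return SEPSet(label, members)


class TestGetSep:
    def test_empty_query_returns_full_store(self, sep_store):
        out = get_sep(sep_store, SEPQuery())
        assert out.k == len(sep_store)

    def test_descr_substring_is_case_sensitive(self, sep_store, annot5):
        out = get_sep(sep_store, SEPQuery(descr="kinase"), annot=annot5)
        assert {s.gene_id for s in out.members} == {"g1", "g3"}
        none = get_sep(sep_store, SEPQuery(descr="KINASE"), annot=annot5)
        assert none.k == 0

    def test_conjunction_of_criteria(self, sep_store, annot5):
        out = get_sep(
            sep_store,
            SEPQuery(descr="MYB", acc_key="AA", is_tf=True),
            annot=annot5,
        )
        assert {s.gene_id for s in out.members} == {"g2", "g5"}
        assert all(s.acc_key == "AA" for s in out.members)

    def test_time_max_exp_filter(self, sep_store):
        out = get_sep(sep_store, SEPQuery(time_max_exp=0.0, acc_key="AA"))
        assert {s.gene_id for s in out.members} == {"g2"}

    def test_model_wildcard(self, sep_store):
        out = get_sep(sep_store, SEPQuery(model=".SSSSS", acc_key="AA"))
        assert {s.gene_id for s in out.members} == {"g1", "g2"}

    def test_exist_in_all(self, sep_store):
        extra = make_sep("only_aa", "AA", "D", "SSSSSI", standardized(range(7)))
        out = get_sep(sep_store + [extra], SEPQuery(exist_in_all=True))
        assert "only_aa" not in {s.gene_id for s in out.members}

    def test_empty_result_warns(self, sep_store):
        with pytest.warns(UserWarning, match="no SEPs"):
            get_sep(sep_store, SEPQuery(acc_key="ZZ"))


class TestSummary:
    def test_identical_members_zero_width_ci(self):
        v = standardized([1, 2, 3, 4, 5, 6, 7])
        s = SEPSet("x", [make_sep(f"g{i}", "AA", "D", "SSSSSI", v) for i in range(3)])
        summ = sep_set_summary(s, alpha=0.05)
        assert summ["ci_low"].to_numpy() == pytest.approx(summ["ci_high"].to_numpy())

    def test_student_t_interval_hand_check(self):
        # k=4 values (-1, 0, 0, 1) at each time: mean 0, sd sqrt(2/3)
        base = np.array([-1.0, 0.0, 0.0, 1.0])
        times = (0.0, 10.0, 20.0)
        members = [
            make_sep(f"g{i}", "AA", "D", "SS", np.full(3, b), times)
            for i, b in enumerate(base)
        ]
        summ = sep_set_summary(SEPSet("x", members), alpha=0.05)
        half = stats.t.ppf(0.975, 3) * base.std(ddof=1) / 2.0
        assert summ["ci_high"].to_numpy() == pytest.approx(np.full(3, half), abs=1e-10)

    def test_smaller_alpha_widens_interval(self):
        s = random_set("a", 5, seed=1)
        w95 = sep_set_summary(s, alpha=0.05)
        w9999 = sep_set_summary(s, alpha=1e-4)
        width95 = (w95["ci_high"] - w95["ci_low"]).to_numpy()
        width9999 = (w9999["ci_high"] - w9999["ci_low"]).to_numpy()
        assert (width9999 > width95).all()

    def test_singleton_set_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sep_set_summary(random_set("a", 1, seed=2))


TABLE3_ROWS = [
    (2, 2, 4, 2, 6),
    (2, 5, 10, 11, 21),
    (2, 10, 20, 46, 66),
    (5, 2, 10, 11, 21),
    (5, 5, 25, 20, 45),
    (5, 10, 50, 55, 105),
    (10, 2, 20, 46, 66),
    (10, 5, 50, 55, 105),
    (10, 10, 100, 90, 190),
    (15, 15, 225, 210, 435),
]


class TestDistances:
    @pytest.mark.parametrize("k,r,n_b,n_w,total", TABLE3_ROWS)
    def test_published_vector_lengths(self, k, r, n_b, n_w, total):
        d = distances_between_within(random_set("a", k, 1), random_set("b", r, 2))
        assert d.d_between.size == n_b
        assert d.d_within.size == n_w
        assert d.d_between.size + d.d_within.size == total

    def test_lengths_match_pair_enumeration_for_all_small_sizes(self):
        for k, r in itertools.product(range(2, 16), repeat=2):
            d = distances_between_within(random_set("a", k, k), random_set("b", r, r))
            cross = len(list(itertools.product(range(k), range(r))))
            within = len(list(itertools.combinations(range(k), 2))) + len(
                list(itertools.combinations(range(r), 2))
            )
            assert d.d_between.size == cross
            assert d.d_within.size == within

    def test_three_four_five(self):
        times = tuple(range(0, 70, 10))
        x = make_sep("x", "AA", "D", "SSSSSS", np.zeros(7), times)
        y = make_sep("y", "AA", "D", "SSSSSS", np.array([3, 0, 0, 0, 0, 0, 4.0]), times)
        a = SEPSet("a", [x, x])
        b = SEPSet("b", [y, y])
        d = distances_between_within(a, b)
        assert d.d_between == pytest.approx([5.0] * 4)
        assert d.d_within == pytest.approx([0.0, 0.0])

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x, y, z = rng.normal(size=(3, 7))
            dxy = np.sqrt(((x - y) ** 2).sum())
            dyx = np.sqrt(((y - x) ** 2).sum())
            dxz = np.sqrt(((x - z) ** 2).sum())
            dzy = np.sqrt(((z - y) ** 2).sum())
            assert dxy == pytest.approx(dyx, abs=1e-12)
            assert dxy <= dxz + dzy + 1e-12

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="time grids"):
            distances_between_within(random_set("a", 3, 1), random_set("b", 3, 2, n_times=5))


class TestAnalyze2Seps:
    def test_size_constraint(self):
        with pytest.raises(ValueError, match="larger than two"):
            analyze_2_seps(random_set("a", 2, 1), random_set("b", 5, 2))
        with pytest.raises(ValueError, match="larger than two"):
            analyze_2_seps(random_set("a", 5, 1), random_set("b", 2, 2))

    def test_symmetric_in_set_order(self):
        a, b = random_set("a", 6, 10), random_set("b", 8, 11)
        r1 = analyze_2_seps(a, b)
        r2 = analyze_2_seps(b, a)
        assert r1.t_statistic == r2.t_statistic
        assert r1.p_value == r2.p_value

    def test_welch_statistic_matches_textbook_formula(self):
        a, b = random_set("a", 5, 20, n_times=3), random_set("b", 5, 21, n_times=3)
        res = analyze_2_seps(a, b)
        d = distances_between_within(a, b)
        x, y = d.d_between, d.d_within
        se2 = x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (x.var(ddof=1) / x.size) ** 2 / (x.size - 1)
            + (y.var(ddof=1) / y.size) ** 2 / (y.size - 1)
        )
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-8)
        assert res.p_value == pytest.approx(float(stats.t.sf(t, df)), abs=1e-10)

    def test_one_tailed_orientation(self):
        a, b = random_set("a", 6, 30), random_set("b", 6, 31)
        res = analyze_2_seps(a, b)
        assert (res.p_value < 0.5) == (res.mean_d_between > res.mean_d_within)

    def test_wilcoxon_corroboration_available(self):
        res = analyze_2_seps(random_set("a", 5, 1), random_set("b", 5, 2), with_wilcoxon=True)
        assert 0.0 <= res.wilcoxon_p <= 1.0


class TestPeakMatrix:
    def test_cell_count_and_percentage_sum(self, sep_store):
        pm = peak_matrix(sep_store, "AA", "BB")
        assert pm.counts.size == 49
        assert pm.percentages.to_numpy().sum() == pytest.approx(100.0, abs=1e-9)
        assert pm.counts.to_numpy().sum() == pm.total_genes

    def test_hand_tabulation(self):
        times = tuple(range(0, 70, 10))

        def peaked_at(gene, acc, t):
            v = np.full(7, -1.0)
            v[times.index(t)] = 6.0
            return make_sep(gene, acc, "D", "SSSSSI", standardized(v), times)

        store = []
        for gene, (ta, tb) in {
            "g1": (0, 0), "g2": (0, 0), "g3": (10, 60), "g4": (60, 60)
        }.items():
            store += [peaked_at(gene, "AA", ta), peaked_at(gene, "BB", tb)]
        pm = peak_matrix(store, "AA", "BB")
        pct = pm.percentages
        assert pct.loc[0, 0] == pytest.approx(50.0)
        assert pct.loc[10, 60] == pytest.approx(25.0)
        assert pct.loc[60, 60] == pytest.approx(25.0)
        assert pm.gene_sets[(0.0, 0.0)] == ["g1", "g2"]
        assert pm.cell_label(0, 60) == "AAm0_BBm60"

    def test_no_shared_genes_rejected(self):
        a = [make_sep("g1", "AA", "D", "SSSSSS", np.zeros(7))]
        with pytest.raises(ValueError, match="shared"):
            peak_matrix(a, "AA", "BB")

    def test_percent_of_rounds_to_printed_precision(self):
        assert PeakMatrix.percent_of(3672, 24720) == 14.85
        assert PeakMatrix.percent_of(758, 24720) == 3.07
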