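import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from conftest import make_count_matrix
from sepkit.data_model import Design
from sepkit.interval_tests import (
    bh_adjust,
    estimate_common_dispersion,
    nb_exact_test,
)
from sepkit.interval_tests import test_neighbor_intervals as run_interval_tests

EQ = np.full(2, 1e6)


def enumeration_oracle(counts_a, counts_b, phi, mu=3.7):
    """Brute-force conditional p-value: enumerate every split of the total.

    Uses raw NB masses for the group sums at an arbitrary mean (the mean
    cancels in the conditional law), entirely independent of the
    implementation's log-space negative-hypergeometric route.
    """
    n_a, n_b = len(counts_a), len(counts_b)
    A, T = int(sum(counts_a)), int(sum(counts_a) + sum(counts_b))
    if phi == 0:
        w = np.array([binom.pmf(a, T, n_a / (n_a + n_b)) for a in range(T + 1)])
    else:
        r_a, r_b = n_a / phi, n_b / phi
        w = np.array(
            [
                nbinom.pmf(a, r_a, r_a / (r_a + n_a * mu))
                * nbinom.pmf(T - a, r_b, r_b / (r_b + n_b * mu))
                for a in range(T + 1)
            ]
        )
        w = w / w.sum()
    return float(w[w <= w[A] * (1 + 1e-9)].sum())


class TestNbExactTest:
    def test_observed_mode_gives_p_one(self):
        assert nb_exact_test([10, 10], [10, 10], EQ, EQ, 0.3) == 1.0

    def test_poisson_limit_matches_binomial_tails(self):
        p = nb_exact_test([0, 0], [10, 10], EQ, EQ, 0.0)
        oracle = binom.pmf(0, 20, 0.5) + binom.pmf(20, 20, 0.5)
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_single_replicate_enumeration_oracle(self):
        p = nb_exact_test([5], [20], EQ[:1], EQ[:1], 0.1)
        assert p == pytest.approx(enumeration_oracle([5], [20], 0.1), abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.4])
    def test_matches_enumeration_small_totals(self, phi):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.integers(0, 13, size=2)
            b = rng.integers(0, 13, size=2)
            p = nb_exact_test(a, b, EQ, EQ, phi)
            assert p == pytest.approx(enumeration_oracle(a, b, phi), abs=1e-12)

    def test_poisson_agrees_with_conditional_binomial_exhaustively(self):
        # every split of every total up to 50, one library per side
        one = np.array([1e6])
        for T in range(1, 51):
            pmf = binom.pmf(np.arange(T + 1), T, 0.5)
            for A in range(T + 1):
                p = nb_exact_test([A], [T - A], one, one, 0.0)
                oracle = pmf[pmf <= pmf[A] * (1 + 1e-9)].sum()
                assert p == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.integers(0, 60, size=3)
            b = rng.integers(0, 60, size=2)
            sa, sb = rng.uniform(5e5, 2e6, 3), rng.uniform(5e5, 2e6, 2)
            assert nb_exact_test(a, b, sa, sb, 0.1) == pytest.approx(
                nb_exact_test(b, a, sb, sa, 0.1), abs=1e-12
            )

    def test_type_one_error_under_null(self):
        # 2000 genes, equal NB means, known dispersion: p < 0.05 near 5%
        rng = np.random.default_rng(2024)
        phi, mu, r = 0.1, 100.0, 10.0
        counts = rng.negative_binomial(r, r / (r + mu), size=(2000, 4))
        pvals = np.array(
            [nb_exact_test(c[:2], c[2:], EQ, EQ, phi) for c in counts]
        )
        frac = (pvals < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="negative"):
            nb_exact_test([-1, 2], [3, 4], EQ, EQ, 0.1)
        with pytest.raises(ValueError, match="positive"):
            nb_exact_test([1, 2], [3, 4], np.array([0.0, 1e6]), EQ, 0.1)


class TestDispersionEstimate:
    def test_poisson_counts_give_near_zero_phi(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, size=(200, 4))
        fit = estimate_common_dispersion(counts, ["a", "a", "b", "b"], np.full(4, 1e6))
        assert fit.common_dispersion < 0.02

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(2)
        mu, phi = 100.0, 0.2
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(500, 4))
        fit = estimate_common_dispersion(counts, ["a", "a", "b", "b"], np.full(4, 1e6))
        assert 0.12 <= fit.common_dispersion <= 0.30

    def test_all_singleton_groups_rejected(self):
        counts = np.array([[5, 9], [3, 2]])
        with pytest.raises(ValueError, match="without replication"):
            estimate_common_dispersion(counts, ["a", "b"], np.full(2, 1e6))


@pytest.fixture
def seven_time_cm():
    design = Design(
        times=tuple(range(0, 70, 10)),
        accessions=(("AA", "D", "a"),),
        replicates_per_point=2,
    )
    counts = {
        "g1": [50] * 14,
        "g2": [20, 22, 40, 38, 41, 39, 80, 82, 79, 81, 80, 78, 160, 158],
    }
    return make_count_matrix(design, counts)


class TestNeighborIntervals:
    def test_seven_times_give_six_intervals(self, seven_time_cm):
        table = run_interval_tests(seven_time_cm, "AA", phi=0.05)
        assert sorted(table["interval"].unique()) == [1, 2, 3, 4, 5, 6]
        assert len(table) == 2 * 6

    def test_constant_gene_has_unit_pvalues(self, seven_time_cm):
        table = run_interval_tests(seven_time_cm, "AA", phi=0.05)
        g1 = table[table["gene_id"] == "g1"]
        assert (g1["p_value"] == 1.0).all()
        assert (g1["q_value"] >= g1["p_value"] - 1e-15).all()

    def test_unknown_accession(self, seven_time_cm):
        with pytest.raises(KeyError, match="unknown accession"):
            run_interval_tests(seven_time_cm, "ZZ", phi=0.05)

    def test_external_pvalue_table_used(self, seven_time_cm):
        ext = pd.DataFrame(
            np.full((2, 6), 0.5), index=["g1", "g2"], columns=range(1, 7)
        )
        table = run_interval_tests(seven_time_cm, "AA", external_pvalues=ext)
        assert (table["p_value"] == 0.5).all()

    def test_incomplete_external_table_rejected(self, seven_time_cm):
        ext = pd.DataFrame(np.full((1, 6), 0.5), index=["g1"], columns=range(1, 7))
        with pytest.raises(ValueError, match="incomplete"):
            run_interval_tests(seven_time_cm, "AA", external_pvalues=ext)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_degenerate_zeros(self):
        assert (bh_adjust(np.zeros(5)) == 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust(np.array([0.5, 1.5]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert q == pytest.approx(q_sm, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_dominates_raw_p_and_is_monotone(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
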