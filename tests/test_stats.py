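"""Statistical kernels against independent enumeration oracles, the
adjacency combinatorial null, micro-homology scanning and group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ilrt.stats import (
    SitePosition,
    adjacency_pvalue,
    association_suite,
    chi_square_2x2,
    cluster_distribution,
    fisher_exact_2x2,
    housekeeping_classify,
    longest_common_substring,
    mann_whitney_u,
    microhomology_scan,
    positional_bias,
    spearman_rho,
)

# ---------------------------------------------------------------------------
# enumeration oracles


def hypergeom_pmf(a, row1, col1, total):
    """P(top-left cell = a) for fixed margins, by binomial coefficients."""
    return (math.comb(col1, a) * math.comb(total - col1, row1 - a)
            / math.comb(total, row1))


def fisher_doubling_oracle(table):
    (a, b), (c, d) = table
    total, row1, col1 = a + b + c + d, a + b, a + c
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    lower = sum(hypergeom_pmf(x, row1, col1, total) for x in range(lo, a + 1))
    upper = sum(hypergeom_pmf(x, row1, col1, total) for x in range(a, hi + 1))
    return min(1.0, 2.0 * min(lower, upper))


def mwu_exact_oracle(x, y):
    """Two-sided exact p by full enumeration of rank assignments."""
    pooled = sorted(x + y)
    n = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    m = len(y)
    mu = n * m / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# contingency kernels


class TestFisher:
    def test_balanced_table_has_no_association(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_agrees_with_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = rng.integers(0, 11, size=(2, 2)).tolist()
            if sum(map(sum, t)) == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_doubling_oracle(t), abs=1e-12)

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            (a, b), (c, d) = rng.integers(0, 40, size=(2, 2)).tolist()
            p1 = fisher_exact_2x2([[a, b], [c, d]])
            p2 = fisher_exact_2x2([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-9)
            assert 0 < p1 <= 1

    def test_parental_enrichment_table_under_both_conventions(self):
        # 18 of 65 intron-losing genes parental vs 622 of 8,410 controls:
        # the published p of 8e-7 corresponds to the minimum-likelihood
        # convention; tail doubling gives twice that
        table = [[18, 47], [622, 7788]]
        assert fisher_exact_2x2(table, "min-likelihood") == pytest.approx(
            8.6e-7, rel=0.05)
        assert fisher_exact_2x2(table) == pytest.approx(1.7e-6, rel=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestChiSquare:
    def test_balanced_table(self):
        assert chi_square_2x2([[5, 5], [5, 5]]) == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])

    def test_signal_peptide_absence_table_reproduces_published_p(self):
        # 60 of 65 intron-losing rat genes lack a signal peptide vs 6,366 of
        # 8,410 controls; the published p of 0.003 requires the continuity
        # correction (uncorrected: 0.0018)
        assert round(chi_square_2x2([[60, 5], [6366, 2044]]), 3) == 0.003
        assert chi_square_2x2([[60, 5], [6366, 2044]], correction=False) == \
            pytest.approx(0.0018, abs=2e-4)

    def test_same_decision_as_fisher_on_small_tables(self):
        rng = np.random.default_rng(2)
        tables = [rng.integers(1, 11, size=(2, 2)).tolist() for _ in range(60)]
        tables += [[[10, 1], [1, 10]], [[9, 1], [2, 10]]]  # clear associations
        rejected = 0
        for t in tables:
            f = fisher_exact_2x2(t)
            c = chi_square_2x2(t)
            # with the conservative Yates correction chi-square never
            # rejects a table that Fisher accepts at alpha = 0.05
            if c < 0.05:
                assert f < 0.05
                rejected += 1
        assert rejected >= 2


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        assert mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_separated_triples_exact_p(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6).tolist(), rng.normal(size=9).tolist()
        assert mann_whitney_u(x, y) == pytest.approx(mann_whitney_u(y, x))

    def test_exact_branch_matches_full_enumeration(self):
        rng = np.random.default_rng(4)
        for n, m in [(3, 3), (4, 5), (6, 6), (2, 6)]:
            x = rng.normal(size=n).tolist()
            y = rng.normal(size=m).tolist()
            assert mann_whitney_u(x, y) == pytest.approx(
                mwu_exact_oracle(x, y), abs=1e-9)

    def test_exact_and_normal_branches_agree_at_n8(self):
        rng = np.random.default_rng(5)
        from scipy.stats import mannwhitneyu
        for _ in range(10):
            x = rng.normal(size=8).tolist()
            y = rng.normal(size=8).tolist()
            exact = mann_whitney_u(x, y)
            approx = float(mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue)
            assert abs(exact - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
        assert spearman_rho(x, [10, 8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_midrank_ties_match_rank_then_pearson_oracle(self):
        x = [1, 2, 2, 3]
        y = [4, 3, 3, 1]
        rho, _ = spearman_rho(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# adjacency null


def cluster_counts_by_enumeration(n, k):
    out = {}
    for subset in itertools.combinations(range(n), k):
        runs = 1 + sum(1 for a, b in zip(subset, subset[1:]) if b - a > 1)
        out[runs] = out.get(runs, 0) + 1
    total = math.comb(n, k)
    return {c: v / total for c, v in out.items()}


class TestClusterDistribution:
    def test_all_introns_lost_is_one_cluster(self):
        assert cluster_distribution(5, 5) == {1: 1.0}

    def test_small_cases(self):
        assert cluster_distribution(3, 2) == pytest.approx({1: 2 / 3, 2: 1 / 3})
        assert cluster_distribution(7, 2)[1] == pytest.approx(6 / 21)

    @given(st.integers(1, 30))
    @settings(max_examples=30, deadline=None)
    def test_pmf_sums_to_one(self, n):
        for k in range(1, n + 1):
            assert sum(cluster_distribution(n, k).values()) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cluster_distribution(3, 0)
        with pytest.raises(ValueError):
            cluster_distribution(3, 4)


class TestAdjacencyPvalue:
    def test_single_gene_example(self):
        # an adjacent pair arises in 2 of the 3 equally likely subsets
        null = adjacency_pvalue([(3, 2)], observed_pairs=1)
        assert null.p_pairs == pytest.approx(2 / 3)
        null0 = adjacency_pvalue([(3, 2)], observed_pairs=0)
        assert null0.p_pairs == pytest.approx(1.0)

    def test_convolution_preserves_mass_and_monotonicity(self):
        genes = [(6, 2), (8, 3), (5, 5), (4, 1)]
        null = adjacency_pvalue(genes)
        assert null.pair_pmf.sum() == pytest.approx(1.0)
        assert null.cluster_pmf.sum() == pytest.approx(1.0)
        prev = 1.1
        for obs in range(0, len(null.pair_pmf)):
            p = adjacency_pvalue(genes, observed_pairs=obs).p_pairs
            assert p <= prev + 1e-12
            prev = p

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            adjacency_pvalue([])


# ---------------------------------------------------------------------------
# micro-homology


class TestMicrohomology:
    def test_planted_hexamer_is_found(self):
        # GATTAC planted just before the donor site and again before the
        # acceptor; verified against an independent longest-common-substring
        # computation to be the only shared hexamer
        up = "TTTCAGAAAATGGTGATTAC"
        intron = "GTCAACGCCAGACGGGTAAAGCAGTTCGTGGATTACACTAAG"
        down = "TGCTTCGTGCTTAGT"
        found, length = microhomology_scan(up, intron, down, min_len=6, window=15)
        assert found and length == 6

    def test_shared_pentamer_only_is_below_threshold(self):
        up = "CAGTCTCTACCATTAGATTA"
        intron = "GTTTCCGGCATGATGAGGATGCAATAGTTCACGATTATGAGAG"
        down = "CACTTAGTCCAATAA"
        found, length = microhomology_scan(up, intron, down, min_len=6, window=15)
        assert not found and length == 5

    def test_unrelated_windows_share_nothing_long(self):
        up = "ACGCGTCTACACATT"
        intron = "GTATGCTTTGCGTGACCGCCGGATCAACGCTAAG"
        down = "ACGCTATATACCTGT"
        found, _ = microhomology_scan(up, intron, down)
        assert not found

    def test_short_sequences_evaluated_as_available(self):
        found, length = microhomology_scan("ACG", "GTAG", "ACG", min_len=2, window=15)
        assert isinstance(found, bool) and length >= 0

    def test_lcs_oracle(self):
        assert longest_common_substring("xABCDEFy", "zABCDEFw") == 6
        assert longest_common_substring("abc", "xyz") == 0

    def test_background_rate_matches_kmer_intersection_oracle(self):
        """Scanner frequency on random windows equals a set-intersection
        computation of shared hexamers, within binomial error."""
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        hits_scan = hits_oracle = 0
        trials = 300
        for _ in range(trials):
            up = "".join(rng.choice(bases, 45))
            intron = "".join(rng.choice(bases, 80))
            down = "".join(rng.choice(bases, 45))
            found, _ = microhomology_scan(up, intron, down)
            w5 = up[-15:] + intron[:15]
            w3 = intron[-15:] + down[:15]
            k5 = {w5[i:i + 6] for i in range(len(w5) - 5)}
            k3 = {w3[i:i + 6] for i in range(len(w3) - 5)}
            hits_scan += found
            hits_oracle += bool(k5 & k3)
        assert hits_scan == hits_oracle


# ---------------------------------------------------------------------------
# positions, housekeeping, association suite


class TestPositionalBias:
    def test_definitions(self):
        site = SitePosition("g", 500, 2000, is_last=False)
        assert site.relative_position == 0.25
        assert site.distance_to_3p == 1500

    def test_last_intron_has_maximal_relative_position(self):
        sites = [SitePosition("g", off, 3000, is_last=(off == 2500))
                 for off in (300, 1200, 2500)]
        last = max(sites, key=lambda s: s.relative_position)
        assert last.is_last

    def test_report_counts(self):
        lost = [SitePosition("g1", 1800, 2000, True),
                SitePosition("g2", 300, 2000, False)]
        cons = [SitePosition("g3", o, 2000, False) for o in (200, 900, 1100, 1500)]
        rep = positional_bias(lost, cons)
        assert rep["n_lost_3prime_most"] == 1
        assert rep["n_lost_3prime_half"] == 1
        assert 0 < rep["relative_position_mwu_p"] <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            positional_bias([], [SitePosition("g", 1, 10, False)])


class TestHousekeeping:
    def _expr(self, rows, tissues=("brain", "liver", "testis")):
        df = pd.DataFrame(rows, columns=list(tissues))
        df.index.name = "gene_id"
        return df

    def test_strictly_above_cutoff_everywhere(self):
        expr = self._expr({"g1": [250, 250, 0], "g2": [250, 200, 999]}.values())
        expr.index = ["g1", "g2"]
        flags = housekeeping_classify(expr, cutoff=200,
                                      excluded_tissues=("testis",))
        assert flags == {"g1": True, "g2": False}  # 200 is not > 200

    def test_reproductive_tissues_ignored(self):
        expr = self._expr([[300, 300, 0]])
        expr.index = ["g"]
        assert housekeeping_classify(expr)["g"] is True

    def test_missing_values_excluded(self):
        expr = self._expr([[300, np.nan, 300]])
        expr.index = ["g"]
        assert housekeeping_classify(expr) == {}

    def test_no_tissues_rejected(self):
        with pytest.raises(ValueError):
            housekeeping_classify(pd.DataFrame(index=["g"]))


class TestAssociationSuite:
    def _inputs(self, pp):
        genes = sorted(pp)
        ann = pd.DataFrame({"gene_id": genes,
                            "has_signal_peptide": [False] * len(genes),
                            "has_tm_domain": [False] * len(genes)})
        expr = pd.DataFrame({"brain": [300] * len(genes)}, index=genes)
        lengths = {g: 2000 for g in genes}
        introns = {g: 5 for g in genes}
        return ann, expr, lengths, introns

    def test_identical_group_composition_gives_null_results(self):
        pp = {f"g{i}": (1 if i % 2 else 0) for i in range(12)}
        il = {f"g{i}" for i in range(0, 6)}
        nil = {f"g{i}" for i in range(6, 12)}
        ann, expr, lengths, introns = self._inputs(pp)
        rep = association_suite(il, nil, pp, ann, expr, lengths, introns,
                                losses_per_gene={g: 1 for g in il})
        assert rep["parental_pp"]["fisher_p"] == 1.0
        assert rep["pp_per_gene"]["mwu_p"] == pytest.approx(1.0)

    def test_toy_table_matches_hypergeometric_enumeration(self):
        pp = {"g1": 2, "g2": 0, "g3": 0, "g4": 0, "g5": 0, "g6": 0}
        il, nil = {"g1", "g2"}, {"g3", "g4", "g5", "g6"}
        ann, expr, lengths, introns = self._inputs(pp)
        rep = association_suite(il, nil, pp, ann, expr, lengths, introns,
                                losses_per_gene={"g1": 1, "g2": 1})
        assert rep["parental_pp"]["table"] == [[1, 1], [0, 4]]
        assert rep["parental_pp"]["fisher_p"] == pytest.approx(
            fisher_doubling_oracle([[1, 1], [0, 4]]))

    def test_empty_or_overlapping_groups_rejected(self):
        pp = {"g1": 1, "g2": 0}
        ann, expr, lengths, introns = self._inputs(pp)
        with pytest.raises(ValueError):
            association_suite(set(), {"g2"}, pp, ann, expr, lengths, introns, {})
        with pytest.raises(ValueError):
            association_suite({"g1"}, {"g1", "g2"}, pp, ann, expr,
                              lengths, introns, {})
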