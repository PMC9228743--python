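import itertools
from math import comb

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.cluster.hierarchy import fcluster, linkage

from podmap import (
    cluster_shared_genes,
    fisher_combine,
    intersect_deg_dpod,
    ora_gmt,
    read_gmt,
    shared_genes,
)
from podmap.errors import (
    EmptyInputError,
    IncompleteProfileError,
    InvalidPValueError,
    SchemaError,
    SubsetError,
)
from podmap.summarize import _complete_linkage_cut, encode_label_profile


class TestSetOperations:
    def test_intersect_deg_dpod(self):
        overlap, n_deg, n_dpod, n = intersect_deg_dpod({"a", "b", "c"}, {"b", "c", "d"})
        assert overlap == {"b", "c"} and (n_deg, n_dpod, n) == (3, 3, 2)
        assert intersect_deg_dpod({"a"}, {"b"})[3] == 0
        assert intersect_deg_dpod({"a", "b"}, {"a", "b"})[3] == 2

    def test_shared_genes(self):
        sets = [{"a", "b"}, {"a", "c"}, {"a"}]
        assert shared_genes(sets, 3) == {"a"}
        assert shared_genes(sets, 1) == {"a", "b", "c"}
        assert shared_genes([], 0) == set()


class TestClusterSharedGenes:
    SE = ("sensitive", "early")
    RE = ("resilient", "early")
    RL = ("resilient", "late")

    def test_identical_profiles_share_cluster(self):
        vectors = {"g1": [self.SE] * 4, "g2": [self.SE] * 4, "g3": [self.RL] * 4}
        for k in (1, 2, 3):
            clusters = {c.gene_id: c.cluster_id for c in cluster_shared_genes(vectors, k=k)}
            assert clusters["g1"] == clusters["g2"]
            if k >= 2:
                assert clusters["g3"] != clusters["g1"]

    def test_ordinal_manhattan_distance(self):
        # one condition flips sensitive -> resilient: |0 - 2| = 2
        a = encode_label_profile([self.SE] * 4)
        b = encode_label_profile([self.RE] + [self.SE] * 3)
        assert np.abs(a - b).sum() == 2.0

    def test_k_above_distinct_profiles_gives_profile_singletons(self):
        vectors = {
            "g1": [self.SE],
            "g2": [self.SE],
            "g3": [self.RL],
            "g4": [self.RE],
        }
        clusters = {c.gene_id: c.cluster_id for c in cluster_shared_genes(vectors, k=10)}
        assert clusters["g1"] == clusters["g2"]
        assert len(set(clusters.values())) == 3  # three distinct profiles

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(10)
        sections = list(
            itertools.product(("sensitive", "intermediate", "resilient"), ("early", "middle", "late"))
        )
        genes = {f"g{i}": [sections[rng.integers(9)] for _ in range(4)] for i in range(12)}
        base = cluster_shared_genes(genes, k=4)
        base_part = {}
        for c in base:
            base_part.setdefault(c.cluster_id, set()).add(c.gene_id)
        shuffled_names = list(genes)
        rng.shuffle(shuffled_names)
        other = cluster_shared_genes({g: genes[g] for g in shuffled_names}, k=4)
        other_part = {}
        for c in other:
            other_part.setdefault(c.cluster_id, set()).add(c.gene_id)
        assert set(map(frozenset, base_part.values())) == set(map(frozenset, other_part.values()))

    def test_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(11)
        X = rng.random((9, 3))  # continuous: merge heights distinct a.s.
        ours = _complete_linkage_cut(X, 3)
        theirs = fcluster(linkage(X, method="complete", metric="cityblock"), 3, "maxclust")
        ours_part = {frozenset(np.flatnonzero(ours == c)) for c in set(ours)}
        theirs_part = {frozenset(np.flatnonzero(theirs == c)) for c in set(theirs)}
        assert ours_part == theirs_part

    def test_incomplete_profile_raises(self):
        with pytest.raises(IncompleteProfileError):
            cluster_shared_genes({"g1": [self.SE, self.RL], "g2": [self.SE]}, k=2)


class TestFisherCombine:
    def test_single_p_identity(self):
        for p in (0.001, 0.3, 1.0):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-12)

    def test_two_equal_pvalues_closed_form(self):
        # X = -4 ln 0.05; with df 4 the tail is exp(-X/2) (1 + X/2)
        x = -4 * np.log(0.05)
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(closed, rel=1e-12)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.01748, abs=5e-6)
        assert fisher_combine([1.0, 1.0, 1.0]) == 1.0

    def test_matches_chi_square_density_integration(self):
        rng = np.random.default_rng(12)
        for k in range(1, 6):
            p = rng.uniform(0.01, 0.99, size=k)
            x = -2 * np.log(p).sum()
            tail, _ = integrate.quad(lambda v: stats.chi2.pdf(v, 2 * k), x, np.inf)
            assert fisher_combine(p) == pytest.approx(tail, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidPValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(EmptyInputError):
            fisher_combine([])


class TestOraGmt:
    def test_exact_hypergeometric_tail(self):
        universe = {f"u{i}" for i in range(100)}
        query = {f"u{i}" for i in range(10)}
        gene_set = {f"u{i}" for i in range(5, 15)}  # overlap 5, size 10
        table = ora_gmt(query, universe, {"s": gene_set})
        expected = sum(
            comb(10, x) * comb(90, 10 - x) / comb(100, 10) for x in range(5, 11)
        )
        assert table["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(6.716277e-4, rel=1e-5)
        assert table["overlap"].iloc[0] == 5

    def test_no_overlap_and_maximal_overlap(self):
        universe = {f"u{i}" for i in range(50)}
        query = {f"u{i}" for i in range(5)}
        collection = {
            "none": {f"u{i}" for i in range(40, 45)},
            "exact": set(query),
            "half": {f"u{i}" for i in range(3, 10)},
        }
        table = ora_gmt(query, universe, collection).set_index("set_name")
        assert table.loc["none", "pvalue"] > 0.5
        assert table.index[0] == "exact"  # sorted by p, maximal overlap first
        assert table.loc["exact", "overlap"] == 5
        assert (table["adj_pvalue"] >= table["pvalue"] - 1e-15).all()

    def test_monte_carlo_permutation_oracle(self):
        rng = np.random.default_rng(13)
        m, nq, ns, n_draws = 30, 6, 8, 100_000
        universe = [f"u{i}" for i in range(m)]
        gene_set = set(universe[:ns])
        query = set(universe[10:10 + nq])
        observed = len(gene_set & query)
        table = ora_gmt(query, set(universe), {"s": gene_set})
        # resample random queries of the same size from the universe
        draws = np.argsort(rng.random((n_draws, m)), axis=1)[:, :nq]
        overlaps = (draws < ns).sum(axis=1)
        mc_p = (overlaps >= observed).mean()
        se = np.sqrt(mc_p * (1 - mc_p) / n_draws)
        assert abs(table["pvalue"].iloc[0] - mc_p) < 3 * se + 1e-12

    def test_query_must_be_subset(self):
        with pytest.raises(SubsetError):
            ora_gmt({"x"}, {"a", "b"}, {})


class TestReadGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc one\tg1\tg2\tg3\ns2\t\tg2\tg4\n\n")
        collection = read_gmt(path)
        assert collection == {"s1": {"g1", "g2", "g3"}, "s2": {"g2", "g4"}}

    def test_malformed_and_duplicate_lines(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\n")
        with pytest.raises(SchemaError):
            read_gmt(path)
        path.write_text("s1\td\tg1\ns1\td\tg2\n")
        with pytest.raises(SchemaError):
            read_gmt(path)
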