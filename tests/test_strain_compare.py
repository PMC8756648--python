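"""Shared-peptide matrices, presence queries and clustering order."""

import itertools

import numpy as np
import pytest

from sigpep import strain_compare as sc
from sigpep.records import SignalPeptideRecord, StrainPeptideSet


_LABEL_CHARS = "abcdefghijklmnopqrstuvwxyz0123456789"
_PAIR = "ACDEFG"


def _encode(label):
    """Map a short label to a distinct valid peptide string."""
    body = "".join(
        _PAIR[_LABEL_CHARS.index(c) // 6] + _PAIR[_LABEL_CHARS.index(c) % 6]
        for c in label.lower()
    )
    return "MK" + body


def _set(strain_id, members):
    return StrainPeptideSet(strain_id=strain_id, peptides=frozenset(map(_encode, members)))


def random_panel(rng, n_strains, universe_size=60, max_size=50):
    universe = ["MK" + "".join(rng.choice(list("ACDEFGHILNPQSTVWY"), 8)) for _ in range(universe_size)]
    sets = []
    for i in range(n_strains):
        k = int(rng.integers(1, max_size + 1))
        members = rng.choice(universe, size=min(k, len(universe)), replace=False)
        sets.append(StrainPeptideSet(strain_id=f"s{i:02d}", peptides=frozenset(members)))
    return sets


def brute_force_shared(sets):
    """Quadratic membership-loop oracle for the shared-count matrix."""
    n = len(sets)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                m[i, j] = len(sets[i].peptides)
            else:
                m[i, j] = sum(p in sets[j].peptides for p in sets[i].peptides)
    return m


class TestSharedCounts:
    def test_enumeration_example(self):
        sets = [_set("A", ["a", "b", "c"]), _set("B", ["b", "c", "d"])]
        m = sc.shared_counts(sets)
        assert m[0, 1] == 2 and m[0, 0] == 3 and m[1, 1] == 3

    def test_identical_and_disjoint_sets(self):
        a = _set("A", ["a", "b", "c"])
        same = StrainPeptideSet(strain_id="B", peptides=a.peptides)
        assert sc.shared_counts([a, same])[0, 1] == 3
        assert sc.shared_counts([a, _set("C", ["x", "y"])])[0, 1] == 0

    def test_duplicate_strain_ids_rejected(self):
        a = _set("A", ["a"])
        with pytest.raises(ValueError, match="duplicate"):
            sc.shared_counts([a, _set("A", ["b"])])

    def test_equivalence_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            panel = random_panel(rng, int(rng.integers(2, 11)))
            assert np.array_equal(sc.shared_counts(panel), brute_force_shared(panel))


class TestPercentShared:
    def test_jaccard_example(self):
        sim = sc.percent_shared([_set("A", ["a", "b", "c"]), _set("B", ["b", "c", "d"])])
        assert sim.percent[0, 1] == pytest.approx(50.0)

    def test_identical_sets_are_100_disjoint_0(self):
        a = _set("A", ["a", "b"])
        b = StrainPeptideSet(strain_id="B", peptides=a.peptides)
        assert sc.percent_shared([a, b]).percent[0, 1] == 100.0
        assert sc.percent_shared([a, _set("C", ["z"])]).percent[0, 1] == 0.0

    def test_empty_set_convention(self):
        a = _set("A", ["a"])
        empty = StrainPeptideSet(strain_id="E", peptides=frozenset())
        with pytest.warns(UserWarning, match="empty"):
            sim = sc.percent_shared([a, empty])
        assert sim.percent[0, 1] == 0.0
        assert sim.percent[1, 1] == 100.0

    def test_symmetry_and_diagonal_on_random_panels(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            sim = sc.percent_shared(random_panel(rng, int(rng.integers(2, 8))))
            assert np.allclose(sim.percent, sim.percent.T)
            assert np.allclose(np.diag(sim.percent), 100.0)
            assert sim.percent.min() >= 0.0 and sim.percent.max() <= 100.0
            assert np.array_equal(sim.shared, sim.shared.T)

    def test_jaccard_distance_triangle_inequality(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            sim = sc.percent_shared(random_panel(rng, 3))
            d = 1.0 - sim.percent / 100.0
            for i, j, k in itertools.permutations(range(3), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestPresence:
    def _panel(self):
        return [
            _set("s1", ["a", "b"]),
            _set("s2", ["a"]),
            _set("s3", ["a", "c"]),
            _set("s4", ["c"]),
        ]

    def _query(self, label):
        return SignalPeptideRecord(id="q", sp_seq=_encode(label))

    def test_three_of_four(self):
        table = sc.presence([self._query("a")], self._panel())
        assert table.loc["q", "percent_present"] == 75.0
        assert list(table.loc["q", ["s1", "s2", "s3", "s4"]]) == [True, True, True, False]

    def test_absent_query(self):
        table = sc.presence([self._query("z")], self._panel())
        assert table.loc["q", "percent_present"] == 0.0

    def test_single_strain_panel(self):
        table = sc.presence([self._query("a")], [_set("only", ["a"])])
        assert table.loc["q", "percent_present"] == 100.0

    def test_empty_query_list_gives_empty_table(self):
        assert sc.presence([], self._panel()).empty

    def test_identity_threshold_mode_accepts_near_match(self):
        panel = [StrainPeptideSet(strain_id="s", peptides=frozenset({"MKAAAAAAAL"}))]
        q = SignalPeptideRecord(id="q", sp_seq="MKAAAAAAAV")  # 9/10 identical
        assert sc.presence([q], panel, min_identity=0.9).loc["q", "percent_present"] == 100.0
        assert sc.presence([q], panel).loc["q", "percent_present"] == 0.0


class TestMeanOffdiag:
    def test_constant_percents(self):
        sets = [_set(c, ["x", c]) for c in "abc"]  # every pair shares exactly one peptide
        sim = sc.percent_shared(sets)
        mean, sd = sc.mean_offdiag(sim)
        assert sd == pytest.approx(0.0)

    def test_two_value_sample_sd_by_hand(self):
        sim = sc.SimilarityMatrix(
            strains=["a", "b", "c"],
            shared=np.zeros((3, 3), dtype=int),
            percent=np.array([[100.0, 0.0, 100.0], [0.0, 100.0, 50.0], [100.0, 50.0, 100.0]]),
        )
        mean, sd = sc.mean_offdiag(sim, subset=["a", "b", "c"])
        assert mean == pytest.approx(50.0)
        # sample SD of {0, 100, 50} = 50
        assert sd == pytest.approx(50.0)
        mean2, sd2 = sc.mean_offdiag(sim.subset(["a", "b"]))
        assert (mean2, sd2) == (0.0, 0.0)

    def test_single_pair_subset_has_zero_sd_by_convention(self):
        sim = sc.SimilarityMatrix(
            strains=["a", "b", "c"],
            shared=np.zeros((3, 3), dtype=int),
            percent=np.array(
                [[100.0, 0.0, 100.0], [0.0, 100.0, 100.0], [100.0, 100.0, 100.0]]
            ),
        )
        assert sc.mean_offdiag(sim, subset=["a", "b"]) == (0.0, 0.0)

    def test_planted_uniform_jaccard_panel_has_zero_spread(self):
        from sigpep.synthetic_data import PanelGenParams, gen_strain_panel

        panel = gen_strain_panel(
            PanelGenParams(n_strains=4, set_size=35, target_jaccard=0.4, seed=3)
        )
        mean, sd = sc.mean_offdiag(sc.percent_shared(panel))
        assert mean == pytest.approx(40.0)
        assert sd == pytest.approx(0.0)

    def test_subset_too_small_rejected(self):
        sim = sc.percent_shared([_set("a", ["x"]), _set("b", ["x"])])
        with pytest.raises(ValueError):
            sc.mean_offdiag(sim, subset=["a"])


class TestClusterOrder:
    def test_identical_pair_merges_first(self):
        a = _set("a", ["x", "y"])
        b = StrainPeptideSet(strain_id="b", peptides=a.peptides)
        c = _set("c", ["z"])
        sim = sc.percent_shared([a, b, c])
        leaves, merges = sc.cluster_order(sim)
        assert merges[0][:2] == (["a"], ["b"]) and merges[0][2] == 0.0
        assert leaves.index("c") == 2

    def test_planted_blocks_stay_contiguous(self):
        block1 = [_set(f"a{i}", ["s", f"a{i}"]) for i in range(2)]
        block2 = [_set(f"b{i}", ["t", f"b{i}"]) for i in range(2)]
        sim = sc.percent_shared(block1 + block2)
        leaves, _ = sc.cluster_order(sim)
        # block membership must be contiguous: the two a-strains adjacent, likewise b
        pos = {name: i for i, name in enumerate(leaves)}
        assert abs(pos["a0"] - pos["a1"]) == 1
        assert abs(pos["b0"] - pos["b1"]) == 1

    def test_all_equal_distances_fall_back_to_lexicographic(self):
        sets = [_set(s, [s]) for s in ["d", "b", "c", "a"]]  # all pairwise disjoint
        sim = sc.percent_shared(sets)
        leaves, _ = sc.cluster_order(sim)
        assert leaves == ["a", "b", "c", "d"]


class TestMatrixIO:
    def test_percent_matrix_round_trip_one_decimal(self, tmp_path):
        sim = sc.percent_shared(
            [_set("A", ["a", "b", "c"]), _set("B", ["b", "c", "d"]), _set("C", ["a"])]
        )
        path = tmp_path / "percent.tsv"
        sc.write_matrix_tsv(sim, path)
        strains, mat = sc.read_matrix_tsv(path)
        assert strains == ["A", "B", "C"]
        assert mat[0, 1] == pytest.approx(50.0)
        assert np.allclose(np.diag(mat), 100.0)
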