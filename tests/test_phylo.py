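"""Gap-column editing, distances, NJ, bootstrap, newick I/O, clade calls."""

import numpy as np
import pytest

from peroxfam import phylo, synthetic

AA = list("ACDEFGHIKLMNPQRSTVWY")


def aln(rows, ids=None):
    ids = ids or [f"t{i}" for i in range(len(rows))]
    return phylo.Alignment(ids=ids, rows=rows)


class TestGapFilter:
    def test_strict_inequality_boundary(self):
        a = aln(["A-A-", "A-A-", "A-AC", "AAAC"])  # col1: 3/4 gaps, col3: 2/4
        edited, removed = phylo.filter_gap_columns(a, threshold=0.5)
        assert removed == [1]
        assert edited.rows == ["AA-", "AA-", "AAC", "AAC"]

    def test_gap_free_alignment_is_identity(self):
        a = aln(["ACDE", "ACDF", "ACDG"])
        edited, removed = phylo.filter_gap_columns(a)
        assert removed == [] and edited.rows == a.rows

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(AA + ["-"] * 8, size=60)) for _ in range(6)]
        once, _ = phylo.filter_gap_columns(aln(rows))
        twice, removed2 = phylo.filter_gap_columns(once)
        assert removed2 == [] and twice.rows == once.rows

    def test_matches_per_column_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            rows = ["".join(rng.choice(AA + ["-"] * 10, size=40)) for _ in range(8)]
            _, removed = phylo.filter_gap_columns(aln(rows), threshold=0.5)
            expected = [
                j for j in range(40)
                if sum(r[j] == "-" for r in rows) / 8 > 0.5
            ]
            assert removed == expected

    def test_ragged_alignment_rejected(self):
        with pytest.raises(phylo.AlignmentError, match="ragged"):
            aln(["ACD", "AC"])


class TestDistances:
    def test_identical_rows_zero(self):
        dm = phylo.distance_matrix(aln(["ACDE", "ACDE"]))
        assert dm["t0", "t1"] == 0.0

    def test_p_distance_arithmetic(self):
        dm = phylo.distance_matrix(aln(["AAAA", "AAAT"]))
        assert dm["t0", "t1"] == pytest.approx(0.25)

    def test_poisson_correction(self):
        dm = phylo.distance_matrix(aln(["AAAA", "AAAT"]), model="poisson")
        assert dm["t0", "t1"] == pytest.approx(-np.log(0.75))

    def test_poisson_saturated_pair_is_error(self):
        with pytest.raises(phylo.AlignmentError, match="Poisson"):
            phylo.distance_matrix(aln(["AAAA", "CCCC"]), model="poisson")

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(phylo.AlignmentError, match="comparable"):
            phylo.distance_matrix(aln(["A--A", "-AA-"]))

    def test_selenocysteine_scored_as_cysteine(self):
        dm = phylo.distance_matrix(aln(["UCAA", "CCAA"]))
        assert dm["t0", "t1"] == 0.0

    def test_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(21)
        rows = ["".join(rng.choice(AA + ["-"] * 3, size=50)) for _ in range(7)]
        dm = phylo.distance_matrix(aln(rows))
        for i in range(7):
            for j in range(7):
                cols = [
                    (a, b) for a, b in zip(rows[i], rows[j])
                    if a != "-" and b != "-"
                ]
                expected = sum(a != b for a, b in cols) / len(cols)
                assert dm[f"t{i}", f"t{j}"] == pytest.approx(expected)


def random_additive_tree(rng, n_taxa):
    """Random binary tree topology with branch lengths; returns (newick, D)."""
    import itertools
    nodes = {i: f"t{i}" for i in range(n_taxa)}
    # adjacency with branch lengths, built by random sequential joining
    adj: dict[str, list[tuple[str, float]]] = {f"t{i}": [] for i in range(n_taxa)}
    active = [f"t{i}" for i in range(n_taxa)]
    counter = 0
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        new = f"n{counter}"; counter += 1
        adj[new] = []
        for child in (a, b):
            w = float(rng.uniform(0.1, 1.0))
            adj[new].append((child, w))
            adj[child].append((new, w))
        active = [x for x in active if x not in (a, b)] + [new]
    hub = f"n{counter}"
    adj[hub] = []
    for child in active:
        w = float(rng.uniform(0.1, 1.0))
        adj[hub].append((child, w))
        adj[child].append((hub, w))

    def dist(a, b):
        seen, stack = {a}, [(a, 0.0)]
        while stack:
            node, d = stack.pop()
            if node == b:
                return d
            for nb, w in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, d + w))
        raise AssertionError

    ids = [f"t{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        D[i, j] = D[j, i] = dist(ids[i], ids[j])
    return ids, D


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_matrix(self):
        # classic additive example: ((a:2,b:3):3,(c:4,d:4)) style distances
        from skbio import DistanceMatrix
        D = np.array([
            [0, 5, 9, 9],
            [5, 0, 10, 10],
            [9, 10, 0, 8],
            [9, 10, 8, 0],
        ], dtype=float)
        tree = phylo.nj_tree(DistanceMatrix(D, ids=list("abcd")))
        tips = {t.name: t for t in tree.tips()}
        for (x, y), expected in [(("a", "b"), 5), (("a", "c"), 9), (("c", "d"), 8)]:
            assert tips[x].distance(tips[y]) == pytest.approx(expected, abs=1e-9)
        assert phylo.bipartitions(tree) == {frozenset({"c", "d"})}

    def test_random_additive_matrices_recovered_exactly(self):
        from skbio import DistanceMatrix
        rng = np.random.default_rng(33)
        for _ in range(10):
            ids, D = random_additive_tree(rng, 8)
            tree = phylo.nj_tree(DistanceMatrix(D, ids=ids))
            tipdist = tree.tip_tip_distances(endpoints=ids)
            err = np.max(np.abs(tipdist.data - D))
            assert err < 1e-9

    def test_star_matrix_gives_zero_internal_lengths(self):
        from skbio import DistanceMatrix
        n = 5
        D = np.full((n, n), 2.0) - 2.0 * np.eye(n)
        tree = phylo.nj_tree(DistanceMatrix(D, ids=[f"t{i}" for i in range(n)]))
        for node in tree.non_tips(include_self=False):
            assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_too_few_taxa_rejected(self):
        from skbio import DistanceMatrix
        with pytest.raises(phylo.TreeError):
            phylo.nj_tree(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))

    def test_group_monophyly_on_synthetic_families(self):
        fam = synthetic.generate_subfamily_alignment(seed=5)
        dm = phylo.distance_matrix(fam.alignment)
        tree = phylo.nj_tree(dm)
        bps = phylo.bipartitions(tree)
        leaves = frozenset(fam.alignment.ids)
        anchor = min(leaves)
        for g in ("G1", "G2", "G3", "G4"):
            side = frozenset(i for i, lab in fam.labels.items() if lab == g)
            canon = leaves - side if anchor in side else side
            assert canon in bps


class TestBootstrap:
    def test_identical_columns_force_full_support(self):
        # every column carries the same split pattern, so every resample
        # reproduces the alignment and all supports are 100
        rows = ["AAAA", "AAAA", "CCCC", "CCCC", "GGGG"]
        rows = [r for r in rows]
        a = aln(["A" * 30, "A" * 30, "C" * 30, "C" * 30, "G" * 30])
        # identical pair rows give distance 0; still a valid NJ input
        tree, supports = phylo.bootstrap_support(a, B=1, seed=0)
        assert supports and all(s == 100.0 for s in supports.values())

    def test_supports_in_range_and_seed_deterministic(self):
        fam = synthetic.generate_subfamily_alignment(seed=6, members_per_group=4, length=80)
        t1, s1 = phylo.bootstrap_support(fam.alignment, B=30, seed=9)
        t2, s2 = phylo.bootstrap_support(fam.alignment, B=30, seed=9)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())
        _, s3 = phylo.bootstrap_support(fam.alignment, B=30, seed=10)
        assert set(s3) == set(s1)  # same tree, possibly different supports


class TestNewickIO:
    def test_support_labels_parsed(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a:1,b:1)90:0.5,c:2);\n")
        tree = phylo.read_newick(p)
        supported = [n for n in tree.non_tips(include_self=False)
                     if getattr(n, "support", None) is not None]
        assert len(supported) == 1 and supported[0].support == 90.0

    def test_round_trip_preserves_topology_lengths_supports(self, tmp_path):
        rng = np.random.default_rng(55)
        from skbio import DistanceMatrix
        for k in range(10):
            ids, D = random_additive_tree(rng, int(rng.integers(5, 12)))
            tree = phylo.nj_tree(DistanceMatrix(D, ids=ids))
            p1, p2 = tmp_path / f"a{k}.nwk", tmp_path / f"b{k}.nwk"
            phylo.write_newick(tree, p1)
            back = phylo.read_newick(p1)
            assert phylo.bipartitions(back) == phylo.bipartitions(tree)
            d1 = tree.tip_tip_distances(endpoints=ids).data
            d2 = back.tip_tip_distances(endpoints=ids).data
            assert np.allclose(d1, d2, atol=1e-6)
            phylo.write_newick(back, p2)
            assert p1.read_text() == p2.read_text()

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "e.nwk"
        p.write_text("")
        with pytest.raises(phylo.TreeError):
            phylo.read_newick(p)

    def test_unbalanced_parentheses_rejected(self, tmp_path):
        p = tmp_path / "u.nwk"
        p.write_text("((a:1,b:1:0.5,c:2);")
        with pytest.raises(phylo.TreeError):
            phylo.read_newick(p)


def dendropy_assign_oracle(newick: str, labels: dict, query: str):
    """Independent clade-assignment oracle via dendropy bipartitions."""
    import dendropy
    t = dendropy.Tree.get(data=newick, schema="newick")
    taxa = {lf.taxon.label for lf in t.leaf_node_iter()}
    sides = set()
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        for side in (below, frozenset(taxa - below)):
            if query in side and 0 < len(side) < len(taxa):
                sides.add(side)
    cands = [s for s in sides if any(x in labels for x in s if x != query)]
    if not cands:
        return None
    msize = min(len(s) for s in cands)
    minimal = [s for s in cands if len(s) == msize]
    labelsets = [
        {labels[x] for x in s if x in labels and x != query} for s in minimal
    ]
    union = set().union(*labelsets)
    if len(union) == 1 and all(len(ls) == 1 for ls in labelsets):
        return next(iter(union))
    return None


class TestAssignClade:
    def build_tree(self, newick, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(newick)
        return phylo.read_newick(p)

    def test_query_inside_pure_clade(self, tmp_path):
        tree = self.build_tree("(((q:1,r1:1):1,r2:1):1,(s1:1,s2:1):1,out:3);", tmp_path)
        labels = {"r1": "PRX6", "r2": "PRX6", "s1": "PRX5", "s2": "PRX5"}
        a = phylo.assign_clade(tree, labels, "q")
        assert a.label == "PRX6" and a.clade_size == 2

    def test_mixed_minimal_clade_unassigned(self, tmp_path):
        tree = self.build_tree("(((r1:1,s1:1):1,q:1):1,(r2:1,s2:1):1,out:3);", tmp_path)
        labels = {"r1": "PRX6", "r2": "PRX6", "s1": "PRX5", "s2": "PRX5"}
        a = phylo.assign_clade(tree, labels, "q")
        assert a.label is None and a.cause == "mixed"

    def test_query_sister_to_all_references_ambiguous(self, tmp_path):
        tree = self.build_tree("((a1:1,a2:1):1,(b1:1,b2:1):1,q:2);", tmp_path)
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        a = phylo.assign_clade(tree, labels, "q")
        assert a.label is None

    def test_min_support_blocks_weak_edges(self, tmp_path):
        tree = self.build_tree("(((q:1,r1:1)40:1,r2:1)90:1,(s1:1,s2:1)95:1,out:3);", tmp_path)
        labels = {"r1": "PRX6", "r2": "PRX6", "s1": "PRX5", "s2": "PRX5"}
        strict = phylo.assign_clade(tree, labels, "q", min_support=80.0)
        assert strict.label is None and strict.cause == "low support"
        lax = phylo.assign_clade(tree, labels, "q", min_support=30.0)
        assert lax.label == "PRX6"

    def test_query_not_in_tree_is_error(self, tmp_path):
        tree = self.build_tree("((a:1,b:1):1,c:1,d:1);", tmp_path)
        with pytest.raises(phylo.TreeError):
            phylo.assign_clade(tree, {"a": "A"}, "zz")

    def test_agrees_with_dendropy_bipartition_oracle(self, tmp_path):
        from skbio import DistanceMatrix
        rng = np.random.default_rng(71)
        mismatches = 0
        for k in range(25):
            n = int(rng.integers(6, 16))
            ids, D = random_additive_tree(rng, n)
            tree = phylo.nj_tree(DistanceMatrix(D, ids=ids))
            p = tmp_path / f"o{k}.nwk"
            phylo.write_newick(tree, p)
            newick = p.read_text()
            for _ in range(8):
                query = ids[int(rng.integers(n))]
                others = [x for x in ids if x != query]
                n_lab = int(rng.integers(2, len(others) + 1))
                chosen = list(rng.choice(others, size=n_lab, replace=False))
                labels = {x: str(rng.choice(["A", "B", "C"])) for x in chosen}
                got = phylo.assign_clade(tree, labels, query).label
                want = dendropy_assign_oracle(newick, labels, query)
                if got != want:
                    mismatches += 1
        assert mismatches == 0
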