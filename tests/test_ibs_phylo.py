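import subprocess

import numpy as np
import pytest
from skbio.tree import TreeNode

from ghostdex.genodata import assign_blocks
from ghostdex.ibs_phylo import (
    DistanceMatrix,
    classical_mds,
    ibs_matrix,
    nj_tree,
    node_support_pseudobootstrap,
    outgroup_distance_qc,
    tree_bipartitions,
)
from ghostdex.synthetic_data import preset_library, simulate_scenario

from conftest import make_matrix


def dist(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(labels=labels, d=d,
                          n_compared=np.full(d.shape, 10, dtype=np.int64))


class TestIbsMatrix:
    def test_identical_and_opposite_vectors(self):
        m = make_matrix(np.column_stack([np.zeros(10), np.zeros(10),
                                         np.ones(10)]).astype(np.int8))
        dm = ibs_matrix(m)
        assert dm.d[0, 1] == 0.0 and dm.d[0, 2] == 1.0

    def test_pairwise_deletion_definition(self):
        m = make_matrix(np.array([[0, 0], [1, 0], [-1, 1], [0, 0]],
                                 dtype=np.int8))
        dm = ibs_matrix(m)
        assert dm.d[0, 1] == pytest.approx(1 / 3)
        assert dm.n_compared[0, 1] == 3

    def test_zero_cocalled_pair_flagged_undefined(self):
        m = make_matrix(np.array([[0, -1], [-1, 1]], dtype=np.int8))
        dm = ibs_matrix(m)
        assert dm.undefined_pairs() == [("s0", "s1")]
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dist(["a", "b", "c"], [[0, 1, np.nan], [1, 0, 1],
                                           [np.nan, 1, 0]]))

    def test_random_matrix_equals_per_pair_loop_oracle(self, random_matrix):
        m = random_matrix(n_sites=120, n_samples=30, missing=0.25, seed=31)
        dm = ibs_matrix(m)
        for i in range(0, 30, 7):
            for j in range(i + 1, 30, 5):
                ci, cj = m.calls[:, i], m.calls[:, j]
                both = (ci >= 0) & (cj >= 0)
                expect = (ci[both] != cj[both]).mean()
                assert dm.d[i, j] == pytest.approx(expect)
                assert dm.d[j, i] == dm.d[i, j]

    def test_concatenation_is_cocalled_weighted_combination(self, random_matrix):
        a = random_matrix(n_sites=60, n_samples=5, seed=32)
        b = random_matrix(n_sites=80, n_samples=5, seed=33)
        both = make_matrix(np.vstack([a.calls, b.calls]),
                           chroms=["1"] * 140, positions=list(range(1, 141)))
        da, db, dc = ibs_matrix(a), ibs_matrix(b), ibs_matrix(both)
        na, nb = da.n_compared, db.n_compared
        mism = da.d * na + db.d * nb
        np.testing.assert_allclose(dc.d, mism / (na + nb), atol=1e-12)

    def test_region_restriction(self):
        m = make_matrix([[0, 1]] * 4, chroms=["1", "1", "1", "2"],
                        positions=[5, 10, 20, 5])
        dm = ibs_matrix(m, region=("1", 5, 10))
        assert dm.n_compared[0, 1] == 2


class TestNeighborJoining:
    def test_additive_four_taxon_split_and_lengths(self):
        # tree ((A:1,B:1):1,(C:1,D:1)): d(A,B)=2, d(C,D)=2, cross pairs 3
        d = [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]]
        t = nj_tree(dist(list("ABCD"), d))
        assert tree_bipartitions(t, list("ABCD")) == {frozenset("CD")}
        for tip in t.tips():
            assert tip.length == pytest.approx(1.0)

    def test_three_taxa_three_point_formulas(self):
        t = nj_tree(dist(list("ABC"), [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            nj_tree(dist(["a", "b"], [[0, 1], [1, 0]]))

    def test_random_additive_matrix_recovers_generating_topology(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            labels = [f"t{i}" for i in range(6)]
            gen = _random_tree(labels, rng)
            d = _tree_distance_matrix(gen, labels)
            rec = nj_tree(dist(labels, d))
            assert tree_bipartitions(rec, labels) == \
                tree_bipartitions(gen, labels)
            # branch lengths reproduce the generating additive distances
            drec = _tree_distance_matrix(rec, labels)
            np.testing.assert_allclose(drec, d, atol=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(42)
        labels = [f"t{i}" for i in range(6)]
        gen = _random_tree(labels, rng)
        d = _tree_distance_matrix(gen, labels)
        t1 = nj_tree(dist(labels, d))
        perm = rng.permutation(6)
        t2 = nj_tree(dist([labels[i] for i in perm],
                          np.asarray(d)[np.ix_(perm, perm)]))
        assert tree_bipartitions(t1, labels) == tree_bipartitions(t2, labels)

    def test_matches_ape_nj_topology(self, tmp_path):
        """Independent cross-check against the canonical R implementation."""
        rng = np.random.default_rng(43)
        labels = [f"t{i}" for i in range(7)]
        gen = _random_tree(labels, rng)
        d = _tree_distance_matrix(gen, labels)
        d = d + rng.uniform(0, 0.01, size=d.shape)  # mild non-additive noise
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        mine = nj_tree(dist(labels, d))
        mat = tmp_path / "d.tsv"
        np.savetxt(mat, d, delimiter="\t")
        script = (
            f"d <- as.matrix(read.table('{mat}', sep='\\t'));"
            f"rownames(d) <- colnames(d) <- c({','.join(repr(l) for l in labels)});"
            "t <- ape::nj(as.dist(d));"
            "cat(ape::write.tree(t))"
        )
        try:
            out = subprocess.run(["Rscript", "-e", script],
                                 capture_output=True, text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript unavailable")
        assert out.returncode == 0, out.stderr
        ape = TreeNode.read([out.stdout.strip()])
        assert tree_bipartitions(ape, labels) == \
            tree_bipartitions(mine, labels)

    def test_negative_branch_clamped_with_warning(self):
        # strongly non-additive matrix forcing a negative NJ branch
        d = [[0, 1, 1, 1], [1, 0, 1, 10], [1, 1, 0, 10], [1, 10, 10, 0]]
        with pytest.warns(UserWarning, match="clamped"):
            t = nj_tree(dist(list("ABCD"), d))
        assert all((tip.length or 0) >= 0 for tip in t.traverse())

    def test_rooting_on_outgroup_leaf(self):
        d = [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]]
        t = nj_tree(dist(list("ABCD"), d), root_on="A")
        assert len(t.children) == 2
        assert "A" in [c.name for c in t.children]


class TestPseudoBootstrap:
    def _clean_matrix(self, seed=51, n_sites=4000):
        scn = preset_library("introgressed_block", seed=seed)
        scn.alpha = 0.0
        scn.ghost_region = None
        scn.ghost_pop = None
        scn.admix_target = None
        scn.n_sites = n_sites
        m, _, _ = simulate_scenario(scn)
        from ghostdex.genodata import polarize
        pm, _ = polarize(m)
        return pm

    def test_uniform_structure_gives_100_support_everywhere(self):
        pm = self._clean_matrix()
        blocks = assign_blocks(pm)
        samples = ["tur1_00", "tur2_00", "bezoar_00", "dom_ref_00"]
        tree, sup = node_support_pseudobootstrap(
            pm, blocks, n_regions=8, n_reps=25, seed=1, samples=samples)
        assert sup and all(v == 100.0 for v in sup.values())

    def test_same_seed_identical_supports(self):
        pm = self._clean_matrix()
        blocks = assign_blocks(pm)
        a = node_support_pseudobootstrap(pm, blocks, n_regions=8, n_reps=10,
                                         seed=9)[1]
        b = node_support_pseudobootstrap(pm, blocks, n_regions=8, n_reps=10,
                                         seed=9)[1]
        assert a == b

    def test_too_few_blocks_rejected(self):
        pm = self._clean_matrix(n_sites=500)
        blocks = assign_blocks(pm)
        with pytest.raises(ValueError, match="n_regions"):
            node_support_pseudobootstrap(pm, blocks,
                                         n_regions=blocks.n_blocks + 1)

    def test_conflicting_blocks_enumerated_single_region_draws(self):
        """Two blocks supporting conflicting splits: with n_regions=1 each
        replicate is one of the C(2,1) draws, so support equals the draw
        frequency of the agreeing block."""
        rng = np.random.default_rng(3)
        # block 1 supports AB|CD, block 2 supports AC|BD
        def block_calls(split, n):
            base = {"AB|CD": [0, 0, 1, 1], "AC|BD": [0, 1, 0, 1]}[split]
            out = np.tile(base, (n, 1)).astype(np.int8)
            noise = rng.random(out.shape) < 0.02
            return np.where(noise, 1 - out, out).astype(np.int8)
        calls = np.vstack([block_calls("AB|CD", 50), block_calls("AC|BD", 50)])
        m = make_matrix(calls, chroms=["1"] * 100,
                        positions=list(range(1, 51)) + list(range(51, 101)),
                        samples=list("ABCD"))
        blocks = assign_blocks(m, 50)
        assert blocks.n_blocks == 2
        tree, sup = node_support_pseudobootstrap(m, blocks, n_regions=1,
                                                 n_reps=100, seed=4)
        # base tree over all sites picks one split; replicate draws are
        # uniform over the two blocks -> support near 50
        draws = [np.random.default_rng(4 + r).choice(2, size=1, replace=False)
                 for r in range(100)]
        frac_block0 = np.mean([d[0] == 0 for d in draws])
        (bp,) = sup
        base_split = tree_bipartitions(tree, list("ABCD"))
        expect = frac_block0 if frozenset("CD") in base_split else 1 - frac_block0
        assert sup[bp] == pytest.approx(100 * expect)


class TestMds:
    def test_collinear_points_embed_exactly_in_1d(self):
        dm = dist(list("ABC"), [[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        co = classical_mds(dm, k=1).to_numpy()[:, 0]
        d = np.abs(co[:, None] - co[None, :])
        np.testing.assert_allclose(d, dm.d, atol=1e-10)

    def test_identical_samples_identical_coordinates(self):
        dm = dist(list("ABC"), [[0, 0, 1], [0, 0, 1], [1, 1, 0]])
        co = classical_mds(dm, k=1).to_numpy()
        np.testing.assert_allclose(co[0], co[1], atol=1e-10)

    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(61)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        co = classical_mds(dist([f"p{i}" for i in range(8)], d), k=2)
        co = co.to_numpy()
        d2 = np.sqrt(((co[:, None] - co[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_k_at_least_n_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(dist(list("ABC"),
                               [[0, 1, 1], [1, 0, 1], [1, 1, 0]]), k=3)

    def test_sign_convention_deterministic(self):
        dm = dist(list("ABCD"), [[0, 1, 2, 3], [1, 0, 1, 2],
                                 [2, 1, 0, 1], [3, 2, 1, 0]])
        co = classical_mds(dm, k=1).to_numpy()[:, 0]
        assert co[np.argmax(np.abs(co))] > 0


class TestOutgroupQc:
    def test_high_error_sample_flagged(self):
        scn = preset_library("introgressed_block", seed=71)
        scn.alpha = 0.0; scn.ghost_region = None
        scn.ghost_pop = None; scn.admix_target = None
        scn.n_sites = 4000
        m, _, _ = simulate_scenario(scn)
        from ghostdex.genodata import polarize
        pm, _ = polarize(m)
        # corrupt one dom_ref sample with 5% call errors
        rng = np.random.default_rng(0)
        j = pm.samples.index("dom_ref_01")
        col = pm.calls[:, j]
        flip = (rng.random(pm.n_sites) < 0.05) & (col >= 0)
        pm.calls[flip, j] = 1 - col[flip]
        dm = ibs_matrix(pm)
        groups = {s: s.rsplit("_", 1)[0] for s in pm.samples}
        qc = outgroup_distance_qc(dm, "sheep_like_00", groups)
        flagged = qc[qc["flag"] == "high"]["sample"].tolist()
        assert "dom_ref_01" in flagged

    def test_equal_error_peers_unflagged(self):
        # identical distances to the outgroup: nothing to flag
        n = 8
        d = np.full((n, n), 0.3)
        np.fill_diagonal(d, 0)
        dm = dist([f"s{i}" for i in range(n)], d)
        qc = outgroup_distance_qc(dm, "s0")
        assert (qc["flag"] == "").all()

    def test_sample_identical_to_outgroup_flagged_low(self):
        rng = np.random.default_rng(2)
        n = 8
        d = np.full((n, n), 0.3) + rng.normal(0, 0.002, (n, n))
        d = (d + d.T) / 2
        d[0, 1] = d[1, 0] = 0.0  # sample s1 identical to the outgroup s0
        np.fill_diagonal(d, 0)
        qc = outgroup_distance_qc(dist([f"s{i}" for i in range(n)], d), "s0")
        assert qc.set_index("sample").loc["s1", "flag"] == "low"


def _random_tree(labels, rng) -> TreeNode:
    """Random binary unrooted tree with positive branch lengths."""
    nodes = [TreeNode(name=l, length=float(rng.uniform(0.5, 2.0)))
             for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.5, 2.0)))
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.append(n)
    return root


def _tree_distance_matrix(tree, labels):
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = tree.find(labels[i])
            b = tree.find(labels[j])
            d[i, j] = d[j, i] = a.distance(b)
    return d
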