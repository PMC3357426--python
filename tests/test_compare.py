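"""Profile matrices, Spearman distances, clustering, MDS and scatters."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.ordination import pcoa

from metacaz import compare
from metacaz.compare import (
    DistanceMatrix,
    ProfileMatrix,
    assemble_matrix,
    cluster,
    family_class,
    mds,
    pairwise_scatter,
    spearman_distance,
)
from metacaz.io_formats import ValidationError
from metacaz.tiling_profile import FamilyProfile

from oracles import spearman_oracle


def _profile(label, values):
    return FamilyProfile(label, dict(values), 1e6)


def _matrix(arr, labels=None, families=None):
    labels = labels or [f"m{i}" for i in range(arr.shape[1])]
    families = families or [f"GH{i + 1}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=families, columns=labels)
    return ProfileMatrix(df, {f: family_class(f) for f in families})


class TestFamilyClass:
    @pytest.mark.parametrize("fam,cls", [
        ("GH13", "GH"), ("GT2", "GT"), ("CE1", "CE"), ("CBM33", "CBM"),
        ("LO2", "LO"), ("LDA7", "LDA"), ("GH94/GT84", "GH"),
        ("GH10/CE1", "GH"), ("GH16/GH43", "GH"), ("weird", "other"),
    ])
    def test_examples(self, fam, cls):
        assert family_class(fam) == cls


class TestAssembleMatrix:
    def test_gh_only_drops_transferases(self):
        a = _profile("A", {"GH13": 10, "GT2": 5, "LO2": 2})
        b = _profile("B", {"GH13": 8, "GT4": 1})
        m = assemble_matrix([a, b], "gh_only")
        assert m.families == ["GH13"]

    def test_zero_fill_union(self):
        a = _profile("A", {"GH13": 10.0})
        b = _profile("B", {"GH5": 4.0})
        m = assemble_matrix([a, b], "all")
        assert m.data.at["GH5", "A"] == 0.0
        assert m.data.at["GH13", "B"] == 0.0

    def test_composite_gh_majority_kept_under_gh_only(self):
        a = _profile("A", {"GH94/GT84": 3.0, "GT2": 1.0})
        b = _profile("B", {"GH94/GT84": 2.0})
        m = assemble_matrix([a, b], "gh_only")
        assert m.families == ["GH94/GT84"]

    def test_single_profile_rejected(self):
        with pytest.raises(ValidationError):
            assemble_matrix([_profile("A", {"GH1": 1.0})])


class TestSpearmanDistance:
    def test_identical_columns_distance_zero(self):
        m = _matrix(np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]]))
        d = spearman_distance(m)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        m = _matrix(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        d = spearman_distance(m)
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            arr = rng.uniform(0, 100, size=(20, 6))
            arr[rng.random(arr.shape) < 0.2] = 0.0    # ties
            m = _matrix(arr)
            d = spearman_distance(m)
            for i in range(6):
                for j in range(6):
                    rho = spearman_oracle(arr[:, i], arr[:, j])
                    assert d.values[i, j] == pytest.approx(1 - rho, abs=1e-12)

    def test_zero_variance_column_distance_one_with_warning(self):
        arr = np.array([[1.0, 7.0], [1.0, 3.0], [1.0, 9.0]])
        m = _matrix(arr)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            d = spearman_distance(m)
        assert d.values[0, 1] == pytest.approx(1.0)
        assert d.values[0, 0] == 0.0

    def test_too_few_families_rejected(self):
        with pytest.raises(ValidationError):
            spearman_distance(_matrix(np.ones((2, 3))))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(0, 50, size=(15, 4))
        d1 = spearman_distance(_matrix(arr))
        arr2 = arr.copy()
        arr2[:, 0] = np.exp(arr2[:, 0] / 10.0)      # strictly monotone
        d2 = spearman_distance(_matrix(arr2))
        assert np.allclose(d1.values, d2.values, atol=1e-12)


class TestCluster:
    def test_two_labels_join_at_half_distance(self):
        d = DistanceMatrix(["x", "y"], np.array([[0.0, 0.8], [0.8, 0.0]]))
        tree = TreeNode.read(io.StringIO(cluster(d)))
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"x": pytest.approx(0.4), "y": pytest.approx(0.4)}

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, size=(5, 2))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = ["a", "b", "c", "d", "e"]
        perm = [3, 1, 4, 0, 2]
        d1 = DistanceMatrix(labels, dm)
        d2 = DistanceMatrix([labels[i] for i in perm], dm[np.ix_(perm, perm)])

        def splits(newick):
            tree = TreeNode.read(io.StringIO(newick))
            return {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}

        assert splits(cluster(d1)) == splits(cluster(d2))

    def test_clear_two_cluster_structure_splits_at_root(self):
        labels = ["g1", "g2", "g3", "f1", "f2", "f3"]
        d = np.full((6, 6), 1.2)
        d[:3, :3] = 0.2
        d[3:, 3:] = 0.2
        np.fill_diagonal(d, 0.0)
        tree = TreeNode.read(io.StringIO(cluster(DistanceMatrix(labels, d))))
        sides = [frozenset(t.name for t in ch.tips()) or frozenset([ch.name])
                 for ch in tree.children]
        assert frozenset(["g1", "g2", "g3"]) in sides

    def test_unknown_linkage_rejected(self):
        d = DistanceMatrix(["x", "y"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError):
            cluster(d, "ward")


class TestMds:
    def test_three_equidistant_points(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        coords = mds(d, k=2)
        dists = [np.linalg.norm(coords[x] - coords[y])
                 for x, y in (("a", "b"), ("b", "c"), ("a", "c"))]
        assert max(dists) - min(dists) < 1e-9

    def test_exact_euclidean_matrix_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-0.5, 0.5, size=(7, 2))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(7)]
        coords = mds(DistanceMatrix(labels, dm), k=2)
        for i in range(7):
            for j in range(7):
                got = np.linalg.norm(coords[labels[i]] - coords[labels[j]])
                assert got == pytest.approx(dm[i, j], abs=1e-9)

    def test_matches_pcoa_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-0.5, 0.5, size=(6, 3))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(6)]
        coords = mds(DistanceMatrix(labels, dm), k=2)
        ord_res = pcoa(SkbioDM(dm, ids=labels), number_of_dimensions=2)
        ref = ord_res.samples.values
        got = np.array([coords[l] for l in labels])
        for axis in range(2):
            assert (np.allclose(got[:, axis], ref[:, axis], atol=1e-8)
                    or np.allclose(got[:, axis], -ref[:, axis], atol=1e-8))

    def test_k_must_be_below_label_count(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        with pytest.raises(ValidationError):
            mds(d, k=3)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-0.5, 0.5, size=(5, 2))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(5)]
        c1 = mds(DistanceMatrix(labels, dm), k=2)
        c2 = mds(DistanceMatrix(labels, dm), k=2)
        for l in labels:
            assert np.array_equal(c1[l], c2[l])
        first = c1[labels[0]]
        assert (first >= 0).all() or np.any([np.abs(c1[l]) > 1e-12 for l in labels])


class TestPairwiseScatter:
    def test_self_comparison_on_diagonal(self):
        a = _profile("A", {"GH5": 10.0, "LO2": 3.0, "GH13": 7.0})
        b = _profile("B", {"GH5": 2.0})
        m = assemble_matrix([a, b], "all")
        rows = pairwise_scatter(m, "A", "A")
        assert all(va == vb for _, va, vb, _ in rows)

    def test_absent_lo_families_visible_as_zero(self):
        gut = _profile("gut", {"GH2": 30.0, "GH10": 20.0, "GH5": 1.0})
        free = _profile("free", {"GH5": 25.0, "LO1": 5.0, "LO2": 6.0, "GH10": 8.0})
        m = assemble_matrix([gut, free], "all")
        rows = pairwise_scatter(m, "gut", "free", "biomass")
        lo_rows = [(f, va, vb) for f, va, vb, cls in rows if cls == "LO"]
        assert lo_rows and all(va == 0.0 for _, va, _ in lo_rows)
        assert {f for f, *_ in rows} == {"GH2", "GH10", "GH5", "LO1", "LO2"}

    def test_row_count_equals_filtered_union(self):
        a = _profile("A", {"GH5": 1.0, "GT2": 2.0, "GH9": 3.0})
        b = _profile("B", {"GH43": 4.0, "LO3": 5.0})
        m = assemble_matrix([a, b], "all")
        rows = pairwise_scatter(m, "A", "B", "biomass")
        assert [r[0] for r in rows] == ["GH43", "GH5", "GH9", "LO3"]

    def test_unknown_label_rejected(self):
        a = _profile("A", {"GH5": 1.0})
        b = _profile("B", {"GH5": 2.0})
        m = assemble_matrix([a, b], "all")
        with pytest.raises(ValidationError):
            pairwise_scatter(m, "A", "Z")


def test_rescaling_one_metagenome_changes_nothing():
    """Per-million normalization plus rank-based distances make the whole
    comparison invariant to scaling one metagenome's raw totals."""
    rng = np.random.default_rng(6)
    fams = [f"GH{i}" for i in range(1, 13)]
    base = {f: float(rng.uniform(10, 1000)) for f in fams}
    other = {f: float(rng.uniform(10, 1000)) for f in fams}
    third = {f: float(rng.uniform(10, 1000)) for f in fams}
    p1 = [FamilyProfile("A", base, 5e5), FamilyProfile("B", other, 5e5),
          FamilyProfile("C", third, 5e5)]
    scaled = {f: 7.3 * v for f, v in base.items()}
    p2 = [FamilyProfile("A", scaled, 7.3 * 5e5), FamilyProfile("B", other, 5e5),
          FamilyProfile("C", third, 5e5)]
    d1 = spearman_distance(assemble_matrix(p1, "gh_only"))
    d2 = spearman_distance(assemble_matrix(p2, "gh_only"))
    assert np.allclose(d1.values, d2.values, atol=1e-12)
    m1, m2 = mds(d1), mds(d2)
    for lab in d1.labels:
        assert np.allclose(m1[lab], m2[lab], atol=1e-9)
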