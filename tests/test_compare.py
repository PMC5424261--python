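"""Entropy, Jensen-Shannon divergence, weighted profile distance, and MDS."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mgssp.compare import (
    ProfileDistanceMatrix,
    classical_mds,
    distance_matrix,
    js_divergence,
    rarity_correlation,
    shannon_entropy,
    weighted_profile_distance,
)
from mgssp.profile import GSSP, PositionProfile, RarityTable


def onehot(i, n=20):
    v = np.zeros(n)
    v[i] = 1.0
    return v


def make_profile(gene, spec, dialect="imgt", n=100):
    """spec: {position: (n_covered, n_mutated, {aa: count})}"""
    positions = [
        PositionProfile(pos, frozenset("S"), cov, mut, dict(counts))
        for pos, (cov, mut, counts) in sorted(spec.items())
    ]
    return GSSP(gene, dialect, n, positions)


class TestEntropy:
    def test_closed_forms(self):
        assert shannon_entropy(onehot(3)) == 0.0
        assert shannon_entropy([0.5, 0.5] + [0.0] * 18) == pytest.approx(1.0)
        assert shannon_entropy(np.full(20, 0.05)) == pytest.approx(np.log2(20))

    def test_rejects_non_distribution(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.full(20, 0.04))
        with pytest.raises(ValueError):
            shannon_entropy([-0.5, 1.5] + [0.0] * 18)


class TestJsDivergence:
    def test_identical_distributions(self):
        p = np.full(20, 0.05)
        assert js_divergence(p, p) == 0.0

    def test_disjoint_onehot_is_one_bit(self):
        assert js_divergence(onehot(0), onehot(5)) == pytest.approx(1.0)

    def test_against_scipy_entropy_oracle(self):
        p = np.array([0.7, 0.3] + [0.0] * 18)
        q = np.array([0.3, 0.7] + [0.0] * 18)
        expected = stats.entropy((p + q) / 2, base=2) - (
            stats.entropy(p, base=2) + stats.entropy(q, base=2)
        ) / 2
        assert js_divergence(p, q) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 10.0), min_size=20, max_size=20),
           st.lists(st.floats(0.01, 10.0), min_size=20, max_size=20))
    def test_symmetric_and_bounded(self, a, b):
        p = np.array(a) / np.sum(a)
        q = np.array(b) / np.sum(b)
        j = js_divergence(p, q)
        assert 0.0 <= j <= 1.0
        assert j == pytest.approx(js_divergence(q, p), abs=1e-12)


class TestWeightedDistance:
    def test_self_distance_zero(self):
        g = make_profile("IGHV1-2", {1: (100, 40, {"G": 30, "N": 10})})
        assert weighted_profile_distance(g, g) == 0.0

    def test_single_weighted_position_dominates(self):
        # only position 2 has substitutions in both profiles
        a = make_profile("IGHV1-2", {1: (100, 0, {}), 2: (100, 20, {"G": 20})})
        b = make_profile("IGHV1-2", {1: (100, 0, {}), 2: (100, 10, {"N": 10})})
        expected = js_divergence(
            a.by_position[2].f, b.by_position[2].f
        )
        assert weighted_profile_distance(a, b) == pytest.approx(expected)

    def test_three_position_toy_matches_oracle(self):
        a = make_profile(
            "IGHV1-2",
            {1: (100, 10, {"G": 8, "N": 2}),
             2: (100, 50, {"A": 25, "T": 25}),
             3: (100, 30, {"G": 30})},
        )
        b = make_profile(
            "IGHV1-2",
            {1: (100, 20, {"G": 10, "N": 10}),
             2: (100, 40, {"A": 40}),
             3: (100, 30, {"N": 30})},
        )
        # independent oracle: explicit sum over positions
        num = den = 0.0
        for pos in (1, 2, 3):
            pa, pb = a.by_position[pos], b.by_position[pos]
            w = (pa.m + pb.m) / 2
            h = stats.entropy((pa.f + pb.f) / 2, base=2) - (
                stats.entropy(pa.f[pa.f > 0], base=2)
                + stats.entropy(pb.f[pb.f > 0], base=2)
            ) / 2
            num += w * h
            den += w
        assert weighted_profile_distance(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_one_sided_zero_positions_excluded(self):
        shared = {1: (100, 20, {"G": 20})}
        a = make_profile("IGHV1-2", {**shared, 2: (100, 10, {"N": 10})})
        b = make_profile("IGHV1-2", {**shared, 2: (100, 0, {})})
        base = make_profile("IGHV1-2", shared)
        assert weighted_profile_distance(a, b) == pytest.approx(
            weighted_profile_distance(base, base)
        )

    def test_cross_gene_requires_imgt(self):
        a = make_profile("geneA", {1: (10, 5, {"G": 5})}, dialect="sequential")
        b = make_profile("geneB", {1: (10, 5, {"G": 5})}, dialect="sequential")
        with pytest.raises(ValueError, match="IMGT"):
            weighted_profile_distance(a, b)

    def test_no_shared_positions_errors(self):
        a = make_profile("geneA", {1: (10, 5, {"G": 5})})
        b = make_profile("geneB", {2: (10, 5, {"G": 5})})
        with pytest.raises(ValueError, match="no qualifying"):
            weighted_profile_distance(a, b)


class TestDistanceMatrix:
    def _profiles(self):
        rng = np.random.default_rng(0)
        out = []
        for i in range(4):
            spec = {
                pos: (100, int(rng.integers(5, 50)),
                      {"G": int(rng.integers(1, 20)), "N": int(rng.integers(1, 20))})
                for pos in range(1, 6)
            }
            for pos, (cov, _, counts) in spec.items():
                spec[pos] = (cov, sum(counts.values()), counts)
            out.append(make_profile(f"g{i}", spec))
        return out

    def test_duplicate_profile_entry_is_zero(self):
        p = self._profiles()[0]
        dm = distance_matrix([p, p])
        assert dm.values[0, 1] == 0.0

    def test_symmetry_zero_diagonal_and_bounds(self):
        dm = distance_matrix(self._profiles())
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert np.all((dm.values >= 0.0) & (dm.values <= 1.0))

    def test_label_permutation_equivariance(self):
        profiles = self._profiles()
        dm = distance_matrix(profiles)
        perm = [2, 0, 3, 1]
        dm_p = distance_matrix([profiles[i] for i in perm])
        assert np.allclose(dm_p.values, dm.values[np.ix_(perm, perm)])


class TestClassicalMds:
    def test_all_zero_matrix(self):
        dm = ProfileDistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        emb = classical_mds(dm)
        assert np.allclose(emb.coordinates, 0.0)

    def test_two_points(self):
        dm = ProfileDistanceMatrix(["a", "b"], np.array([[0.0, 0.8], [0.8, 0.0]]))
        emb = classical_mds(dm, dims=1)
        assert sorted(emb.coordinates[:, 0]) == pytest.approx([-0.4, 0.4])

    def test_planar_points_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = classical_mds(ProfileDistanceMatrix(list("abcde"), d))
        d2 = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1
        )
        assert np.max(np.abs(d - d2)) < 1e-6

    def test_embedding_is_centered(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = classical_mds(ProfileDistanceMatrix(list("abcdef"), d))
        assert np.allclose(emb.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_matches_r_cmdscale(self, tmp_path):
        """Cross-check against R's cmdscale on the same matrix (embeddings
        compared via their pairwise distances, which are rotation-free)."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(5, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.savetxt(tmp_path / "d.tsv", d, delimiter="\t")
        script = (
            f'd <- as.matrix(read.table("{tmp_path}/d.tsv"));'
            'fit <- cmdscale(as.dist(d), k=2);'
            f'write.table(fit, "{tmp_path}/fit.tsv", sep="\\t", '
            "row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r_coords = np.loadtxt(tmp_path / "fit.tsv")
        emb = classical_mds(ProfileDistanceMatrix(list("abcde"), d))
        dist_r = np.linalg.norm(r_coords[:, None] - r_coords[None, :], axis=-1)
        dist_py = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1
        )
        assert np.allclose(dist_py, dist_r, atol=1e-6)


class TestRarityCorrelation:
    def _table(self, values):
        return RarityTable({("g", i + 1, "G"): v for i, v in enumerate(values)})

    def test_self_correlation_is_one(self):
        t = self._table([0.2, 0.5, 0.9, 1.0])
        assert rarity_correlation(t, t) == pytest.approx(1.0)

    def test_anti_ordered_tables_give_minus_one(self):
        values = np.array([0.1, 0.4, 0.6, 0.9])
        assert rarity_correlation(
            self._table(values), self._table(1.0 - values)
        ) == pytest.approx(-1.0)

    def test_too_few_shared_entries_errors(self):
        with pytest.raises(ValueError, match="need >= 3"):
            rarity_correlation(self._table([0.5]), self._table([0.5]))
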