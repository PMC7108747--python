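"""Descriptive statistics on partitioned pangenomes."""

import numpy as np
import pytest

from pangem.genome import Contig, Gene, Genome
from pangem.graph import build_graph
from pangem.matrix import PAMatrix
from pangem.partition import Partitioning
from pangem.stats import (
    mash_distance_to_ani_percent,
    partition_degree_stats,
    shell_jaccard_distances,
    shell_structure_correlation,
    summary_table,
)


def _part(family_ids, labels):
    labels = np.array(labels, dtype=object)
    comp = np.where(labels == "persistent", 1, np.where(labels == "cloud", 3, 2))
    return Partitioning(
        family_ids=list(family_ids),
        K=3,
        labels=labels,
        components=comp,
        posteriors=np.zeros((len(labels), 3)),
    )


def _genome(gid, fams):
    genes = [
        Gene(f"{gid}_{i}", gid, "c", 1 + 10 * i, 5 + 10 * i, "+", f)
        for i, f in enumerate(fams)
    ]
    return Genome(gid, [Contig("c", genes)])


class TestDegreeStats:
    def test_triangle_of_persistent(self):
        graph = build_graph(
            [_genome("g1", ["A", "B", "C"]), _genome("g2", ["B", "C", "A"])]
        )
        df = partition_degree_stats(graph, _part("ABC", ["persistent"] * 3))
        row = df[df.partition == "persistent"].iloc[0]
        assert row.mean_intra_degree == pytest.approx(2.0)
        assert row.n_components == 1

    def test_isolated_cloud_singletons(self):
        graph = build_graph([_genome("g1", ["A"]), _genome("g2", ["B"]), _genome("g3", ["C"])])
        df = partition_degree_stats(graph, _part("ABC", ["cloud"] * 3))
        row = df[df.partition == "cloud"].iloc[0]
        assert row.mean_intra_degree == 0.0
        assert row.n_singletons == 3

    def test_shell_path(self):
        graph = build_graph([_genome("g1", ["A", "B", "C", "D"])])
        df = partition_degree_stats(graph, _part("ABCD", ["shell"] * 4))
        row = df[df.partition == "shell"].iloc[0]
        assert row.mean_intra_degree == pytest.approx(1.5)
        assert row.n_components == 1 and row.largest_component == 4

    def test_empty_partition_reported_absent(self):
        graph = build_graph([_genome("g1", ["A", "B"])])
        df = partition_degree_stats(graph, _part("AB", ["persistent", "persistent"]))
        assert np.isnan(df[df.partition == "cloud"].mean_intra_degree.iloc[0])


class TestShellCorrelation:
    def _fixture(self):
        # persistent everywhere; shell block S1 in clade {g0,g1}, S2 in {g2,g3}
        fams = ["P1", "P2", "S1a", "S1b", "S2a", "S2b", "C1"]
        X = np.array(
            [
                [1, 1, 1, 1],
                [1, 1, 1, 1],
                [1, 1, 0, 0],
                [1, 1, 0, 0],
                [0, 0, 1, 1],
                [0, 0, 1, 1],
                [1, 0, 0, 0],
            ]
        )
        pa = PAMatrix(X, fams, [f"g{j}" for j in range(4)])
        labels = ["persistent"] * 2 + ["shell"] * 4 + ["cloud"]
        return pa, _part(fams, labels)

    def test_identical_shell_vectors_zero_distance(self):
        pa, part = self._fixture()
        J = shell_jaccard_distances(pa, part)
        assert J[0, 1] == 0.0 and J[2, 3] == 0.0
        assert J[0, 2] == 1.0

    def test_self_correlation_is_one(self):
        pa, part = self._fixture()
        J = shell_jaccard_distances(pa, part)
        rho, _ = shell_structure_correlation(pa, part, J)
        assert rho == pytest.approx(1.0)

    def test_clade_structure_detected(self, rng):
        """Shell blocks aligned with two genome clades correlate strongly
        with the clade distance matrix."""
        N = 20
        clade = np.array([0] * 10 + [1] * 10)
        rows, fams, labels = [], [], []
        for i in range(30):
            rows.append(np.ones(N, dtype=int))
            fams.append(f"P{i}")
            labels.append("persistent")
        for i in range(40):
            c = i % 2
            row = (clade == c).astype(int)
            flip = rng.random(N) < 0.1
            rows.append(np.where(flip, 1 - row, row))
            fams.append(f"S{i}")
            labels.append("shell")
        X = np.array(rows)
        keep = X.sum(axis=1) > 0
        pa = PAMatrix(X[keep], [f for f, k in zip(fams, keep) if k], [f"g{j}" for j in range(N)])
        part = _part(pa.family_ids, [l for l, k in zip(labels, keep) if k])
        D = np.where(clade[:, None] == clade[None, :], 0.05, 0.8)
        np.fill_diagonal(D, 0.0)
        rho, p = shell_structure_correlation(pa, part, D)
        assert rho > 0.75
        assert p < 1e-6

    def test_no_shell_families_rejected(self):
        pa = PAMatrix(np.ones((2, 3), dtype=int), ["A", "B"], ["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="shell"):
            shell_structure_correlation(pa, _part("AB", ["persistent", "cloud"]), np.zeros((3, 3)))

    def test_jaccard_is_a_metric(self, rng):
        """Triangle inequality on random binary genome profiles."""
        X = rng.integers(0, 2, size=(25, 12))
        X[:, X.sum(axis=0) == 0] = 1
        X[X.sum(axis=1) == 0, 0] = 1
        pa = PAMatrix(X, [f"f{i}" for i in range(25)], [f"g{j}" for j in range(12)])
        part = _part(pa.family_ids, ["shell"] * 25)
        J = shell_jaccard_distances(pa, part)
        assert (J >= 0).all() and (J <= 1).all()
        n = J.shape[0]
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    assert J[a, c] <= J[a, b] + J[b, c] + 1e-12


class TestSummaryTable:
    def test_all_persistent_all_ones(self):
        pa = PAMatrix(np.ones((6, 4), dtype=int), [f"f{i}" for i in range(6)], list("wxyz"))
        per_genome, overview = summary_table(_part(pa.family_ids, ["persistent"] * 6), pa)
        assert (per_genome["persistent"] == 6).all()
        row = overview[overview.partition == "persistent"].iloc[0]
        assert row.median_per_genome == 6 and row.iqr_per_genome == 0

    def test_counts_reflect_presence_only(self):
        X = np.array([[1, 0], [1, 1], [1, 1], [0, 1]])
        pa = PAMatrix(X, list("abcd"), ["g1", "g2"])
        per_genome, _ = summary_table(
            _part(pa.family_ids, ["persistent", "persistent", "shell", "cloud"]), pa
        )
        g1 = per_genome[per_genome.genome_id == "g1"].iloc[0]
        assert (g1.persistent, g1.shell, g1.cloud, g1.total) == (2, 1, 0, 3)

    def test_per_genome_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(40, 8))
        X[X.sum(axis=1) == 0, 0] = 1
        pa = PAMatrix(X, [f"f{i}" for i in range(40)], [f"g{j}" for j in range(8)])
        labels = rng.choice(["persistent", "shell", "cloud"], size=40)
        per_genome, _ = summary_table(_part(pa.family_ids, labels), pa)
        assert (
            per_genome[["persistent", "shell", "cloud"]].sum(axis=1) == per_genome.total
        ).all()

    def test_soft_core_includes_one_absence_in_twenty(self):
        X = np.ones((3, 20), dtype=int)
        X[0, 5] = 0
        pa = PAMatrix(X, list("abc"), [f"g{j}" for j in range(20)])
        _, overview = summary_table(_part(pa.family_ids, ["persistent"] * 3), pa)
        assert overview.attrs["soft_core_size"] == 3


def test_mash_conspecific_cutoff_maps_to_94_percent_ani():
    assert mash_distance_to_ani_percent(0.06) == pytest.approx(94.0)
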