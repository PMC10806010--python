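"""Hamming matrices, dynamic thresholds and clone clustering vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myotcr.clustering import (
    cluster_clones,
    cross_patient_sharing,
    dynamic_threshold,
    hamming_matrix,
)
from myotcr.model import AA_ALPHABET
from myotcr.simulate import CohortConfig, generate_cohort


def hamming_naive(a, b):
    if len(a) != len(b):
        return np.inf
    return sum(x != y for x, y in zip(a, b))


def union_find_components(matrix, threshold):
    """Independent union-find oracle for single-linkage clustering."""
    n = matrix.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i, j] < threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(map(frozenset, groups.values()), key=min)


def random_cdr3s(rng, n, lengths=(12, 13, 14)):
    return [
        "".join(rng.choice(list(AA_ALPHABET), size=rng.choice(lengths)))
        for _ in range(n)
    ]


class TestHammingMatrix:
    def test_identity_and_single_mismatch(self):
        m = hamming_matrix(["CASSL", "CASSL", "CASSV"])
        assert m[0, 1] == 0 and m[0, 2] == 1 and m[1, 2] == 1

    def test_unequal_lengths_are_infinite(self):
        m = hamming_matrix(["CASSL", "CASSLL"])
        assert np.isinf(m[0, 1])

    def test_levenshtein_mode_for_unequal_lengths(self):
        m = hamming_matrix(["CASSL", "CASSLL"], unequal="levenshtein")
        assert m[0, 1] == 1

    def test_matches_naive_oracle_on_random_strings(self):
        rng = np.random.default_rng(0)
        seqs = random_cdr3s(rng, 30)
        m = hamming_matrix(seqs)
        for i in range(30):
            for j in range(30):
                assert m[i, j] == hamming_naive(seqs[i], seqs[j])

    def test_symmetric_zero_diagonal(self):
        m = hamming_matrix(random_cdr3s(np.random.default_rng(1), 20))
        assert np.array_equal(m, m.T) and (np.diag(m) == 0).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            hamming_matrix([])


def planted_bimodal_matrix(rng, n=40, low=(1, 4), high=(11, 15)):
    """Symmetric matrix with within-block distances in `low`, between in `high`."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    same_block = ((iu[0] < n // 2) & (iu[1] < n // 2)) | (
        (iu[0] >= n // 2) & (iu[1] >= n // 2)
    )
    vals = np.where(
        same_block,
        rng.integers(*low, size=len(iu[0])),
        rng.integers(*high, size=len(iu[0])),
    )
    m[iu] = vals
    return m + m.T


def kde_valley_oracle(matrix, grid_step=0.001):
    """Dense-grid search of the same Gaussian density, built from scratch."""
    iu = np.triu_indices(matrix.shape[0], 1)
    d = matrix[iu]
    d = d[np.isfinite(d)]
    n = d.size
    sigma = np.sqrt(np.cov(d, ddof=1)) * (n * 3.0 / 4.0) ** (-1.0 / 5.0)
    grid = np.arange(0.0, d.max() + grid_step, grid_step)
    dens = np.exp(-((grid[:, None] - d[None, :]) ** 2) / (2 * sigma**2)).mean(axis=1)
    dens /= sigma * np.sqrt(2 * np.pi)
    maxima = [
        i for i in range(1, len(grid) - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    top2 = sorted(sorted(maxima, key=lambda i: -dens[i])[:2])
    lo, hi = top2
    inner = np.argmin(dens[lo + 1:hi]) + lo + 1
    return float(grid[inner])


class TestDynamicThreshold:
    def test_planted_valley_recovered(self):
        rng = np.random.default_rng(3)
        m = planted_bimodal_matrix(rng)
        est = dynamic_threshold(m)
        oracle = kde_valley_oracle(m)
        assert est.mode == "bimodal_valley"
        assert est.valley_position == pytest.approx(oracle, abs=0.011)
        assert est.threshold == int(np.floor(est.valley_position + 0.5))

    def test_tight_unimodal_falls_back_to_floor(self):
        rng = np.random.default_rng(4)
        n = 20
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.integers(1, 3, size=len(iu[0]))
        est = dynamic_threshold(m + m.T)
        assert est.threshold == 3
        assert est.mode in ("unimodal_fallback", "floor_applied")

    def test_low_valley_floored_at_three(self):
        # two modes close together so the valley lands below 3
        rng = np.random.default_rng(5)
        m = planted_bimodal_matrix(rng, low=(1, 2), high=(4, 6))
        est = dynamic_threshold(m)
        assert est.threshold == 3
        if est.valley_position is not None:
            assert est.valley_position < 3.5

    def test_deterministic_for_fixed_multiset(self):
        m = planted_bimodal_matrix(np.random.default_rng(6))
        a, b = dynamic_threshold(m), dynamic_threshold(m)
        assert a.threshold == b.threshold and a.valley_position == b.valley_position

    def test_all_infinite_distances_error(self):
        m = np.full((3, 3), np.inf)
        np.fill_diagonal(m, 0)
        with pytest.raises(ValueError):
            dynamic_threshold(m)


class TestClusterClones:
    def test_threshold_one_clusters_only_identical(self):
        m = hamming_matrix(["CASSL", "CASSL", "CASSV"])
        res = cluster_clones(m, threshold=1)
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_chain_transitive_closure(self):
        m = np.array([[0, 2, 4], [2, 0, 2], [4, 2, 0]], dtype=float)
        res = cluster_clones(m, threshold=3)
        assert len(set(res.labels)) == 1

    def test_edge_rule_le_includes_boundary(self):
        m = np.array([[0, 3], [3, 0]], dtype=float)
        assert len(set(cluster_clones(m, 3, edge_rule="lt").labels)) == 2
        assert len(set(cluster_clones(m, 3, edge_rule="le").labels)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seqs = random_cdr3s(rng, 100, lengths=(5, 6))
        m = hamming_matrix(seqs)
        for threshold in (1, 2, 3, 4):
            res = cluster_clones(m, threshold)
            got = sorted(map(frozenset, res.members().values()), key=min)
            assert got == union_find_components(m, threshold)

    def test_raising_threshold_never_splits_clusters(self):
        rng = np.random.default_rng(7)
        m = hamming_matrix(random_cdr3s(rng, 40, lengths=(6,)))
        prev = cluster_clones(m, 1).labels
        for threshold in range(2, int(m.max()) + 2):
            cur = cluster_clones(m, threshold).labels
            # every previous cluster stays within one current cluster
            for c in np.unique(prev):
                assert len(set(cur[prev == c])) == 1
            prev = cur

    def test_input_order_invariance(self):
        seqs = ["CASSA", "CASSG", "CTWYH", "CTWYQ"]
        m1 = hamming_matrix(seqs)
        perm = [2, 0, 3, 1]
        m2 = hamming_matrix([seqs[i] for i in perm])
        r1 = cluster_clones(m1, 3)
        r2 = cluster_clones(m2, 3)
        part1 = {frozenset(seqs[i] for i in grp) for grp in r1.members().values()}
        part2 = {frozenset(seqs[perm[i]] for i in grp) for grp in r2.members().values()}
        assert part1 == part2


class TestCrossPatientSharing:
    def test_mutually_distant_clones_no_multi_patient_clusters(self):
        rng = np.random.default_rng(8)
        seqs = random_cdr3s(rng, 30, lengths=(14,))
        subjects = [f"P{i % 10}" for i in range(30)]
        clusters, edges, res = cross_patient_sharing(seqs, subjects, threshold=3)
        assert (clusters["n_patients"] <= 1).all()

    def test_planted_public_motif_links_exactly_its_patients(self):
        config = CohortConfig(n_patients=8, n_controls=0, clones_per_sample=400,
                              depth_reads=12_000, public_motif_patients=5)
        samples, _, truth = generate_cohort(config, seed=21)
        public = truth.clones[truth.clones["public"]]
        assert public["subject_id"].nunique() == 5
        dominant = truth.clones[
            (truth.clones["origin"] == "muscle") & truth.clones["dominant_model"]
        ]
        clusters, _, _ = cross_patient_sharing(
            list(dominant["cdr3_aa"]), list(dominant["subject_id"])
        )
        expected = frozenset(public["subject_id"])
        multi = clusters[clusters["n_patients"] >= 2]
        assert any(
            frozenset(row.patient_ids.split(",")) == expected
            for row in multi.itertuples()
        )

    def test_one_edge_per_close_pair(self):
        seqs = ["CASSA", "CASSG", "CASST", "CWWWW"]
        clusters, edges, res = cross_patient_sharing(seqs, ["a", "b", "c", "d"],
                                                     threshold=2)
        close = {(i, j) for i in range(4) for j in range(i + 1, 4)
                 if hamming_naive(seqs[i], seqs[j]) < 2}
        assert set(zip(edges["i"], edges["j"])) == close
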