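"""Bray-Curtis, donor trajectories, PCoA, PERMANOVA and dispersion
homogeneity, checked against brute force and scikit-bio oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pouchtrack import (
    DistanceMatrix, bray_curtis, distance_matrix, donor_dissimilarity,
    donor_dissimilarity_trajectory, pcoa, permanova, betadisper,
)
from pouchtrack.beta import n_distinct_arrangements

from conftest import make_table, make_meta, random_table


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    ids = ids or [f"s{i}" for i in range(len(points))]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(ids, d)


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([3, 1, 0], [3, 1, 0]) == 0.0
        assert bray_curtis([1, 0], [0, 5]) == 1.0

    def test_hand_value_on_fractions(self):
        # (6,2,0) vs (2,2,2): 1 - 2(1/3 + 1/4 + 0)/2 = 5/12
        assert bray_curtis([6, 2, 0], [2, 2, 2]) == pytest.approx(5 / 12, abs=1e-12)

    def test_matches_scipy_oracle(self, rng):
        from scipy.spatial.distance import braycurtis as scipy_bc

        for _ in range(30):
            x = rng.integers(0, 20, size=10).astype(float)
            y = rng.integers(0, 20, size=10).astype(float)
            if x.sum() == 0 or y.sum() == 0:
                continue
            ours = bray_curtis(x, y, fractions=False)
            assert ours == pytest.approx(scipy_bc(x, y), abs=1e-12)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestDistanceMatrix:
    def test_matches_brute_force_double_loop(self, rng):
        t = random_table(rng, n_taxa=15, n_samples=8)
        dm = distance_matrix(t, rank=None)
        rel = t.counts / t.counts.sum(axis=0)
        for i, a in enumerate(t.samples):
            for j, b in enumerate(t.samples):
                expected = 0.0 if i == j else bray_curtis(rel[a], rel[b], fractions=False)
                assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matches_skbio(self, rng):
        from skbio.diversity import beta_diversity

        t = random_table(rng, n_taxa=15, n_samples=8)
        rel = (t.counts / t.counts.sum(axis=0)).to_numpy().T
        sk = beta_diversity("braycurtis", rel, ids=t.samples)
        dm = distance_matrix(t, rank=None)
        assert np.allclose(dm.data, sk.data, atol=1e-10)

    def test_duplicate_sample_distance_zero(self):
        t = make_table({"a": [5, 5], "b": [5, 5], "c": [1, 9]})
        dm = distance_matrix(t, rank=None)
        assert dm.loc("a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        t = random_table(rng, n_taxa=10, n_samples=5)
        dm1 = distance_matrix(t, rank=None)
        order = ["S3", "S1", "S5", "S2", "S4"]
        dm2 = distance_matrix(t.subset_samples(order), rank=None)
        for a in order:
            for b in order:
                assert dm1.loc(a, b) == pytest.approx(dm2.loc(a, b), abs=1e-14)


class TestDonorDissimilarity:
    def test_mean_of_pairwise(self):
        d = np.zeros((4, 4))
        d[0, 1:] = d[1:, 0] = [0.2, 0.4, 0.6]
        d[1, 2] = d[2, 1] = 0.3
        d[1, 3] = d[3, 1] = 0.3
        d[2, 3] = d[3, 2] = 0.3
        dm = DistanceMatrix(["p", "d1", "d2", "d3"], d)
        assert donor_dissimilarity("p", ["d1", "d2", "d3"], dm) == pytest.approx(0.4)
        assert donor_dissimilarity("p", ["d1"], dm) == pytest.approx(0.2)

    def test_unknown_id_errors(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(KeyError):
            donor_dissimilarity("zz", ["a"], dm)


class TestTrajectory:
    def _cohort(self):
        lin = None
        cols = {}
        rng = np.random.default_rng(5)
        for sid in ["d1", "d2"]:
            cols[sid] = rng.integers(1, 50, 6)
        for subj, relapse in (("p1", 4), ("p2", None)):
            for wk in (0, 4, 12, 26, 52):
                cols[f"{subj}_w{wk}"] = rng.integers(1, 50, 6)
        t = make_table(cols, lin)
        rows = [
            {"sample_id": "d1", "subject_id": "donor", "arm": "donor", "week": 1},
            {"sample_id": "d2", "subject_id": "donor", "arm": "donor", "week": 2},
        ]
        for subj, relapse in (("p1", 4), ("p2", None)):
            for wk in (0, 4, 12, 26, 52):
                rows.append({
                    "sample_id": f"{subj}_w{wk}", "subject_id": subj, "arm": "FMT",
                    "week": wk, "relapse_week": "none" if relapse is None else str(relapse),
                })
        return t, make_meta(rows)

    def test_post_relapse_exclusion_keeps_relapse_week(self):
        t, meta = self._cohort()
        traj, _ = donor_dissimilarity_trajectory(t, meta, ["d1", "d2"], True, rank=None)
        p1 = traj[traj["subject_id"] == "p1"]["week"].tolist()
        assert sorted(p1) == [0, 4]  # relapse at week 4: later samples excluded
        p2 = traj[traj["subject_id"] == "p2"]["week"].tolist()
        assert sorted(p2) == [0, 4, 12, 26, 52]

    def test_flag_off_keeps_all(self):
        t, meta = self._cohort()
        traj, _ = donor_dissimilarity_trajectory(t, meta, ["d1", "d2"], False, rank=None)
        assert sorted(traj[traj["subject_id"] == "p1"]["week"]) == [0, 4, 12, 26, 52]

    def test_pairwise_mean_equals_manual(self):
        t, meta = self._cohort()
        traj, _ = donor_dissimilarity_trajectory(t, meta, ["d1", "d2"], True, rank=None)
        dm = distance_matrix(t, rank=None)
        row = traj[traj["sample_id"] == "p2_w0"].iloc[0]
        manual = np.mean([dm.loc("p2_w0", "d1"), dm.loc("p2_w0", "d2")])
        assert row["dissimilarity"] == pytest.approx(manual, abs=1e-12)


class TestPCoA:
    def test_recovers_line(self):
        x = np.array([[0.0], [1.0], [2.0], [5.0]])
        dm = euclidean_dm(x)
        ordn = pcoa(dm, 2)
        # axis 1 recovers the line up to rigid motion; remaining eigenvalues ~ 0
        d1 = np.abs(np.diff(np.sort(ordn.coordinates[:, 0])))
        assert np.allclose(np.sort(d1), [1.0, 1.0, 3.0], atol=1e-8)
        assert ordn.eigenvalues.size == 1 or ordn.eigenvalues[1] < 1e-8

    def test_distances_reproduced_for_euclidean_input(self, rng):
        pts = rng.normal(size=(7, 3))
        dm = euclidean_dm(pts)
        ordn = pcoa(dm, 6)
        c = ordn.coordinates
        rec = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, dm.data, atol=1e-8)

    def test_identical_samples_identical_coordinates(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
        ordn = pcoa(euclidean_dm(pts), 2)
        assert np.allclose(ordn.coordinates[0], ordn.coordinates[1], atol=1e-10)

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as sk_pcoa
        from skbio.stats.distance import DistanceMatrix as SkDM

        t = random_table(rng, n_taxa=12, n_samples=7)
        dm = distance_matrix(t, rank=None)
        ours = pcoa(dm, 3)
        sk = sk_pcoa(SkDM(dm.data, ids=dm.sample_ids))
        sk_pos = np.array([e for e in sk.eigvals if e > 1e-10])
        assert np.allclose(ours.eigenvalues, sk_pos[: ours.eigenvalues.size], atol=1e-8)
        assert np.allclose(np.abs(ours.coordinates[:, 0]),
                           np.abs(sk.samples.values[:, 0]), atol=1e-8)


def brute_force_permanova(d: np.ndarray, labels: np.ndarray):
    """Straight-from-definition PERMANOVA on squared distances."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    a = len(groups)
    f = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    return f, 1 - ss_within / ss_total


class TestPermanova:
    def test_clone_clusters_maximal_r2(self):
        pts = np.array([[0, 0], [0.01, 0], [0, 0.01], [10, 10], [10.01, 10], [10, 10.01]], float)
        dm = euclidean_dm(pts)
        res = permanova(dm, ["A", "A", "A", "B", "B", "B"], n_perm=999, seed=1)
        assert res.r_squared > 0.99
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 20)  # the two extreme arrangements tie F_obs

    def test_exact_p_matches_brute_force_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = euclidean_dm(pts)
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        res = permanova(dm, labels, n_perm=999, seed=0)
        f_obs, r2 = brute_force_permanova(dm.data, labels)
        assert res.pseudo_f == pytest.approx(f_obs, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        # brute force over all C(6,3)=20 distinct arrangements
        hits = total = 0
        for idx in itertools.combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            for i in idx:
                lab[i] = "A"
            f, _ = brute_force_permanova(dm.data, lab)
            total += 1
            if f >= f_obs - 1e-12:
                hits += 1
        assert n_distinct_arrangements(labels) == 20 == total
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_matches_skbio_pseudo_f(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM, permanova as sk_permanova

        t = random_table(rng, n_taxa=12, n_samples=9)
        dm = distance_matrix(t, rank=None)
        labels = ["A"] * 4 + ["B"] * 5
        res = permanova(dm, np.array(labels), n_perm=99, seed=0)
        sk = sk_permanova(SkDM(dm.data, ids=dm.sample_ids), grouping=labels, permutations=99)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], abs=1e-8)

    def test_r2_identity(self, rng):
        t = random_table(rng, n_taxa=10, n_samples=8)
        dm = distance_matrix(t, rank=None)
        labels = np.array(["A", "B"] * 4)
        res = permanova(dm, labels, n_perm=99, seed=3)
        f, r2 = brute_force_permanova(dm.data, labels)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)
        assert 0.0 <= res.r_squared <= 1.0

    def test_invariant_to_reordering_and_relabeling(self, rng):
        t = random_table(rng, n_taxa=10, n_samples=8)
        dm = distance_matrix(t, rank=None)
        labels = pd.Series(["A", "B"] * 4, index=dm.sample_ids)
        res1 = permanova(dm, labels, n_perm=199, seed=5)
        order = list(reversed(dm.sample_ids))
        dm2 = dm.subset(order)
        res2 = permanova(dm2, labels, n_perm=199, seed=5)
        res3 = permanova(dm, labels.map({"A": "x", "B": "y"}), n_perm=199, seed=5)
        assert res1.p_value == res2.p_value == res3.p_value
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f, abs=1e-12)

    def test_small_group_errors(self):
        dm = euclidean_dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["A", "A", "A", "B"], 99, 0)


class TestBetadisper:
    def test_brute_force_distances_on_euclidean_fixture(self):
        pts = np.array([[0, 0], [2, 0], [1, 2], [10, 10], [14, 10], [12, 13]], float)
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        dm = euclidean_dm(pts)
        res = betadisper(dm, labels, n_perm=99, seed=0)
        # PCoA of a Euclidean matrix reproduces the geometry, so the
        # centroid distances equal those computed directly on the points.
        for g in ("A", "B"):
            idx = labels == g
            centroid = pts[idx].mean(axis=0)
            expected = np.sqrt(((pts[idx] - centroid) ** 2).sum(1)).mean()
            assert res.group_means[g] == pytest.approx(expected, abs=1e-8)

    def test_mirror_groups_equal_dispersion(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]], float)
        res = betadisper(euclidean_dm(pts), ["A"] * 3 + ["B"] * 3, n_perm=199, seed=2)
        assert res.group_means["A"] == pytest.approx(res.group_means["B"], abs=1e-8)
        assert res.p_value > 0.2

    def test_duplicated_points_zero_dispersion(self):
        pts = np.array([[1, 1], [1, 1], [1, 1], [0, 0], [4, 0], [2, 3]], float)
        res = betadisper(euclidean_dm(pts), ["A"] * 3 + ["B"] * 3, n_perm=99, seed=0)
        assert res.group_means["A"] == pytest.approx(0.0, abs=1e-9)
        assert res.group_means["B"] > 0.5
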