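import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans as SKKMeans
from sklearn.metrics import adjusted_rand_score

from somgait.clustering import (
    assign_limbs,
    canonicalize_labels,
    cluster_som,
    kmeans,
    select_k,
)
from somgait.scores import GVS_NAMES, GVSVector
from somgait.som import SOMTrainConfig, train_som, bmu_batch


def exhaustive_kmeans_optimum(points: np.ndarray, k: int) -> float:
    """Brute-force minimum within-cluster sum of squares over all partitions."""
    best = np.inf
    n = len(points)
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        labels = np.asarray(assignment)
        total = 0.0
        for j in range(k):
            pts = points[labels == j]
            total += float(np.sum((pts - pts.mean(axis=0)) ** 2))
        best = min(best, total)
    return best


class TestKMeans:
    def test_k1_closed_form(self):
        pts = np.random.default_rng(0).normal(0, 2, (12, 3))
        cm = kmeans(pts, 1, seed=0)
        np.testing.assert_allclose(cm.centroids[0], pts.mean(axis=0))
        assert cm.inertia == pytest.approx(np.sum((pts - pts.mean(axis=0)) ** 2))

    def test_k_equals_m_zero_inertia(self):
        pts = np.arange(12.0).reshape(6, 2)
        cm = kmeans(pts, 6, seed=0, n_init=5)
        assert cm.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(cm.labels.tolist())) == 6

    def test_k_above_m_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((3, 2)), 4)

    def test_two_tight_triples_optimal(self):
        rng = np.random.default_rng(5)
        pts = np.vstack(
            [rng.normal(0, 0.05, (3, 2)), rng.normal(20, 0.05, (3, 2))]
        )
        cm = kmeans(pts, 2, seed=0, n_init=5)
        assert cm.inertia == pytest.approx(exhaustive_kmeans_optimum(pts, 2))
        assert len(set(cm.labels[:3].tolist())) == 1
        assert len(set(cm.labels[3:].tolist())) == 1

    def test_matches_exhaustive_optimum_on_small_instances(self):
        """With >= 20 restarts the global optimum is found in >= 95% of seeds."""
        hits = 0
        n_trials = 20
        for seed in range(n_trials):
            rng = np.random.default_rng(100 + seed)
            pts = rng.normal(0, 1, (8, 2))
            cm = kmeans(pts, 3, seed=seed, n_init=20)
            opt = exhaustive_kmeans_optimum(pts, 3)
            if cm.inertia <= opt + 1e-9:
                hits += 1
        assert hits >= int(np.ceil(0.95 * n_trials))

    def test_agrees_with_sklearn_cross_check(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, (60, 5))
        ours = kmeans(pts, 4, seed=0, n_init=20)
        theirs = SKKMeans(n_clusters=4, n_init=20, random_state=0).fit(pts)
        assert ours.inertia == pytest.approx(theirs.inertia_, rel=0.02)


class TestClusterSOM:
    def test_k1_uniform_labels(self, trained_som):
        cm, grid = cluster_som(trained_som, 1, seed=0)
        assert set(cm.labels.tolist()) == {0}
        assert grid.shape == (10, 10)

    def test_two_blob_codebook_labels_bmu_regions_uniformly(self):
        rng = np.random.default_rng(7)
        data = np.vstack(
            [rng.normal(0, 1, (50, 13)), rng.normal(10, 1, (50, 13))]
        )
        model = train_som(data, SOMTrainConfig(seed=3))
        cm, _ = cluster_som(model, 2, seed=0)
        units1 = bmu_batch(model, data[:50])
        units2 = bmu_batch(model, data[50:])
        assert len(set(cm.labels[units1].tolist())) == 1
        assert len(set(cm.labels[units2].tolist())) == 1
        assert cm.labels[units1[0]] != cm.labels[units2[0]]

    def test_labels_compare_up_to_permutation(self, trained_som):
        cm1, _ = cluster_som(trained_som, 4, seed=0)
        cm2, _ = cluster_som(trained_som, 4, seed=99)
        ari = adjusted_rand_score(cm1.labels, cm2.labels)
        assert ari > 0.5  # same structure, possibly permuted labels


class TestAssignLimbs:
    def _vector(self, limb_id, values):
        return GVSVector(limb_id, "barefoot", dict(zip(GVS_NAMES, values)))

    def test_codebook_vector_gets_unit_label(self, trained_som):
        cm, _ = cluster_som(trained_som, 3, seed=0)
        raw = trained_som.denormalize(trained_som.codebook[42])[0]
        raw = np.clip(raw, 0.0, None)  # GVSVector requires non-negative scores
        z = trained_som.normalize(raw)[0]
        unit = int(np.argmin(np.sum((trained_som.codebook - z) ** 2, axis=1)))
        assignment = assign_limbs(trained_som, cm, [self._vector("L", raw)])
        assert assignment["L"] == (unit, int(cm.labels[unit]))

    def test_duplicate_limbs_identical(self, trained_som, cohort_scores):
        cm, _ = cluster_som(trained_som, 6, seed=0)
        gvs = cohort_scores["gvs"][:5]
        twin = GVSVector("twin", "barefoot", dict(gvs[0].scores))
        assignment = assign_limbs(trained_som, cm, gvs + [twin])
        assert assignment["twin"] == assignment[gvs[0].limb_id]

    def test_every_limb_labeled(self, trained_som, cohort_scores, cohort_assignment):
        assert len(cohort_assignment) == len(cohort_scores["gvs"]) == 250
        labels = [lab for _, lab in cohort_assignment.values()]
        assert all(0 <= lab for lab in labels)


class TestSelectK:
    def test_deterministic(self, trained_som, sensitivity):
        k2, diags2 = select_k(trained_som, range(2, 11), seed=0)
        assert (k2, [d["k"] for d in diags2]) == (
            sensitivity[0],
            [d["k"] for d in sensitivity[1]],
        )
        for a, b in zip(sensitivity[1], diags2):
            assert a["silhouette"] == pytest.approx(b["silhouette"])

    def test_degenerate_codebook_flagged(self, trained_som):
        degenerate = type(trained_som)(
            codebook=np.zeros_like(trained_som.codebook),
            grid_coords=trained_som.grid_coords,
            norm_mean=trained_som.norm_mean,
            norm_sd=trained_som.norm_sd,
            zero_variance=trained_som.zero_variance,
            config=trained_som.config,
        )
        with pytest.raises(ValueError, match="degenerate"):
            select_k(degenerate, range(2, 5), seed=0)

    def test_invalid_range_rejected(self, trained_som):
        with pytest.raises(ValueError):
            select_k(trained_som, [1], seed=0)

    def test_recovers_six_groups_on_default_cohort(self, sensitivity):
        chosen_k, _ = sensitivity
        assert chosen_k == 6


class TestCanonicalization:
    def test_td_dominated_cluster_is_group_zero(self, cohort_scores,
                                                cohort_assignment, sensitivity):
        chosen_k, _ = sensitivity
        td_ids = {c.limb_id for c in cohort_scores["td"]}
        relabel = canonicalize_labels(
            {l: lab for l, (_, lab) in cohort_assignment.items()}, td_ids, chosen_k
        )
        relabeled = {l: relabel[lab] for l, (_, lab) in cohort_assignment.items()}
        td_labels = [relabeled[l] for l in td_ids]
        # group 0 holds the plurality of TD limbs by construction
        counts = np.bincount(td_labels, minlength=chosen_k)
        assert counts[0] == counts.max()
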