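"""Silhouettes, leave-one-subject-out label transfer, elbow selection."""

import numpy as np
import pytest

from cytopheno.clustering import ClusterLabels
from cytopheno.io import PanelConfig
from cytopheno.presets import well_separated_spec
from cytopheno.resolution import (
    FoldSkipped,
    ResolutionScan,
    cv_fold,
    cv_score_for_labels,
    select_elbow,
    silhouette_per_cell,
)
from cytopheno.synthetic import generate_cohort


def brute_force_silhouette(X, labels):
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    out = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        if same.sum() == 1:
            out[i] = 0.0
            continue
        a = D[i, same & (np.arange(n) != i)].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


class TestSilhouette:
    def test_coincident_pairs_far_apart_score_one(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [10.0, 0.0]])
        s = silhouette_per_cell(X, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(s, 1.0)

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [5.0]])
        s = silhouette_per_cell(X, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 6))
        labels = rng.integers(0, 4, 200)
        np.testing.assert_allclose(
            silhouette_per_cell(X, labels), brute_force_silhouette(X, labels),
            atol=1e-10,
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="single cluster"):
            silhouette_per_cell(np.zeros((5, 2)), np.zeros(5, dtype=int))


def tight_cohort(seed=1, cells=1000, n_subjects=8):
    """Populations separated by ~60 SDs: label transfer is unambiguous."""
    spec = well_separated_spec(
        cells_per_subject=cells, n_subjects=n_subjects, separation_sds=60.0,
        sd=0.1, seed=seed,
    )
    table = generate_cohort(spec)
    panel = PanelConfig(markers=list(table.markers))
    truth = np.unique(table.truth_population, return_inverse=True)[1]
    labels = ClusterLabels(labels=truth, resolution=0.1, seed=0)
    return table, panel, labels


class TestCVFold:
    def test_duplicated_cells_are_memorized(self):
        table, panel, labels = tight_cohort(cells=200, n_subjects=4)
        held = table.subjects[0]
        fold = cv_fold(table, labels, held, panel, seed=0,
                       classifier_params={"n_estimators": 25})
        # held-out cells are draws from the same populations as training;
        # with ~30-SD separation every prediction must match the truth
        truth = np.unique(table.truth_population, return_inverse=True)[1]
        assert (fold.predicted == truth[fold.cell_index]).all()
        assert fold.silhouette.min() > 0.8

    def test_predictions_invariant_to_training_cell_order(self):
        table, panel, labels = tight_cohort(cells=150, n_subjects=4)
        held = table.subjects[1]
        a = cv_fold(table, labels, held, panel, seed=3,
                    classifier_params={"n_estimators": 25})
        perm = np.random.default_rng(0).permutation(table.n_cells)
        table_p = table.take(perm)
        labels_p = ClusterLabels(labels=labels.labels[perm], resolution=0.1, seed=0)
        b = cv_fold(table_p, labels_p, held, panel, seed=3,
                    classifier_params={"n_estimators": 25})
        # same held-out subject; align by global index
        ap = dict(zip(a.cell_index.tolist(), a.predicted.tolist()))
        bp = dict(zip(perm[b.cell_index].tolist(), b.predicted.tolist()))
        assert ap == bp

    def test_single_cluster_training_skips_fold(self):
        table, panel, labels = tight_cohort(cells=150, n_subjects=4)
        one = ClusterLabels(labels=np.zeros(table.n_cells, dtype=int),
                            resolution=0.1, seed=0)
        with pytest.raises(FoldSkipped):
            cv_fold(table, one, table.subjects[0], panel, seed=0)


class TestCVScore:
    def test_well_separated_populations_score_high(self):
        table, panel, labels = tight_cohort(cells=400)
        score, per_cluster, folds = cv_score_for_labels(
            table, labels, panel, seed=1, classifier_params={"n_estimators": 50},
        )
        assert score >= 0.9
        assert len(folds) == 8
        assert all(-1 <= v <= 1 for v in per_cluster.values())

    def test_homogeneous_population_split_in_two_scores_low(self):
        rng = np.random.default_rng(0)
        from cytopheno.events import EventTable

        n = 1600
        table = EventTable(
            values=rng.normal(size=(n, 5)),
            markers=[f"M{i}" for i in range(5)],
            subject_id=np.repeat([f"s{j}" for j in range(4)], n // 4).astype(object),
            group=np.array(["g"] * n, dtype=object),
            compartment=np.array(["blood"] * n, dtype=object),
        )
        panel = PanelConfig(markers=list(table.markers))
        # arbitrary split of one blob into two "clusters"
        labels = ClusterLabels(labels=(np.arange(n) % 2), resolution=0.2, seed=0)
        score, _, _ = cv_score_for_labels(
            table, labels, panel, seed=0, classifier_params={"n_estimators": 50},
        )
        assert score <= 0.25

    def test_invariant_to_subject_iteration_order(self):
        table, panel, labels = tight_cohort(cells=200, n_subjects=4)
        score_a, _, _ = cv_score_for_labels(
            table, labels, panel, seed=2, classifier_params={"n_estimators": 25})
        # reverse the subject blocks
        order = np.concatenate([
            np.flatnonzero(table.subject_id == s) for s in table.subjects[::-1]
        ])
        table_r = table.take(order)
        labels_r = ClusterLabels(labels=labels.labels[order], resolution=0.1, seed=0)
        score_b, _, _ = cv_score_for_labels(
            table_r, labels_r, panel, seed=2, classifier_params={"n_estimators": 25})
        assert score_a == pytest.approx(score_b, abs=1e-12)

    def test_leave_one_subject_out_stability(self):
        table, panel, labels = tight_cohort(cells=300)
        score_full, _, _ = cv_score_for_labels(
            table, labels, panel, seed=0, classifier_params={"n_estimators": 25})
        drop = table.subjects[-1]
        keep = np.flatnonzero(table.subject_id != drop)
        table_d = table.take(keep)
        labels_d = ClusterLabels(labels=labels.labels[keep], resolution=0.1, seed=0)
        score_drop, _, _ = cv_score_for_labels(
            table_d, labels_d, panel, seed=0, classifier_params={"n_estimators": 25})
        assert abs(score_full - score_drop) < 0.1


def scan_of(scores, grid=None):
    scores = np.asarray(scores, dtype=float)
    grid = np.asarray(grid if grid is not None else np.linspace(0.01, 0.2, len(scores)))
    return ResolutionScan(
        grid=grid, scores=scores, n_clusters=np.zeros(len(scores), dtype=int),
        per_cluster=[{} for _ in scores], n_subjects=0,
    )


class TestSelectElbow:
    def test_corner_of_saturating_curve(self):
        scan = scan_of([0.20, 0.60, 0.90, 0.92, 0.93])
        assert select_elbow(scan) == pytest.approx(scan.grid[2])

    def test_linear_curve_falls_back_to_maximum(self):
        scan = scan_of([0.1, 0.2, 0.3, 0.4, 0.5])
        assert select_elbow(scan) == pytest.approx(scan.grid[-1])

    def test_interior_spike_is_selected(self):
        scan = scan_of([0.1, 0.1, 0.8, 0.1, 0.1])
        assert select_elbow(scan) == pytest.approx(scan.grid[2])

    def test_constant_curve_ties_break_to_smaller_resolution(self):
        scan = scan_of([0.5, 0.5, 0.5, 0.5])
        assert select_elbow(scan) == pytest.approx(scan.grid[0])

    def test_missing_points_are_skipped(self):
        scan = scan_of([0.2, np.nan, 0.6, 0.9, 0.92])
        # valid curve [0.2, 0.6, 0.9, 0.92] elbows at 0.9
        assert select_elbow(scan) == pytest.approx(scan.grid[3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            select_elbow(scan_of([0.5, np.nan, 0.6]))
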