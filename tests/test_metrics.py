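"""Unit tests for the evaluation metrics, with brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from sccorrect.metrics import (
    clustering_agreement,
    lisi,
    lisi_f1,
    overall_score,
    pos,
    principal_curve_pseudotime,
    pseudotime_conservation,
    silhouette,
    specificity,
)


# ------------------------------------------------------- brute-force oracles


def bf_pair_counts(truth, pred):
    """Enumerate all C(n,2) pairs and classify their co-assignment."""
    n = len(truth)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_t, same_p = truth[i] == truth[j], pred[i] == pred[j]
        if same_t and same_p:
            ss += 1
        elif same_t:
            sd += 1
        elif same_p:
            ds += 1
        else:
            dd += 1
    return ss, sd, ds, dd


def bf_agreement(truth, pred):
    """Independent formula-level recomputation of all four metrics."""
    n = len(truth)
    ss, sd, ds, dd = bf_pair_counts(truth, pred)
    total = ss + sd + ds + dd
    jaccard = ss / (ss + sd + ds) if (ss + sd + ds) else 1.0
    # ARI from pair counts (permutation-model adjustment)
    sum_t, sum_p = ss + sd, ss + ds
    expected = sum_t * sum_p / total
    max_index = (sum_t + sum_p) / 2
    ari = 1.0 if max_index == expected else (ss - expected) / (max_index - expected)
    # NMI with arithmetic-mean normalization, from the contingency table
    t_vals, p_vals = sorted(set(truth)), sorted(set(pred))
    table = np.array(
        [[sum(t == a and p == b for t, p in zip(truth, pred)) for b in p_vals] for a in t_vals],
        dtype=float,
    )
    pt, pp = table.sum(1) / n, table.sum(0) / n
    ht = -sum(q * np.log(q) for q in pt if q > 0)
    hp = -sum(q * np.log(q) for q in pp if q > 0)
    mi = 0.0
    for a in range(len(t_vals)):
        for b in range(len(p_vals)):
            q = table[a, b] / n
            if q > 0:
                mi += q * np.log(q / (pt[a] * pp[b]))
    nmi = mi / ((ht + hp) / 2) if (ht + hp) else 1.0
    purity = sum(table.max(axis=0)) / n
    return {"nmi": nmi, "ari": ari, "jaccard": jaccard, "purity": purity}


def bf_silhouette(x, labels):
    d = cdist(x, x)
    scores = []
    for i in range(len(labels)):
        own = [j for j in range(len(labels)) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(len(labels)) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestClusteringAgreement:
    def test_perfect_match_under_relabeling(self, rng):
        truth = rng.integers(0, 4, 40)
        relabeled = np.array(["wxyz"[t] for t in truth])
        out = clustering_agreement(truth, relabeled)
        assert out == {"nmi": 1.0, "ari": 1.0, "jaccard": 1.0, "purity": 1.0}

    def test_one_big_cluster_hand_example(self):
        truth = [0] * 4 + [1] * 4
        pred = [0] * 8
        out = clustering_agreement(truth, pred)
        assert out["purity"] == 0.5
        assert out["jaccard"] == pytest.approx(12 / 28)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_exhaustive_pair_oracle(self, rng, trial):
        n = 50
        truth = rng.integers(0, 4, n).tolist()
        pred = rng.integers(0, 3, n).tolist()
        got = clustering_agreement(truth, pred)
        expected = bf_agreement(truth, pred)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-10), key

    def test_label_renaming_invariance(self, rng):
        truth = rng.integers(0, 3, 30)
        pred = rng.integers(0, 3, 30)
        renamed = np.array([f"c{p}" for p in pred])
        assert clustering_agreement(truth, pred) == pytest.approx(
            clustering_agreement(truth, renamed)
        )

    def test_degenerate_single_labels(self):
        out = clustering_agreement([1, 1, 1], [2, 2, 2])
        assert out["nmi"] == 1.0


class TestSilhouette:
    def test_six_point_hand_configuration(self):
        x = np.array([[0.0, 0], [1, 0], [0, 1], [10, 0], [11, 0], [10, 1]])
        labels = [0, 0, 0, 1, 1, 1]
        assert silhouette(x, labels) == pytest.approx(bf_silhouette(x, labels), abs=1e-12)

    def test_well_separated_near_one(self, rng):
        x = np.vstack(
            [rng.normal(0, 0.01, (20, 2)), rng.normal(50, 0.01, (20, 2))]
        )
        labels = [0] * 20 + [1] * 20
        assert silhouette(x, labels) > 0.99

    def test_matches_reference_for_random_data(self, rng):
        x = rng.normal(size=(100, 3))
        labels = rng.integers(0, 4, 100)
        from sklearn.metrics import silhouette_score

        assert silhouette(x, labels) == pytest.approx(
            silhouette_score(x, labels), abs=1e-10
        )

    def test_single_cluster_error(self, rng):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette(rng.normal(size=(10, 2)), [1] * 10)


class TestLISI:
    def test_mixed_batches_raw_near_two(self, rng):
        x = rng.normal(size=(300, 2))
        batches = rng.integers(0, 2, 300)  # perfectly interleaved
        scalar, raw = lisi(x, batches, perplexity=30, return_raw=True)
        assert np.median(raw) == pytest.approx(2.0, abs=0.1)
        assert np.all((raw >= 1.0 - 1e-9) & (raw <= 2.0 + 1e-9))

    def test_separated_batches_raw_near_one(self, rng):
        x = np.vstack(
            [rng.normal(0, 1, (150, 2)), rng.normal(100, 1, (150, 2))]
        )
        batches = np.array([0] * 150 + [1] * 150)
        _, raw = lisi(x, batches, perplexity=30, return_raw=True)
        assert np.median(raw) == pytest.approx(1.0, abs=0.05)

    def test_raw_range_bounded_by_label_count(self, rng):
        x = rng.normal(size=(200, 3))
        labels = rng.integers(0, 5, 200)
        _, raw = lisi(x, labels, return_raw=True)
        assert raw.min() >= 1.0 - 1e-9
        assert raw.max() <= 5.0 + 1e-9


class TestLisiF1:
    @pytest.mark.parametrize(
        "b, c, expected",
        [(1.0, 0.0, 1.0), (0.0, 0.3, 0.0), (0.0, 0.9, 0.0), (0.5, 0.5, 0.5)],
    )
    def test_endpoint_identities(self, b, c, expected):
        assert lisi_f1(b, c) == pytest.approx(expected)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError, match="bLISI"):
            lisi_f1(1.5, 0.5)


class TestSpecificity:
    def test_isolated_clump_scores_one(self, rng):
        specific = rng.normal(0, 0.1, (30, 2))
        others = rng.normal(100, 0.1, (50, 2))
        x = np.vstack([specific, others])
        mask = np.array([True] * 30 + [False] * 50)
        assert specificity(x, mask, k=20) == 1.0

    def test_interleaved_lattice_half(self):
        # 1:1 alternating lattice: each specific cell's neighbors alternate
        x = np.arange(200, dtype=float)[:, None] * np.ones((1, 2))
        mask = np.arange(200) % 2 == 0
        score = specificity(x, mask, k=20)
        assert score == pytest.approx(0.5, abs=0.05)

    def test_surrounded_cells_score_zero(self, rng):
        others = rng.normal(0, 1.0, (80, 2))
        specific = rng.normal(0, 1.0, (3, 2))
        x = np.vstack([specific, others])
        mask = np.array([True] * 3 + [False] * 80)
        assert specificity(x, mask, k=20) <= 0.1

    def test_rigid_transform_invariance(self, rng):
        x = rng.normal(size=(100, 2))
        mask = rng.random(100) < 0.3
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert specificity(x, mask) == pytest.approx(
            specificity(x @ rot + 5.0, mask)
        )

    def test_no_specific_cells_error(self, rng):
        with pytest.raises(ValueError, match="specific"):
            specificity(rng.normal(size=(30, 2)), np.zeros(30, bool))


class TestPOS:
    def test_identical_and_reversed(self):
        t = np.array([0.1, 0.4, 0.5, 0.9])
        assert pos(t, t) == (1.0, 1.0)
        p, tau = pos(-t, t)
        assert (p, tau) == (0.0, -1.0)

    def test_single_swap_nine_of_ten(self):
        gold = [1, 2, 3, 4, 5]
        swapped = [1, 3, 2, 4, 5]
        p, _ = pos(swapped, gold)
        assert p == pytest.approx(0.9)

    def test_matches_pair_enumeration(self, rng):
        p_vec = rng.normal(size=20)
        g_vec = rng.normal(size=20)
        c = nc = 0
        for i, j in itertools.combinations(range(20), 2):
            s = np.sign(p_vec[i] - p_vec[j]) * np.sign(g_vec[i] - g_vec[j])
            c += s > 0
            nc += s < 0
        assert pos(p_vec, g_vec)[0] == pytest.approx(c / (c + nc))

    def test_monotone_transform_invariance(self, rng):
        p_vec = rng.normal(size=15)
        g_vec = rng.normal(size=15)
        assert pos(np.exp(p_vec), g_vec) == pytest.approx(pos(p_vec, g_vec))

    def test_all_tied_error(self):
        with pytest.raises(ValueError, match="tied"):
            pos([1.0, 1.0, 1.0], [1, 2, 3])


class TestPrincipalCurve:
    def test_line_identity_correlation_one(self, rng):
        t = np.sort(rng.uniform(0, 1, 120))
        line = np.column_stack([t, 2 * t]) + rng.normal(0, 1e-3, (120, 2))
        out = pseudotime_conservation({"b1": line}, line, np.array(["b1"] * 120))
        assert out["b1"] > 0.999

    def test_rigid_rotation_preserves_arclength(self, rng):
        t = np.sort(rng.uniform(0, 1, 120))
        line = np.column_stack([t, 0.5 * t]) + rng.normal(0, 1e-3, (120, 2))
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        out = pseudotime_conservation(
            {"b1": line}, line @ rot, np.array(["b1"] * 120)
        )
        assert out["b1"] > 0.999

    def test_noisy_s_curve_after_mean_shift_removal(self, rng):
        t = np.sort(rng.uniform(0, 2 * np.pi, 300))
        curve = np.column_stack([t, np.sin(t)])
        noise = rng.normal(0, 0.05, curve.shape)
        b1 = curve[:150] + noise[:150]
        b2 = curve[150:] + noise[150:] + np.array([0.0, 3.0])  # batch shift
        integrated = np.vstack([b1, b2 - np.array([0.0, 3.0])])
        batches = np.array(["b1"] * 150 + ["b2"] * 150)
        out = pseudotime_conservation(
            {"b1": b1, "b2": b2}, integrated, batches
        )
        assert out["b1"] >= 0.9 and out["b2"] >= 0.9

    def test_pseudotime_orders_line_correctly(self, rng):
        t = np.sort(rng.uniform(0, 1, 80))
        line = np.column_stack([t, t]) + rng.normal(0, 1e-4, (80, 2))
        ps = principal_curve_pseudotime(line)
        p, _ = pos(ps, t)
        assert max(p, 1 - p) > 0.99


class TestOverallScore:
    def test_dominant_method_scores_max(self):
        table = pd.DataFrame(
            {"m1": [4, 3, 2, 1], "m2": [0.9, 0.1, 0.2, 0.3], "m3": [1, 0, 0.5, 0.2]},
            index=["a", "b", "c", "d"],
        )
        out = overall_score(table, {"bio": ["m1", "m2", "m3"]})
        assert out.loc["a", "overall"] == 4.0

    def test_two_methods_ordered(self):
        table = pd.DataFrame({"m1": [1, 0], "m2": [0.7, 0.2]}, index=["x", "y"])
        out = overall_score(table, {"all": ["m1", "m2"]})
        assert out.loc["x", "overall"] == 2.0
        assert out.loc["y", "overall"] == 1.0

    def test_planted_rank_permutation_hand_average(self):
        table = pd.DataFrame(
            {
                "m1": [4, 3, 2, 1],  # points 4,3,2,1
                "m2": [1, 4, 3, 2],  # points 1,4,3,2
                "m3": [2, 1, 4, 3],  # points 2,1,4,3
            },
            index=["a", "b", "c", "d"],
        )
        out = overall_score(table, {"cat": ["m1", "m2"]})
        np.testing.assert_allclose(out["cat"], [2.5, 3.5, 2.5, 1.5])
        np.testing.assert_allclose(out["overall"], [7 / 3, 8 / 3, 3.0, 2.0])

    def test_ties_share_mean_points(self):
        table = pd.DataFrame({"m1": [1.0, 1.0, 0.0]}, index=["a", "b", "c"])
        out = overall_score(table, {"cat": ["m1"]})
        assert out.loc["a", "overall"] == 2.5 == out.loc["b", "overall"]
        assert out.loc["c", "overall"] == 1.0

    def test_missing_metric_skipped_with_warning(self):
        table = pd.DataFrame(
            {"m1": [1.0, 0.5], "m2": [np.nan, 0.1]}, index=["a", "b"]
        )
        with pytest.warns(UserWarning, match="m2"):
            out = overall_score(table, {"cat": ["m1", "m2"]})
        assert out.loc["a", "overall"] == 2.0
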