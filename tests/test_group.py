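"""Group-level statistics: gated SMP tests, asymmetry, backbones, maps."""

import numpy as np
import pytest
from scipy import stats

import smnet as sm
from smnet.graph import SEMI_METRIC
from smnet.parcellation import RegionHierarchy

from conftest import build_subject, random_proximity

# 3-node weights: edge (0, 2) semi-metric (the worked closure example)
W_SEMI = np.array([[0.0, 0.8, 0.2], [0.8, 0.0, 0.8], [0.2, 0.8, 0.0]])
# uniform triangle: no semi-metric edge
W_METRIC = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])


@pytest.fixture
def tri_parcellation():
    return sm.Parcellation(
        ids=("n0", "n1", "n2"), labels=("a", "b", "c"),
        hemisphere=("left",) * 3, lobe=("frontal",) * 3,
        centroids=np.array([[-10.0, 0, 0], [-20, 0, 0], [-30, 0, 0]]),
    )


@pytest.fixture
def twelve_parcellation():
    ids, hemi, lobe, cents = [], [], [], []
    for side, sign in (("left", -1), ("right", 1)):
        for k in range(6):
            ids.append(f"{side[0]}{k}")
            hemi.append(side)
            lobe.append("frontal" if k < 3 else "temporal")
            cents.append([sign * (10 + 5 * k), k * 8.0, 0.0])
    return sm.Parcellation(ids=tuple(ids), labels=tuple(ids),
                           hemisphere=tuple(hemi), lobe=tuple(lobe),
                           centroids=np.array(cents))


def make_study(subjects, parcellation, labels=("A", "B")):
    return sm.GroupStudy(
        subjects=tuple(subjects), parcellation=parcellation,
        hierarchy=sm.build_hierarchy(parcellation), group_labels=labels,
    )


class TestWelchKernel:
    def test_closed_form_example(self):
        # hand-computable: equal n = 3, equal variances 0.01
        row = sm.smp_group_test([0.3, 0.4, 0.5], [0.6, 0.7, 0.8], name="x")
        assert row.difference == pytest.approx(-0.3)
        se = np.sqrt(0.01 / 3 + 0.01 / 3)
        assert row.difference / se == pytest.approx(-3.6742346, abs=1e-6)
        # Welch df is exactly 4 here; p from the t(4) tail
        assert row.p_value == pytest.approx(0.0213116411, abs=1e-9)
        assert row.ci_low == pytest.approx(-0.5266957936, abs=1e-9)
        assert row.ci_high == pytest.approx(-0.0733042064, abs=1e-9)
        assert row.ci_low <= row.difference <= row.ci_high

    def test_identical_groups(self):
        row = sm.smp_group_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert row.difference == 0.0
        assert row.p_value == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self):
        r1 = sm.smp_group_test([0.3, 0.4, 0.5], [0.6, 0.7, 0.9])
        r2 = sm.smp_group_test([0.6, 0.7, 0.9], [0.3, 0.4, 0.5])
        assert r2.difference == pytest.approx(-r1.difference)
        assert r2.p_value == pytest.approx(r1.p_value)
        assert r2.ci_low == pytest.approx(-r1.ci_high)
        assert r2.ci_high == pytest.approx(-r1.ci_low)

    def test_zero_variance_rejected(self):
        with pytest.raises(sm.DegenerateGroupsError):
            sm.smp_group_test([0.2, 0.2], [0.5, 0.5])


class TestSMPProfiles:
    def test_all_metric_subject_profiles_zero(self, tri_parcellation):
        s = build_subject("s", "A", W_METRIC, node_ids=tri_parcellation.ids)
        profile = sm.subject_smp_profile(
            s.closure, sm.build_hierarchy(tri_parcellation)
        )
        assert profile["whole_brain"] == 0.0
        assert profile["left_hemisphere"] == 0.0
        assert profile["right_hemisphere"] is None  # no right pairs

    def test_planted_left_edge(self, tri_parcellation):
        s = build_subject("s", "A", W_SEMI, node_ids=tri_parcellation.ids)
        h = sm.build_hierarchy(tri_parcellation)
        profile = sm.subject_smp_profile(s.closure, h)
        assert profile["left_hemisphere"] == pytest.approx(1 / 3)
        assert profile["whole_brain"] == pytest.approx(1 / 3)

    def test_global_classification_consistency(self, default_study):
        # subset SMPs re-count the same globally classified edges
        study, _ = default_study
        s = study.subjects[0]
        profile = sm.subject_smp_profile(s.closure, study.hierarchy)
        assert profile["whole_brain"] == pytest.approx(sm.smp(s.closure, "all"))


class TestGatedHierarchy:
    def _planted_right_study(self, twelve_parcellation, n_per_group=6):
        rng = np.random.default_rng(99)
        ids = twelve_parcellation.ids
        subjects = []
        for grp, plant in (("A", True), ("B", False)):
            for k in range(n_per_group):
                w = rng.uniform(0.35, 0.45, (12, 12))
                w = (w + w.T) / 2
                if plant:
                    # strong two-hop bridge inside the right hemisphere
                    for i, hub, j in [(6, 7, 8), (9, 10, 11)]:
                        w[i, hub] = w[hub, i] = 0.9
                        w[j, hub] = w[hub, j] = 0.9
                        w[i, j] = w[j, i] = 0.1
                np.fill_diagonal(w, 0.0)
                subjects.append(build_subject(f"{grp}{k}", grp, w, node_ids=ids))
        return make_study(subjects, twelve_parcellation)

    def test_gating_consistency(self, twelve_parcellation):
        study = self._planted_right_study(twelve_parcellation)
        rows = sm.gated_hierarchy_test(study, alpha=0.05)
        by_name = {r.name: r for r in rows}
        assert by_name["whole_brain"].tested
        for r in rows:
            parent = study.hierarchy.parents[r.name]
            if parent is None:
                continue
            parent_sig = (by_name[parent].tested
                          and by_name[parent].p_value is not None
                          and by_name[parent].p_value < 0.05)
            if r.note == "undefined for too many subjects":
                continue
            assert (r.tested or r.note == "zero variance") == parent_sig, r.name
            if not r.tested:
                assert r.p_value is None and r.ci_low is None

    def test_planted_right_effect_detected(self, twelve_parcellation):
        study = self._planted_right_study(twelve_parcellation)
        rows = {r.name: r for r in sm.gated_hierarchy_test(study)}
        assert rows["right_hemisphere"].tested
        assert rows["right_hemisphere"].p_value < 0.05
        assert rows["right_hemisphere"].difference > 0

    def test_null_study_reports_all_rows(self):
        parc = sm.make_parcellation_fixture(n_nodes=36, seed=5)
        spec = sm.GroupSpec(n_subjects=6, mu_r=0.3, sigma_r=0.05, n_triads=3)
        study, _ = sm.make_group_study(spec, spec, parcellation=parc, seed=42)
        rows = sm.gated_hierarchy_test(study)
        assert [r.name for r in rows] == list(study.hierarchy.order)
        assert rows[0].name == "whole_brain" and rows[0].tested

    def test_single_level_hierarchy_equals_plain_test(self, tri_parcellation):
        # SMPs vary within each group so the Welch test is well defined:
        # A = {1/3, 1/3, 0}, B = {0, 0, 1/3}
        a_weights = [W_SEMI, W_SEMI, W_METRIC]
        b_weights = [W_METRIC, W_METRIC, W_SEMI]
        subjects = [
            build_subject(f"A{k}", "A", w, node_ids=tri_parcellation.ids)
            for k, w in enumerate(a_weights)
        ] + [
            build_subject(f"B{k}", "B", w, node_ids=tri_parcellation.ids)
            for k, w in enumerate(b_weights)
        ]
        h = RegionHierarchy(
            subsets={"whole_brain": sm.build_hierarchy(tri_parcellation).pairs("whole_brain")},
            parents={"whole_brain": None},
            order=("whole_brain",),
        )
        study = sm.GroupStudy(subjects=tuple(subjects),
                              parcellation=tri_parcellation,
                              hierarchy=h, group_labels=("A", "B"))
        profiles = sm.compute_profiles(study)
        rows = sm.gated_hierarchy_test(study, profiles=profiles)
        a = [profiles[s.subject_id]["whole_brain"] for s in study.group("A")]
        b = [profiles[s.subject_id]["whole_brain"] for s in study.group("B")]
        direct = sm.smp_group_test(a, b, name="whole_brain")
        assert len(rows) == 1
        assert rows[0].p_value == direct.p_value
        assert rows[0].difference == direct.difference


class TestAsymmetry:
    def _study_with_profiles(self, tri_parcellation, indices_a, indices_b):
        """Inject hemisphere SMPs so the indices are exactly as requested."""
        subjects, profiles = [], {}
        for grp, idxs in (("A", indices_a), ("B", indices_b)):
            for k, target in enumerate(idxs):
                sid = f"{grp}{k}"
                subjects.append(
                    build_subject(sid, grp, W_METRIC, node_ids=tri_parcellation.ids)
                )
                # r, l chosen so (r - l)/(r + l) = target with r + l = 1
                profiles[sid] = {"right_hemisphere": (1 + target) / 2,
                                 "left_hemisphere": (1 - target) / 2}
        return make_study(subjects, tri_parcellation), profiles

    def test_index_values(self, tri_parcellation):
        study, profiles = self._study_with_profiles(
            tri_parcellation, [0.2], [0.0]
        )
        res = sm.asymmetry_test(study, profiles=profiles)
        assert res.indices["A0"] == pytest.approx(0.2)
        assert res.indices["B0"] == pytest.approx(0.0)

    def test_u_statistic_matches_enumeration(self, tri_parcellation):
        a = [0.2, 0.5, 0.7]
        b = [0.1, 0.3, 0.4, 0.6]
        study, profiles = self._study_with_profiles(tri_parcellation, a, b)
        res = sm.asymmetry_test(study, profiles=profiles)
        # brute-force U: pairs where a beats b (+0.5 for ties)
        u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert res.u_statistic == u
        # exact two-sided p by exhaustive relabelling of the 7 indices
        from itertools import combinations

        pooled = a + b
        obs = u
        count = 0
        total = 0
        for pick in combinations(range(7), 3):
            xa = [pooled[i] for i in pick]
            xb = [pooled[i] for i in range(7) if i not in pick]
            uu = sum((x > y) + 0.5 * (x == y) for x in xa for y in xb)
            total += 1
            if abs(uu - len(xa) * len(xb) / 2) >= abs(obs - len(a) * len(b) / 2) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total)

    def test_degenerate_subject_excluded_with_warning(self, tri_parcellation):
        study, profiles = self._study_with_profiles(tri_parcellation,
                                                    [0.2, 0.1], [0.0, -0.1])
        profiles["A0"] = {"right_hemisphere": 0.0, "left_hemisphere": 0.0}
        with pytest.warns(UserWarning, match="A0"):
            res = sm.asymmetry_test(study, profiles=profiles)
        assert "A0" not in res.indices
        assert res.excluded == ("A0",)


class TestBackbone:
    def _group(self, n_semi, n_total, ids=None):
        subs = [build_subject(f"s{k}", "A", W_SEMI, node_ids=ids)
                for k in range(n_semi)]
        subs += [build_subject(f"m{k}", "A", W_METRIC, node_ids=ids)
                 for k in range(n_total - n_semi)]
        return subs

    def test_full_consensus_kept(self):
        bb = sm.backbone(self._group(10, 10), threshold=0.9)
        assert bb.consensus[0, 2] == 1.0
        assert (0, 2, 1.0) in bb.edges

    def test_exact_threshold_dropped(self):
        # the >90% rule is strict: consensus of exactly 0.9 is excluded
        bb = sm.backbone(self._group(9, 10), threshold=0.9)
        assert bb.consensus[0, 2] == pytest.approx(0.9)
        assert bb.edges == ()

    def test_threshold_zero_is_union_and_monotone(self, default_study):
        study, _ = default_study
        grp = study.group(study.group_labels[0])
        union = set()
        for s in grp:
            union |= set(s.closure.semi_metric_pairs())
        bb0 = sm.backbone(grp, threshold=1e-12)
        assert {(i, j) for i, j, _ in bb0.edges} == union
        counts = [len(sm.backbone(grp, threshold=t).edges)
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)
        assert 0.0 <= bb0.consensus.min() and bb0.consensus.max() <= 1.0


class TestDifferenceMap:
    def _random_study(self, rng, perturb_node=None):
        parc = sm.make_parcellation_fixture(n_nodes=15, seed=2)
        subjects = []
        for grp in ("A", "B"):
            local = np.random.default_rng(123)  # same graphs in both groups
            for k in range(4):
                p = random_proximity(local, 15, 0.7)
                w = p.weights.copy()
                if grp == "B" and perturb_node is not None:
                    w[perturb_node, :] *= 0.3
                    w[:, perturb_node] *= 0.3
                subjects.append(build_subject(f"{grp}{k}", grp, w,
                                              node_ids=parc.ids))
        return make_study(subjects, parc)

    def test_identical_groups_zero(self, rng):
        study = self._random_study(rng)
        scores = sm.group_difference_map(study)
        np.testing.assert_allclose(scores, 0.0, atol=1e-14)

    def test_perturbed_node_scores_high(self, rng):
        study = self._random_study(rng, perturb_node=3)
        scores = sm.group_difference_map(study)
        assert scores[3] > np.median(scores)

    def test_group_order_symmetry_and_normalization(self, rng):
        study = self._random_study(rng, perturb_node=3)
        flipped = sm.GroupStudy(
            subjects=study.subjects, parcellation=study.parcellation,
            hierarchy=study.hierarchy,
            group_labels=(study.group_labels[1], study.group_labels[0]),
        )
        np.testing.assert_allclose(sm.group_difference_map(study),
                                   sm.group_difference_map(flipped))
        normed = sm.group_difference_map(study, normalize=True)
        assert normed.max() == pytest.approx(1.0)


class TestDistanceRankedSMP:
    def test_sorted_by_distance_and_matches_oracle(self, default_study):
        study, _ = default_study
        rows = sm.distance_ranked_smp(study)
        dists = [mm for _, mm, _ in rows]
        assert dists == sorted(dists)
        profiles = sm.compute_profiles(study)
        ga, gb = study.group_labels
        for name, mm, diff in rows[:5]:
            expect_mm = sm.mean_euclidean_distance(
                study.hierarchy.pairs(name), study.parcellation
            )
            assert mm == pytest.approx(expect_mm)
            a = np.mean([v for s in study.group(ga)
                         if (v := profiles[s.subject_id][name]) is not None])
            b = np.mean([v for s in study.group(gb)
                         if (v := profiles[s.subject_id][name]) is not None])
            assert diff == pytest.approx(a - b)


class TestCorrelationSummary:
    def test_identical_matrices_pooled_sd(self, tri_parcellation):
        corr = np.array([[1.0, 0.5, -0.2], [0.5, 1.0, 0.1], [-0.2, 0.1, 1.0]])
        subjects = [
            build_subject(f"{g}{k}", g, W_METRIC, node_ids=tri_parcellation.ids,
                          correlation=corr)
            for g in ("A", "B") for k in range(3)
        ]
        study = make_study(subjects, tri_parcellation)
        out = sm.correlation_distribution_summary(study)
        tri = np.triu_indices(3, k=1)
        within = corr[tri]
        # pooling identical matrices: same values repeated, SD over the pool
        pooled = np.tile(within, 3)
        assert out["A"]["sd"] == pytest.approx(pooled.std(ddof=1))
        assert out["A"]["median"] == pytest.approx(np.median(within))
        # negative counts identical in both groups: degenerate, reported NaN
        assert np.isnan(out["negative_edges"]["p"])

    def test_negative_count_welch_matches_direct(self, tri_parcellation):
        rng = np.random.default_rng(3)
        subjects = []
        neg = {"A": [], "B": []}
        for g, shift in (("A", -0.1), ("B", 0.2)):
            for k in range(4):
                c = rng.uniform(-0.5, 0.9, (3, 3)) + shift
                c = np.clip((c + c.T) / 2, -1, 1)
                np.fill_diagonal(c, 1.0)
                subjects.append(
                    build_subject(f"{g}{k}", g, W_METRIC,
                                  node_ids=tri_parcellation.ids, correlation=c)
                )
                tri = np.triu_indices(3, k=1)
                neg[g].append(int((c[tri] < 0).sum()))
        study = make_study(subjects, tri_parcellation)
        out = sm.correlation_distribution_summary(study)
        assert out["negative_edges"]["counts"]["A"] == neg["A"]
        expect = stats.ttest_ind(neg["A"], neg["B"], equal_var=False)
        assert out["negative_edges"]["t"] == pytest.approx(expect.statistic)
        assert out["negative_edges"]["p"] == pytest.approx(expect.pvalue)

    def test_symmetric_distribution_mean_near_median(self, default_study):
        study, _ = default_study
        out = sm.correlation_distribution_summary(study, seed=1)
        for label in study.group_labels:
            assert abs(out[label]["mean"] - out[label]["median"]) < 0.01
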