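"""Group-level statistics for two-group semi-metric connectome studies.

A study holds one classified connectome per subject in two labelled groups
(e.g. case vs control).  The analyses implemented here:

* per-subject SMP profiles over the region hierarchy;
* Welch two-sample tests of SMP, run top-down with hierarchical gating
  (a child subset is tested only when its parent's test is significant);
* the hemispheric asymmetry index (r - l)/(r + l) with a Mann-Whitney test;
* consensus semi-metric backbones (edges semi-metric in more than a given
  fraction of a group's subjects);
* node-averaged group-difference maps of the closed (shortest-path)
  connectivity, mapped back to proximity space;
* SMP differences ranked by mean inter-node Euclidean distance;
* summaries of the raw (pre-truncation) correlation distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .graph import (
    ABSENT,
    SEMI_METRIC,
    ClosureResult,
    ProximityGraph,
    UndefinedSMPError,
    distance_to_proximity,
    DistanceGraph,
    smp,
)
from .parcellation import Parcellation, RegionHierarchy, mean_euclidean_distance

__all__ = [
    "Subject",
    "GroupStudy",
    "SMPTestRow",
    "AsymmetryResult",
    "BackboneResult",
    "DegenerateGroupsError",
    "subject_smp_profile",
    "smp_group_test",
    "gated_hierarchy_test",
    "asymmetry_test",
    "backbone",
    "group_difference_map",
    "distance_ranked_smp",
    "correlation_distribution_summary",
]


class DegenerateGroupsError(ValueError):
    """Raised when a two-sample test has no variance in either group."""


@dataclass(frozen=True)
class Subject:
    """One participant: classified connectome plus optional raw correlations."""

    subject_id: str
    group_label: str
    proximity: ProximityGraph
    closure: ClosureResult
    correlation: np.ndarray | None = None  # raw R, pre-truncation
    n_negative: int | None = None  # strictly negative unordered pairs


@dataclass(frozen=True)
class GroupStudy:
    """Labelled two-group collection of subjects sharing one parcellation."""

    subjects: tuple[Subject, ...]
    parcellation: Parcellation
    hierarchy: RegionHierarchy
    group_labels: tuple[str, str]

    def __post_init__(self) -> None:
        ids = self.parcellation.ids
        for s in self.subjects:
            if s.proximity.node_ids != ids:
                raise ValueError(
                    f"subject {s.subject_id} node ids do not match the parcellation"
                )
        for g in self.group_labels:
            if not any(s.group_label == g for s in self.subjects):
                raise ValueError(f"group {g!r} has no subjects")
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def group(self, label: str) -> tuple[Subject, ...]:
        return tuple(s for s in self.subjects if s.group_label == label)


def subject_smp_profile(
    closure: ClosureResult, hierarchy: RegionHierarchy
) -> dict[str, float | None]:
    """SMP per named region subset; None where the subset has no present edge.

    Edges are classified once on the whole-brain closure; subsets only select
    which classified pairs are counted.
    """
    profile: dict[str, float | None] = {}
    for name in hierarchy.order:
        pairs = hierarchy.pairs(name)
        if not pairs:
            profile[name] = None
            continue
        try:
            profile[name] = smp(closure, pairs)
        except UndefinedSMPError:
            profile[name] = None
    return profile


@dataclass(frozen=True)
class SMPTestRow:
    """One row of the hierarchical SMP comparison table."""

    name: str
    n_a: int
    n_b: int
    mean_a: float | None
    mean_b: float | None
    difference: float | None  # mean_a - mean_b
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    tested: bool
    note: str = ""


def smp_group_test(
    a: Sequence[float],
    b: Sequence[float],
    name: str = "",
    confidence: float = 0.95,
) -> SMPTestRow:
    """Welch (unequal-variance) two-sample t-test of per-subject SMPs.

    Reports the difference of means (a - b), its Welch confidence interval
    and the two-tailed p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateGroupsError(f"{name or 'test'}: need >= 2 subjects per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateGroupsError(f"{name or 'test'}: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=confidence)
    return SMPTestRow(
        name=name,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        tested=True,
    )


def _collect_samples(
    study: GroupStudy,
    profiles: dict[str, dict[str, float | None]],
    name: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group SMP samples for one subset, dropping undefined subjects."""
    ga, gb = study.group_labels
    a = [profiles[s.subject_id][name] for s in study.group(ga)]
    b = [profiles[s.subject_id][name] for s in study.group(gb)]
    return (
        np.array([v for v in a if v is not None], dtype=float),
        np.array([v for v in b if v is not None], dtype=float),
    )


def compute_profiles(study: GroupStudy) -> dict[str, dict[str, float | None]]:
    """SMP profile per subject, keyed by subject id."""
    return {
        s.subject_id: subject_smp_profile(s.closure, study.hierarchy)
        for s in study.subjects
    }


def gated_hierarchy_test(
    study: GroupStudy,
    alpha: float = 0.05,
    profiles: dict[str, dict[str, float | None]] | None = None,
    bh_correct_leaves: bool = False,
) -> list[SMPTestRow]:
    """Hierarchically gated SMP comparison over all region subsets.

    The whole-brain subset is always tested; every other subset is tested
    only if its parent's two-tailed p-value is below ``alpha``.  Gated-off
    subsets are still reported (descriptive means only, no p-value or CI).
    ``bh_correct_leaves`` optionally applies a Benjamini-Hochberg correction
    across the tested leaf (lobe / between-lobe) rows.
    """
    if profiles is None:
        profiles = compute_profiles(study)
    rows: list[SMPTestRow] = []
    p_by_name: dict[str, float | None] = {}
    for name in study.hierarchy.order:
        a, b = _collect_samples(study, profiles, name)
        mean_a = float(a.mean()) if a.size else None
        mean_b = float(b.mean()) if b.size else None
        diff = mean_a - mean_b if (mean_a is not None and mean_b is not None) else None
        parent = study.hierarchy.parents[name]
        gate_open = parent is None or (
            p_by_name.get(parent) is not None and p_by_name[parent] < alpha
        )
        if not gate_open:
            rows.append(SMPTestRow(name, a.size, b.size, mean_a, mean_b, diff,
                                   None, None, None, tested=False,
                                   note="gated off"))
            p_by_name[name] = None
            continue
        if a.size < 2 or b.size < 2:
            rows.append(SMPTestRow(name, a.size, b.size, mean_a, mean_b, diff,
                                   None, None, None, tested=False,
                                   note="undefined for too many subjects"))
            p_by_name[name] = None
            continue
        try:
            row = smp_group_test(a, b, name=name)
        except DegenerateGroupsError:
            rows.append(SMPTestRow(name, a.size, b.size, mean_a, mean_b, diff,
                                   None, None, None, tested=False,
                                   note="zero variance"))
            p_by_name[name] = None
            continue
        rows.append(row)
        p_by_name[name] = row.p_value

    if bh_correct_leaves:
        leaf_idx = [
            k for k, r in enumerate(rows)
            if r.tested and study.hierarchy.parents[r.name] not in (None, "whole_brain")
        ]
        if leaf_idx:
            ps = np.array([rows[k].p_value for k in leaf_idx])
            order = np.argsort(ps)
            m = len(ps)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                running = min(running, ps[order[rank]] * m / (rank + 1))
                adj[order[rank]] = running
            for k, p_adj in zip(leaf_idx, adj):
                r = rows[k]
                rows[k] = SMPTestRow(r.name, r.n_a, r.n_b, r.mean_a, r.mean_b,
                                     r.difference, r.ci_low, r.ci_high,
                                     float(p_adj), True, note="BH-adjusted")
    return rows


@dataclass(frozen=True)
class AsymmetryResult:
    """Per-subject hemispheric asymmetry indices and the between-group test."""

    indices: dict[str, float]  # subject id -> (r - l)/(r + l)
    excluded: tuple[str, ...]  # subjects with r + l = 0 or undefined SMP
    u_statistic: float
    p_value: float


def asymmetry_test(
    study: GroupStudy,
    profiles: dict[str, dict[str, float | None]] | None = None,
) -> AsymmetryResult:
    """Asymmetry index (r - l)/(r + l) of hemisphere SMPs, Mann-Whitney U.

    r and l are the subject's right- and left-hemisphere SMPs; subjects with
    r + l = 0 (or an undefined hemisphere SMP) are excluded with a warning.
    The U statistic is for the first group's indices against the second's,
    two-sided.
    """
    if profiles is None:
        profiles = compute_profiles(study)
    indices: dict[str, float] = {}
    excluded: list[str] = []
    for s in study.subjects:
        r = profiles[s.subject_id]["right_hemisphere"]
        l = profiles[s.subject_id]["left_hemisphere"]
        if r is None or l is None or (r + l) == 0:
            excluded.append(s.subject_id)
            continue
        indices[s.subject_id] = (r - l) / (r + l)
    if excluded:
        warnings.warn(
            f"asymmetry index undefined for subjects: {', '.join(excluded)}",
            stacklevel=2,
        )
    ga, gb = study.group_labels
    xa = [indices[s.subject_id] for s in study.group(ga) if s.subject_id in indices]
    xb = [indices[s.subject_id] for s in study.group(gb) if s.subject_id in indices]
    if not xa or not xb:
        raise DegenerateGroupsError("asymmetry test needs indices in both groups")
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    return AsymmetryResult(
        indices=indices,
        excluded=tuple(excluded),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class BackboneResult:
    """Consensus semi-metric backbone of one group."""

    consensus: np.ndarray  # n x n fraction of subjects with a semi-metric edge
    edges: tuple[tuple[int, int, float], ...]  # (i, j, consensus) kept pairs
    threshold: float
    group_label: str


def backbone(
    subjects: Sequence[Subject], threshold: float = 0.9, group_label: str = ""
) -> BackboneResult:
    """Edges semi-metric in strictly more than ``threshold`` of the group.

    Consensus of a node pair is the fraction of the group's subjects in whose
    connectome that pair is labelled semi-metric; the comparison with the
    threshold is strict, so a consensus of exactly 0.9 is dropped at 0.9.
    """
    if not subjects:
        raise ValueError("backbone needs at least one subject")
    n = subjects[0].closure.n_nodes
    counts = np.zeros((n, n))
    for s in subjects:
        counts += s.closure.labels == SEMI_METRIC
    consensus = counts / len(subjects)
    ii, jj = np.where(np.triu(consensus > threshold, k=1))
    edges = tuple(
        (int(i), int(j), float(consensus[i, j])) for i, j in zip(ii, jj)
    )
    return BackboneResult(
        consensus=consensus, edges=edges, threshold=threshold,
        group_label=group_label,
    )


def group_difference_map(study: GroupStudy, normalize: bool = False) -> np.ndarray:
    """Node scores of the between-group difference in closed connectivity.

    Each subject's closed (shortest-path) distances are mapped back to
    proximity space via the inverse isomorphism, averaged elementwise within
    each group, and the elementwise absolute difference of the two group
    means is reduced to one score per node (mean over that node's row,
    diagonal excluded).  Semi-metric edges are strongly distorted by closure,
    so large scores flag nodes whose indirect-path structure differs between
    the groups.  ``normalize`` rescales the scores to max 1 for display.
    """
    ids = study.parcellation.ids
    means = []
    for label in study.group_labels:
        acc = None
        members = study.group(label)
        for s in members:
            closed = DistanceGraph(s.closure.closed_distances, node_ids=ids)
            w = distance_to_proximity(closed).weights
            acc = w if acc is None else acc + w
        means.append(acc / len(members))
    diff = np.abs(means[0] - means[1])
    n = diff.shape[0]
    off = ~np.eye(n, dtype=bool)
    scores = np.array([diff[i][off[i]].mean() for i in range(n)])
    if normalize and scores.max() > 0:
        scores = scores / scores.max()
    return scores


def distance_ranked_smp(
    study: GroupStudy,
    profiles: dict[str, dict[str, float | None]] | None = None,
) -> list[tuple[str, float, float]]:
    """(subset, mean Euclidean distance mm, SMP difference) sorted by distance.

    One row per region subset whose SMP is defined in both groups; ties in
    distance are broken by subset name for a stable order.
    """
    if profiles is None:
        profiles = compute_profiles(study)
    rows = []
    for name in study.hierarchy.order:
        pairs = study.hierarchy.pairs(name)
        if not pairs:
            continue
        a, b = _collect_samples(study, profiles, name)
        if a.size == 0 or b.size == 0:
            continue
        mm = mean_euclidean_distance(pairs, study.parcellation)
        rows.append((name, mm, float(a.mean() - b.mean())))
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows


#: largest pooled sample passed to the Shapiro-Wilk test; beyond this a
#: seeded random subsample is drawn (the test's validity degrades at huge n)
_SHAPIRO_MAX_N = 4000


def correlation_distribution_summary(
    study: GroupStudy, seed: int = 0
) -> dict[str, object]:
    """Summaries of the raw correlation distributions and negative-edge counts.

    Pools all off-diagonal correlations (pre-truncation, negatives included)
    across each group's subjects and reports median, mean, SD and a
    Shapiro-Wilk normality p-value (on a seeded subsample when the pool
    exceeds the test's valid range).  Per-subject counts of strictly negative
    correlations are compared between groups with a Welch t-test; if both
    groups' counts are constant the t and p are reported as NaN.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, object] = {}
    neg_counts: dict[str, list[int]] = {}
    for label in study.group_labels:
        pooled = []
        negs = []
        for s in study.group(label):
            if s.correlation is None:
                raise ValueError(
                    f"subject {s.subject_id} has no raw correlation matrix"
                )
            tri = np.triu_indices(s.correlation.shape[0], k=1)
            vals = s.correlation[tri]
            pooled.append(vals)
            negs.append(int((vals < 0).sum()) if s.n_negative is None
                        else s.n_negative)
        pooled = np.concatenate(pooled)
        sample = pooled
        if pooled.size > _SHAPIRO_MAX_N:
            sample = rng.choice(pooled, size=_SHAPIRO_MAX_N, replace=False)
        sw = stats.shapiro(sample)
        out[label] = {
            "median": float(np.median(pooled)),
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)),
            "n_pooled": int(pooled.size),
            "shapiro_p": float(sw.pvalue),
        }
        neg_counts[label] = negs
    ga, gb = study.group_labels
    a = np.asarray(neg_counts[ga], dtype=float)
    b = np.asarray(neg_counts[gb], dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t_stat, p_val = float("nan"), float("nan")
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    out["negative_edges"] = {
        "counts": {ga: neg_counts[ga], gb: neg_counts[gb]},
        "t": t_stat,
        "p": p_val,
    }
    return out
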