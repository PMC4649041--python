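"""Synthetic two-group connectome studies with controlled semi-metric structure.

The generator emulates a small resting-state case-control study: ~116
atlas regions, 256 time points at TR = 2.43 s, a control group of 12 and a
case group of 11 subjects.  Per-subject proximity graphs are a background
of correlation-like weights (normal with group-specific mean and spread,
clipped to [0, 1]) on which *triads* are planted: a weak direct edge
w_weak between two nodes bridged by two strong edges w_strong through a
third.  Whenever

    2 * (1/w_strong - 1)  <  1/w_weak - 1

the two-hop path is shorter than the direct edge regardless of the
background (additional edges can only shorten shortest paths), so every
planted weak edge is analytically guaranteed to be classified semi-metric.

The case group differs from the control group in three ways, mirroring the
phenomena reported for Alzheimer's disease connectomes: a narrower
correlation spread, more planted triads (higher SMP), and higher topological
jitter — each subject relocates planted triads with some probability, so
case subjects agree less on *where* their semi-metric edges sit and the
group's consensus backbone is sparser.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .connectivity import RegionTimeSeriesSet
from .graph import (
    GraphValidationError,
    ProximityGraph,
    metric_closure,
    proximity_to_distance,
)
from .group import GroupStudy, Subject
from .parcellation import CEREBRAL_LOBES, Parcellation, build_hierarchy

__all__ = [
    "GroupSpec",
    "CONTROL_SPEC",
    "CASE_SPEC",
    "make_parcellation_fixture",
    "plant_triad_sites",
    "sample_subject_proximity",
    "sample_subject_timeseries",
    "make_group_study",
]


@dataclass(frozen=True)
class GroupSpec:
    """Generative conditions for one group of subjects.

    ``mu_r`` / ``sigma_r`` set the background correlation level and spread;
    ``n_triads`` planted triads per subject create guaranteed semi-metric
    edges; ``jitter`` is the per-triad probability that a subject carries the
    triad at a random location instead of the group's canonical one.
    """

    n_subjects: int
    mu_r: float
    sigma_r: float
    n_triads: int
    w_strong: float = 0.8
    w_weak: float = 0.2
    jitter: float = 0.0
    n_timepoints: int = 256
    tr_seconds: float = 2.43

    def __post_init__(self) -> None:
        if not (0 < self.w_weak < self.w_strong <= 1):
            raise GraphValidationError("need 0 < w_weak < w_strong <= 1")
        if 2 * (1 / self.w_strong - 1) >= 1 / self.w_weak - 1:
            raise GraphValidationError(
                "infeasible triad: two-hop path through w_strong edges is not "
                "shorter than the direct w_weak edge"
            )
        if not 0 <= self.jitter <= 1:
            raise GraphValidationError("jitter must be in [0, 1]")
        if self.n_subjects < 1 or self.n_triads < 0:
            raise GraphValidationError("n_subjects >= 1 and n_triads >= 0 required")
        if self.sigma_r < 0:
            raise GraphValidationError("sigma_r must be >= 0")


#: study conditions: control group — wider correlation spread, few triads,
#: low topological jitter
CONTROL_SPEC = GroupSpec(n_subjects=12, mu_r=0.316, sigma_r=0.036,
                         n_triads=6, jitter=0.1)
#: case group — narrower spread, twice the triads, high jitter
CASE_SPEC = GroupSpec(n_subjects=11, mu_r=0.291, sigma_r=0.034,
                      n_triads=12, jitter=0.5)


def make_parcellation_fixture(n_nodes: int = 116, seed: int = 0) -> Parcellation:
    """Deterministic synthetic parcellation in the style of a 116-region atlas.

    Splits nodes into left and right cerebral hemispheres plus a cerebellar
    block (26 of 116 at the default size), cycles the cerebral lobes, and
    draws centroids uniformly in plausible MNI ranges (left x < 0 < right x;
    cerebellum posterior-inferior).
    """
    if n_nodes < 6:
        raise GraphValidationError("need at least 6 regions")
    rng = np.random.default_rng(seed)
    n_cereb = max(2, round(n_nodes * 26 / 116))
    n_cerebral = n_nodes - n_cereb
    n_left = (n_cerebral + 1) // 2
    n_right = n_cerebral - n_left

    ids, labels, hemi, lobe = [], [], [], []
    cents = []
    for side, count, xlo, xhi in (("left", n_left, -70.0, -5.0),
                                  ("right", n_right, 5.0, 70.0)):
        for k in range(count):
            lb = CEREBRAL_LOBES[k % len(CEREBRAL_LOBES)]
            ids.append(f"{side[0].upper()}{k:03d}")
            labels.append(f"{side}_{lb}_{k // len(CEREBRAL_LOBES):02d}")
            hemi.append(side)
            lobe.append(lb)
            cents.append([rng.uniform(xlo, xhi), rng.uniform(-90, 70),
                          rng.uniform(-30, 70)])
    for k in range(n_cereb):
        ids.append(f"C{k:03d}")
        labels.append(f"cerebellum_{k:02d}")
        hemi.append("cerebellum")
        lobe.append("cerebellar")
        cents.append([rng.uniform(-40, 40), rng.uniform(-100, -40),
                      rng.uniform(-50, -10)])
    return Parcellation(
        ids=tuple(ids), labels=tuple(labels), hemisphere=tuple(hemi),
        lobe=tuple(lobe), centroids=np.array(cents),
    )


def plant_triad_sites(
    n_nodes: int, n_triads: int, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Node-disjoint (i, hub, j) triples; the (i, j) edge will be semi-metric."""
    if 3 * n_triads > n_nodes:
        raise GraphValidationError(
            f"{n_triads} disjoint triads need {3 * n_triads} nodes, have {n_nodes}"
        )
    perm = rng.permutation(n_nodes)
    return [tuple(int(v) for v in perm[3 * t: 3 * t + 3]) for t in range(n_triads)]


def sample_subject_proximity(
    spec: GroupSpec,
    parcellation: Parcellation,
    rng: np.random.Generator,
    triad_sites: list[tuple[int, int, int]] | None = None,
) -> tuple[ProximityGraph, list[tuple[int, int]], np.ndarray]:
    """One subject's proximity graph with known ground-truth semi-metric edges.

    Returns (graph, planted weak edges as sorted (i, j) pairs, raw
    correlation matrix before truncation).  With ``triad_sites`` given (the
    group's canonical locations), each triad is independently relocated to a
    fresh random site with probability ``spec.jitter``.
    """
    n = parcellation.n_regions
    if triad_sites is None:
        triad_sites = plant_triad_sites(n, spec.n_triads, rng)
    if len(triad_sites) != spec.n_triads:
        raise GraphValidationError("triad_sites length must equal spec.n_triads")

    raw = rng.normal(spec.mu_r, spec.sigma_r, size=(n, n))
    raw = np.clip((raw + raw.T) / 2, -1.0, 1.0)
    np.fill_diagonal(raw, 1.0)

    # per-subject relocation of triads: jittered triads move to random spots
    # disjoint from every triad used by this subject
    used = {v for tri in triad_sites for v in tri}
    sites: list[tuple[int, int, int]] = []
    for tri in triad_sites:
        if spec.jitter > 0 and rng.random() < spec.jitter:
            used -= set(tri)
            free = np.array(sorted(set(range(n)) - used))
            pick = rng.choice(free, size=3, replace=False)
            tri = (int(pick[0]), int(pick[1]), int(pick[2]))
            used |= set(tri)
        sites.append(tri)

    planted: list[tuple[int, int]] = []
    for i, hub, j in sites:
        raw[i, hub] = raw[hub, i] = spec.w_strong
        raw[j, hub] = raw[hub, j] = spec.w_strong
        raw[i, j] = raw[j, i] = spec.w_weak
        planted.append((min(i, j), max(i, j)))
    weights = np.clip(raw, 0.0, 1.0)
    np.fill_diagonal(weights, 0.0)
    graph = ProximityGraph(weights=weights, node_ids=parcellation.ids)
    return graph, planted, raw


def _nearest_psd_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped positive-semidefinite repair with unit diagonal."""
    sym = (mat + mat.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def sample_subject_timeseries(
    spec: GroupSpec,
    parcellation: Parcellation,
    rng: np.random.Generator,
    proximity: ProximityGraph | None = None,
) -> RegionTimeSeriesSet:
    """Zero-mean Gaussian series whose correlation approximates a target graph.

    The target correlation matrix is the proximity graph with a unit
    diagonal, repaired to the nearest positive-semidefinite correlation by
    eigenvalue clipping.  Samples are temporally white, so band-limited
    (wavelet-coefficient) correlations converge to the same target as the
    series lengthens.
    """
    if proximity is None:
        proximity, _, _ = sample_subject_proximity(spec, parcellation, rng)
    target = proximity.weights.copy()
    np.fill_diagonal(target, 1.0)
    target = _nearest_psd_correlation(target)
    chol = np.linalg.cholesky(target + 1e-10 * np.eye(target.shape[0]))
    z = rng.standard_normal((target.shape[0], spec.n_timepoints))
    return RegionTimeSeriesSet(
        series=chol @ z, tr_seconds=spec.tr_seconds, node_ids=parcellation.ids
    )


def make_group_study(
    control_spec: GroupSpec = CONTROL_SPEC,
    case_spec: GroupSpec = CASE_SPEC,
    parcellation: Parcellation | None = None,
    seed: int = 0,
    group_labels: tuple[str, str] = ("case", "control"),
) -> tuple[GroupStudy, dict[str, list[tuple[int, int]]]]:
    """Full two-group study plus per-subject ground-truth planted edges.

    The first element of ``group_labels`` is the case group.  Each group has
    its own canonical triad sites; subjects deviate from them according to
    their group's jitter.  All graphs are classified (closure computed) and
    the raw correlation matrices retained, so the study is ready for every
    group-level analysis.
    """
    rng = np.random.default_rng(seed)
    if parcellation is None:
        parcellation = make_parcellation_fixture(seed=int(rng.integers(2**31)))
    hierarchy = build_hierarchy(parcellation)
    case_label, control_label = group_labels

    subjects: list[Subject] = []
    ground_truth: dict[str, list[tuple[int, int]]] = {}
    for label, spec in ((case_label, case_spec), (control_label, control_spec)):
        sites = plant_triad_sites(parcellation.n_regions, spec.n_triads, rng)
        for k in range(spec.n_subjects):
            sid = f"{label}_{k:02d}"
            prox, planted, raw = sample_subject_proximity(
                spec, parcellation, rng, triad_sites=sites
            )
            closure = metric_closure(proximity_to_distance(prox))
            tri = np.triu_indices(raw.shape[0], k=1)
            subjects.append(
                Subject(
                    subject_id=sid,
                    group_label=label,
                    proximity=prox,
                    closure=closure,
                    correlation=raw,
                    n_negative=int((raw[tri] < 0).sum()),
                )
            )
            ground_truth[sid] = planted
    study = GroupStudy(
        subjects=tuple(subjects),
        parcellation=parcellation,
        hierarchy=hierarchy,
        group_labels=group_labels,
    )
    return study, ground_truth
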