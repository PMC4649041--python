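"""Region metadata and the nested edge-subset scheme used for regional tests.

Nodes carry a hemisphere (left / right cerebral, or cerebellum incl. vermis),
a lobe, and an MNI centroid.  The hierarchy enumerates named unordered
node-pair subsets: whole brain at the top; the two cerebral hemispheres,
the cerebellum and the between-hemisphere pairs below it; and, within each
hemisphere, one subset per lobe plus the within-hemisphere between-lobe
pairs.  Within a hemisphere the lobe subsets and the between-lobe subset
partition that hemisphere's pairs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HEMISPHERES",
    "CEREBRAL_LOBES",
    "Parcellation",
    "RegionHierarchy",
    "build_hierarchy",
    "mean_euclidean_distance",
]

HEMISPHERES = ("left", "right", "cerebellum")
CEREBRAL_LOBES = ("frontal", "parietal", "occipital", "temporal", "limbic", "subcortical")
_ALL_LOBES = CEREBRAL_LOBES + ("cerebellar",)


@dataclass(frozen=True)
class Parcellation:
    """Per-region metadata: id, label, hemisphere, lobe, centroid (MNI mm)."""

    ids: tuple[str, ...]
    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    lobe: tuple[str, ...]
    centroids: np.ndarray  # n x 3, mm

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("region ids must be unique")
        if not (len(self.labels) == len(self.hemisphere) == len(self.lobe) == n):
            raise ValueError("all per-region columns must have equal length")
        for h in self.hemisphere:
            if h not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {h!r}; expected one of {HEMISPHERES}")
        for l in self.lobe:
            if l not in _ALL_LOBES:
                raise ValueError(f"unknown lobe {l!r}; expected one of {_ALL_LOBES}")
        c = np.asarray(self.centroids, dtype=float)
        if c.shape != (n, 3) or not np.isfinite(c).all():
            raise ValueError("centroids must be a finite n x 3 array")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "centroids", c)

    @property
    def n_regions(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "label": self.labels,
                "hemisphere": self.hemisphere,
                "lobe": self.lobe,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        required = ["id", "label", "hemisphere", "lobe", "x", "y", "z"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"parcellation table missing columns: {missing}")
        return cls(
            ids=tuple(str(v) for v in df["id"]),
            labels=tuple(str(v) for v in df["label"]),
            hemisphere=tuple(str(v) for v in df["hemisphere"]),
            lobe=tuple(str(v) for v in df["lobe"]),
            centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        )


Pair = tuple[int, int]


@dataclass(frozen=True)
class RegionHierarchy:
    """Named unordered node-pair subsets plus the gating parent map.

    ``order`` lists the subsets in reporting order (whole brain, hemispheres,
    cerebellum, between-hemispheres, then per-hemisphere lobes and the
    between-lobe sets); ``parents`` maps each subset to the one whose test
    gates it (None for the whole brain).
    """

    subsets: dict[str, frozenset[Pair]]
    parents: dict[str, str | None]
    order: tuple[str, ...]

    def pairs(self, name: str) -> frozenset[Pair]:
        return self.subsets[name]


def _pairs_within(idx: np.ndarray) -> set[Pair]:
    return {(int(a), int(b)) for k, a in enumerate(idx) for b in idx[k + 1:]}


def _pairs_between(idx_a: np.ndarray, idx_b: np.ndarray) -> set[Pair]:
    return {(min(int(a), int(b)), max(int(a), int(b))) for a in idx_a for b in idx_b}


def build_hierarchy(p: Parcellation) -> RegionHierarchy:
    """Enumerate the nested edge subsets for a parcellation.

    Cerebellar/vermis regions form their own top-level subset and are
    excluded from the cerebral-hemisphere subsets; cerebellum-to-cerebrum
    pairs count toward the whole brain only.  "between_hemispheres" is all
    left x right cerebral pairs.
    """
    hemi = np.asarray(p.hemisphere)
    lobe = np.asarray(p.lobe)
    n = p.n_regions
    left = np.where(hemi == "left")[0]
    right = np.where(hemi == "right")[0]
    cereb = np.where(hemi == "cerebellum")[0]

    subsets: dict[str, frozenset[Pair]] = {}
    parents: dict[str, str | None] = {}
    order: list[str] = []

    def add(name: str, pairs: set[Pair], parent: str | None) -> None:
        subsets[name] = frozenset(pairs)
        parents[name] = parent
        order.append(name)

    all_pairs = _pairs_within(np.arange(n))
    add("whole_brain", all_pairs, None)
    add("left_hemisphere", _pairs_within(left), "whole_brain")
    add("right_hemisphere", _pairs_within(right), "whole_brain")
    add("cerebellum", _pairs_within(cereb), "whole_brain")
    add("between_hemispheres", _pairs_between(left, right), "whole_brain")

    for side, idx in (("left", left), ("right", right)):
        hemi_name = f"{side}_hemisphere"
        within_lobe: set[Pair] = set()
        for lb in CEREBRAL_LOBES:
            lobe_idx = idx[lobe[idx] == lb]
            pairs = _pairs_within(lobe_idx)
            add(f"{side}/{lb}", pairs, hemi_name)
            within_lobe |= pairs
        add(f"{side}/between_lobe", subsets[hemi_name] - within_lobe, hemi_name)

    return RegionHierarchy(subsets=subsets, parents=parents, order=tuple(order))


def mean_euclidean_distance(pairs, p: Parcellation) -> float:
    """Mean straight-line centroid distance (mm) over an edge subset."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty subset has no mean distance")
    idx = np.asarray(pairs, dtype=int)
    diff = p.centroids[idx[:, 0]] - p.centroids[idx[:, 1]]
    return float(np.linalg.norm(diff, axis=1).mean())
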