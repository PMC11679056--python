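"""Stratified camera partitioning for object-detection datasets.

Camera-trap datasets are split by *camera* (whole scenes), so the detector is
evaluated on unseen scenes.  A random camera split easily concentrates a
minority class or a size range in one subset; instead, the assignment of
cameras to train/validation/test is chosen by exhaustive search to minimise

    sigma_N^2 + sigma_S^2 + sigma_R^2

where, across the three subsets, sigma_N^2 sums the per-class variances of
objects-per-image rates, sigma_S^2 the per-(class, size-category) variances
of those rates, and sigma_R^2 the per-class variances of the day fraction of
boxes.  Size categories (small/medium/large) come from 1-D k-medoids (PAM,
k=3) on normalised box areas — medoids rather than means so outlying
close-to-camera boxes do not drag the centres.

Subset statistics pool member cameras by totals (total boxes / total images),
and the population variance over the three subset values is used throughout.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from traplapse.sequence import Modality

logger = logging.getLogger(__name__)

SUBSETS = ("train", "val", "test")
SIZE_NAMES = ("small", "medium", "large")


@dataclass(frozen=True)
class BoxAnnotation:
    """One normalised centre-format bounding box with camera/modality context."""

    image_id: str
    camera_id: str
    class_label: str
    cx: float
    cy: float
    w: float
    h: float
    modality: Modality

    def __post_init__(self):
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box centre out of range: ({self.cx}, {self.cy})")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box extent out of range: ({self.w}, {self.h})")

    @property
    def area(self) -> float:
        return self.w * self.h


# --------------------------------------------------------------------------
# k-medoids size categories


class KMedoids1D(BaseEstimator, ClusterMixin):
    """Exact k-medoids on scalar data with absolute distance (the PAM objective).

    Medoids are data points, so the size categories are robust to the long
    upper tail of box areas.  In one dimension the summed-L1 k-medoid
    objective is solved exactly: an optimal solution partitions the sorted
    data into k contiguous segments whose medoids are the segment medians,
    which a dynamic program finds in O(k n^2).  (Generic PAM build+swap is a
    local search and can stall one swap short of the optimum; the exact
    solution keeps the optimality contract.)  Deterministic: ties resolve to
    the earlier segment boundary / smaller medoid.

    Attributes
    ----------
    medoids_ : (k,) ndarray, sorted ascending
    labels_ : (n,) ndarray of category indices (0 = smallest medoid)
    inertia_ : float, summed absolute distance to nearest medoid
    """

    def __init__(self, n_clusters: int = 3, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.random_state = random_state  # exact solver is deterministic; kept for API symmetry

    def fit(self, X, y=None) -> "KMedoids1D":
        x = np.asarray(X, dtype=np.float64).reshape(-1)
        k = self.n_clusters
        if np.unique(x).size < k:
            raise ValueError(f"need at least {k} distinct values, got {np.unique(x).size}")
        xs = np.sort(x)
        n = xs.size
        P = np.concatenate([[0.0], np.cumsum(xs)])  # prefix sums

        def seg_costs(j: int) -> np.ndarray:
            """cost(i, j) of one cluster on xs[i..j] for all i <= j (medoid = lower median)."""
            i = np.arange(j + 1)
            m = (i + j) // 2
            xm = xs[m]
            right = (P[j + 1] - P[m]) - (j - m + 1) * xm
            left = (m - i + 1) * xm - (P[m + 1] - P[i])
            return right + left

        # dp[c][j]: best cost of covering xs[0..j] with c+1 clusters
        dp = np.full((k, n), np.inf)
        back = np.zeros((k, n), dtype=int)
        for j in range(n):
            dp[0, j] = seg_costs(j)[0]
        for c in range(1, k):
            for j in range(c, n):
                cand = dp[c - 1, c - 1:j] + seg_costs(j)[c:j + 1]
                s = int(np.argmin(cand))  # first minimum: deterministic tie-break
                dp[c, j] = cand[s]
                back[c, j] = s + c  # segment start index
        # backtrack segment boundaries
        bounds = []
        j = n - 1
        for c in range(k - 1, 0, -1):
            start = back[c, j]
            bounds.append((start, j))
            j = start - 1
        bounds.append((0, j))
        medoids = [xs[(i + j) // 2] for i, j in reversed(bounds)]
        self.medoids_ = np.sort(np.asarray(medoids))
        self.inertia_ = float(max(dp[k - 1, n - 1], 0.0))  # guard prefix-sum cancellation
        self.labels_ = self.predict(x)
        return self

    def predict(self, X) -> np.ndarray:
        """Nearest-medoid assignment; ties go to the smaller medoid."""
        x = np.asarray(X, dtype=np.float64).reshape(-1)
        d = np.abs(x[:, None] - self.medoids_[None, :])
        return d.argmin(axis=1)  # argmin takes the first (smaller medoid) on ties


@dataclass
class SizeModel:
    """Three box-size categories defined by k-medoid centres on normalised areas."""

    medoids: np.ndarray

    def __post_init__(self):
        self.medoids = np.sort(np.asarray(self.medoids, dtype=np.float64))

    def category(self, area: float) -> str:
        d = np.abs(self.medoids - area)
        return SIZE_NAMES[int(d.argmin())]


def cluster_box_sizes(areas: Sequence[float], k: int = 3, seed: int | None = None) -> SizeModel:
    """Fit the global small/medium/large size model on normalised box areas."""
    km = KMedoids1D(n_clusters=k, random_state=seed).fit(np.asarray(areas))
    return SizeModel(medoids=km.medoids_)


# --------------------------------------------------------------------------
# Per-camera statistics


@dataclass
class CameraStats:
    """Per-camera annotation bookkeeping feeding the partition objective.

    Counts are canonical (they pool exactly across cameras); the rate and
    fraction views required by the objective are derived properties.
    """

    camera_id: str
    n_images: int
    class_counts: dict[str, int] = field(default_factory=dict)
    size_class_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    day_counts: dict[str, int] = field(default_factory=dict)
    night_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_counts)

    def class_rate(self, cls: str) -> float:
        return self.class_counts.get(cls, 0) / self.n_images

    def size_class_rate(self, cls: str, size: str) -> float:
        return self.size_class_counts.get((cls, size), 0) / self.n_images

    def day_fraction(self, cls: str) -> float | None:
        """Day boxes / all boxes of the class; None (undefined) when absent."""
        day = self.day_counts.get(cls, 0)
        night = self.night_counts.get(cls, 0)
        total = day + night
        return None if total == 0 else day / total


def camera_statistics(
    annotations: Iterable[BoxAnnotation],
    image_index: Mapping[str, tuple[str, Modality]],
    size_model: SizeModel | None = None,
) -> list[CameraStats]:
    """Aggregate annotations into one :class:`CameraStats` per camera.

    Every image in ``image_index`` counts toward its camera's denominator,
    including images with zero boxes.  Size-category counts are filled only
    when a ``size_model`` is supplied.
    """
    per_cam: dict[str, CameraStats] = {}
    n_images: dict[str, int] = {}
    for _, (cam, _) in image_index.items():
        n_images[cam] = n_images.get(cam, 0) + 1
    for cam, n in n_images.items():
        per_cam[cam] = CameraStats(camera_id=cam, n_images=n)
    for ann in annotations:
        if ann.image_id not in image_index:
            raise ValueError(f"annotation references unknown image {ann.image_id!r}")
        cam, _ = image_index[ann.image_id]
        st = per_cam[cam]
        st.class_counts[ann.class_label] = st.class_counts.get(ann.class_label, 0) + 1
        if size_model is not None:
            key = (ann.class_label, size_model.category(ann.area))
            st.size_class_counts[key] = st.size_class_counts.get(key, 0) + 1
        if ann.modality is Modality.DAY:
            st.day_counts[ann.class_label] = st.day_counts.get(ann.class_label, 0) + 1
        else:
            st.night_counts[ann.class_label] = st.night_counts.get(ann.class_label, 0) + 1
    return [per_cam[c] for c in sorted(per_cam)]


# --------------------------------------------------------------------------
# Partition objective


@dataclass
class PartitionResult:
    """A 3-way camera assignment with its objective decomposition."""

    assignment: dict[str, str]
    sigma_n2: float
    sigma_s2: float
    sigma_r2: float
    objective: float
    n_candidates: int | None = None

    def cameras(self, subset: str) -> list[str]:
        return sorted(c for c, s in self.assignment.items() if s == subset)


def _pop_var(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=np.float64)
    return float(v.var())  # population variance, n denominator


def partition_objective(
    assignment: Mapping[str, str], stats: Sequence[CameraStats]
) -> PartitionResult:
    """Evaluate the summed-variance objective of a camera assignment.

    Member cameras of each subset are pooled by totals.  Classes absent from
    any subset are skipped in the day-fraction term (their fraction is
    undefined there), with a logged note.
    """
    by_cam = {s.camera_id: s for s in stats}
    missing = set(by_cam) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover cameras: {sorted(missing)}")
    groups: dict[str, list[CameraStats]] = {s: [] for s in SUBSETS}
    for cam, sub in assignment.items():
        if sub not in groups:
            raise ValueError(f"unknown subset {sub!r} for camera {cam!r}")
        if cam in by_cam:
            groups[sub].append(by_cam[cam])
    for sub, members in groups.items():
        if not members:
            raise ValueError(f"subset {sub!r} is empty")

    classes = sorted({c for s in stats for c in s.class_counts})
    sizes = sorted({sz for s in stats for (_, sz) in s.size_class_counts})

    def pooled(members: list[CameraStats]):
        imgs = sum(m.n_images for m in members)
        cls_rate = {
            c: sum(m.class_counts.get(c, 0) for m in members) / imgs for c in classes
        }
        size_rate = {
            (c, sz): sum(m.size_class_counts.get((c, sz), 0) for m in members) / imgs
            for c in classes
            for sz in sizes
        }
        day_frac = {}
        for c in classes:
            day = sum(m.day_counts.get(c, 0) for m in members)
            night = sum(m.night_counts.get(c, 0) for m in members)
            day_frac[c] = None if day + night == 0 else day / (day + night)
        return cls_rate, size_rate, day_frac

    pooled_stats = [pooled(groups[s]) for s in SUBSETS]

    sigma_n2 = sum(_pop_var([p[0][c] for p in pooled_stats]) for c in classes)
    sigma_s2 = sum(
        _pop_var([p[1][(c, sz)] for p in pooled_stats]) for c in classes for sz in sizes
    )
    sigma_r2 = 0.0
    for c in classes:
        fracs = [p[2][c] for p in pooled_stats]
        if any(f is None for f in fracs):
            logger.debug("class %s absent from a subset; skipped in day-fraction term", c)
            continue
        sigma_r2 += _pop_var(fracs)

    return PartitionResult(
        assignment=dict(assignment),
        sigma_n2=sigma_n2,
        sigma_s2=sigma_s2,
        sigma_r2=sigma_r2,
        objective=sigma_n2 + sigma_s2 + sigma_r2,
    )


# --------------------------------------------------------------------------
# Exhaustive constrained optimisation


def _enumerate_assignments(
    cameras: Sequence[str],
    subset_sizes: tuple[int, int, int],
    forced: Mapping[str, str],
):
    """Yield all assignments respecting subset sizes and forced placements.

    Enumeration order is lexicographic in the sorted camera tuples (train,
    then val), which fixes the tie-break deterministically.
    """
    cameras = sorted(cameras)
    n_train, n_val, n_test = subset_sizes
    forced_by_sub = {s: sorted(c for c, fs in forced.items() if fs == s) for s in SUBSETS}
    for sub, need in zip(SUBSETS, (n_train, n_val, n_test)):
        if len(forced_by_sub[sub]) > need:
            raise ValueError(f"forced placements exceed size of subset {sub!r}")
    free = [c for c in cameras if c not in forced]
    for extra_train in itertools.combinations(free, n_train - len(forced_by_sub["train"])):
        rest = [c for c in free if c not in extra_train]
        for extra_val in itertools.combinations(rest, n_val - len(forced_by_sub["val"])):
            test = [c for c in rest if c not in extra_val]
            if len(test) + len(forced_by_sub["test"]) != n_test:
                continue
            assignment = dict(forced)
            assignment.update({c: "train" for c in extra_train})
            assignment.update({c: "val" for c in extra_val})
            assignment.update({c: "test" for c in test})
            yield assignment


def optimize_partition(
    stats: Sequence[CameraStats],
    subset_sizes: tuple[int, int, int] = (6, 2, 2),
    forced: Mapping[str, str] | None = None,
    max_fraction: float = 0.25,
) -> PartitionResult:
    """Exhaustively find the feasible camera assignment minimising the objective.

    An assignment is rejected when the validation or test subset holds more
    than ``max_fraction`` of all annotated images.  Ties between equal
    objectives resolve to the first assignment in lexicographic enumeration
    order of the sorted camera lists.
    """
    forced = dict(forced or {})
    cameras = sorted(s.camera_id for s in stats)
    if sum(subset_sizes) != len(cameras):
        raise ValueError(
            f"subset sizes {subset_sizes} do not sum to camera count {len(cameras)}"
        )
    unknown = set(forced) - set(cameras)
    if unknown:
        raise ValueError(f"forced placements name unknown cameras: {sorted(unknown)}")
    total_images = sum(s.n_images for s in stats)
    images = {s.camera_id: s.n_images for s in stats}

    best: PartitionResult | None = None
    n_candidates = 0
    n_feasible = 0
    for assignment in _enumerate_assignments(cameras, subset_sizes, forced):
        n_candidates += 1
        val_imgs = sum(images[c] for c, s in assignment.items() if s == "val")
        test_imgs = sum(images[c] for c, s in assignment.items() if s == "test")
        if val_imgs > max_fraction * total_images or test_imgs > max_fraction * total_images:
            continue
        n_feasible += 1
        res = partition_objective(assignment, stats)
        if best is None or res.objective < best.objective - 1e-15:
            best = res
    if best is None:
        raise ValueError(
            f"no feasible assignment: all {n_candidates} candidates violate the "
            f"{max_fraction:.0%} image cap on val/test"
        )
    best.n_candidates = n_candidates
    logger.info(
        "partition search: %d candidates, %d feasible, best objective %.6g",
        n_candidates, n_feasible, best.objective,
    )
    return best


class CameraPartitioner(BaseEstimator):
    """Estimator facade over the exhaustive partition search.

    ``fit`` consumes a list of :class:`CameraStats` and exposes the winning
    assignment and objective decomposition as fitted attributes.
    """

    def __init__(
        self,
        subset_sizes: tuple[int, int, int] = (6, 2, 2),
        forced: dict[str, str] | None = None,
        max_fraction: float = 0.25,
    ):
        self.subset_sizes = subset_sizes
        self.forced = forced
        self.max_fraction = max_fraction

    def fit(self, X: Sequence[CameraStats], y=None) -> "CameraPartitioner":
        res = optimize_partition(
            X, tuple(self.subset_sizes), self.forced, self.max_fraction
        )
        self.result_ = res
        self.assignment_ = res.assignment
        self.objective_ = res.objective
        return self

    def predict(self, X: Sequence[CameraStats]) -> list[str]:
        """Subset label for each camera in ``X`` (must have been seen in fit)."""
        return [self.assignment_[s.camera_id] for s in X]
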