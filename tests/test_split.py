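"""Camera statistics, k-medoids size categories, partition objective and optimizer."""

import itertools

import numpy as np
import pytest

from traplapse.sequence import Modality
from traplapse.split import (
    BoxAnnotation,
    CameraPartitioner,
    CameraStats,
    KMedoids1D,
    SizeModel,
    camera_statistics,
    cluster_box_sizes,
    optimize_partition,
    partition_objective,
)

# --------------------------------------------------------------------------
# Independent oracles


def oracle_kmedoids_cost(x, k=3):
    """Exhaustive search over all C(n, k) medoid sets; returns (cost, medoids)."""
    x = np.asarray(x, dtype=float)
    best = (np.inf, None)
    for meds in itertools.combinations(range(len(x)), k):
        cost = sum(min(abs(v - x[m]) for m in meds) for v in x)
        if cost < best[0] - 1e-12:
            best = (cost, tuple(sorted(x[list(meds)])))
    return best


def oracle_objective(assignment, stats):
    """Plain-loop recomputation of the summed-variance objective."""
    classes = sorted({c for s in stats for c in s.class_counts})
    sizes = sorted({sz for s in stats for (_, sz) in s.size_class_counts})
    subsets = ("train", "val", "test")

    def pool(sub):
        members = [s for s in stats if assignment[s.camera_id] == sub]
        imgs = sum(m.n_images for m in members)
        out = {}
        for c in classes:
            out[("N", c)] = sum(m.class_counts.get(c, 0) for m in members) / imgs
            for sz in sizes:
                out[("S", c, sz)] = (
                    sum(m.size_class_counts.get((c, sz), 0) for m in members) / imgs
                )
            day = sum(m.day_counts.get(c, 0) for m in members)
            night = sum(m.night_counts.get(c, 0) for m in members)
            out[("R", c)] = None if day + night == 0 else day / (day + night)
        return out

    pooled = [pool(s) for s in subsets]

    def popvar(vals):
        mean = sum(vals) / 3
        return sum((v - mean) ** 2 for v in vals) / 3

    total = 0.0
    for c in classes:
        total += popvar([p[("N", c)] for p in pooled])
        for sz in sizes:
            total += popvar([p[("S", c, sz)] for p in pooled])
        fracs = [p[("R", c)] for p in pooled]
        if all(f is not None for f in fracs):
            total += popvar(fracs)
    return total


def random_stats(rng, n_cameras, classes=("a", "b"), sizes=("small", "large")):
    out = []
    for i in range(n_cameras):
        n_images = int(rng.integers(20, 200))
        cls_counts, size_counts, day, night = {}, {}, {}, {}
        for c in classes:
            total = int(rng.integers(0, 4 * n_images))
            cls_counts[c] = total
            split = rng.multinomial(total, [1 / len(sizes)] * len(sizes))
            for sz, v in zip(sizes, split):
                if v:
                    size_counts[(c, sz)] = int(v)
            d = int(rng.integers(0, total + 1))
            if d:
                day[c] = d
            if total - d:
                night[c] = total - d
        out.append(
            CameraStats(
                camera_id=f"C{i:02d}", n_images=n_images, class_counts=cls_counts,
                size_class_counts=size_counts, day_counts=day, night_counts=night,
            )
        )
    return out


# --------------------------------------------------------------------------
# Camera statistics


def _ann(image_id, cls, modality=Modality.DAY, area_side=0.1):
    return BoxAnnotation(
        image_id=image_id, camera_id="", class_label=cls,
        cx=0.5, cy=0.5, w=area_side, h=area_side, modality=modality,
    )


class TestCameraStatistics:
    def test_class_rate_is_boxes_per_image(self):
        # mirrors a real deployment camera: 1072 images, 1226 adult boxes
        index = {f"img{i}": ("cam", Modality.DAY) for i in range(1072)}
        anns = [_ann(f"img{i % 1072}", "adult") for i in range(1226)]
        (st,) = camera_statistics(anns, index)
        assert st.class_rate("adult") == pytest.approx(1226 / 1072)

    def test_day_fraction(self):
        # 127 day and 2 night adult boxes -> fraction 127/129
        index = {f"i{k}": ("cam", Modality.DAY) for k in range(130)}
        anns = [_ann(f"i{k}", "adult", Modality.DAY) for k in range(127)]
        anns += [_ann(f"i{127 + k}", "adult", Modality.NIGHT) for k in range(2)]
        (st,) = camera_statistics(anns, index)
        assert st.day_fraction("adult") == pytest.approx(127 / 129)

    def test_absent_class_has_zero_rate_and_undefined_fraction(self):
        index = {"i0": ("cam", Modality.DAY)}
        (st,) = camera_statistics([_ann("i0", "adult")], index)
        assert st.class_rate("chick") == 0.0
        assert st.day_fraction("chick") is None

    def test_empty_images_count_in_denominator(self):
        index = {"i0": ("cam", Modality.DAY), "i1": ("cam", Modality.DAY)}
        (st,) = camera_statistics([_ann("i0", "adult")], index)
        assert st.n_images == 2
        assert st.class_rate("adult") == 0.5

    def test_unknown_image_is_hard_error(self):
        with pytest.raises(ValueError, match="unknown image"):
            camera_statistics([_ann("ghost", "adult")], {"i0": ("cam", Modality.DAY)})

    def test_size_rates_partition_class_rate(self, rng):
        size_model = SizeModel(medoids=[0.001, 0.01, 0.1])
        index = {f"i{k}": ("cam", Modality.DAY) for k in range(50)}
        anns = [
            _ann(f"i{rng.integers(50)}", "adult", area_side=float(rng.uniform(0.02, 0.5)))
            for _ in range(200)
        ]
        (st,) = camera_statistics(anns, index, size_model)
        total = sum(st.size_class_rate("adult", sz) for sz in ("small", "medium", "large"))
        assert total == pytest.approx(st.class_rate("adult"), abs=1e-9)


# --------------------------------------------------------------------------
# k-medoids


class TestKMedoids:
    def test_worked_example(self):
        model = cluster_box_sizes([0.1, 0.12, 0.5, 0.52, 0.9], k=3)
        km = KMedoids1D(n_clusters=3).fit([0.1, 0.12, 0.5, 0.52, 0.9])
        assert km.inertia_ == pytest.approx(0.04)
        labels = km.predict([0.1, 0.12, 0.5, 0.52, 0.9])
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert len({labels[0], labels[2], labels[4]}) == 3
        assert model.category(0.9) == "large" and model.category(0.11) == "small"

    def test_duplicate_groups_give_zero_cost(self):
        x = [0.2] * 4 + [0.5] * 3 + [0.8] * 5
        km = KMedoids1D(n_clusters=3).fit(x)
        assert km.inertia_ == 0.0
        assert set(km.medoids_) == {0.2, 0.5, 0.8}

    def test_medoids_are_data_points(self, rng):
        x = rng.uniform(size=30)
        km = KMedoids1D(n_clusters=3).fit(x)
        assert all(any(np.isclose(m, v) for v in x) for m in km.medoids_)

    def test_requires_k_distinct_values(self):
        with pytest.raises(ValueError):
            KMedoids1D(n_clusters=3).fit([0.1, 0.1, 0.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = np.round(rng.uniform(0.001, 0.9, size=n), 4)
        if np.unique(x).size < 3:
            pytest.skip("degenerate draw")
        km = KMedoids1D(n_clusters=3).fit(x)
        best_cost, best_meds = oracle_kmedoids_cost(x, 3)
        assert km.inertia_ == pytest.approx(best_cost, abs=1e-12)

    def test_tie_assignment_goes_to_smaller_medoid(self):
        model = SizeModel(medoids=[0.2, 0.4, 0.8])
        assert model.category(0.3) == "small"  # equidistant: smaller medoid wins


# --------------------------------------------------------------------------
# Partition objective and optimizer


def identical_stats(n):
    return [
        CameraStats(
            camera_id=f"C{i}", n_images=100, class_counts={"a": 150},
            day_counts={"a": 100}, night_counts={"a": 50},
        )
        for i in range(n)
    ]


class TestPartitionObjective:
    def test_identical_cameras_give_zero_variances(self):
        stats = identical_stats(4)
        assignment = {"C0": "train", "C1": "train", "C2": "val", "C3": "test"}
        res = partition_objective(assignment, stats)
        assert res.sigma_n2 == res.sigma_s2 == res.sigma_r2 == 0.0
        assert res.objective == 0.0

    def test_hand_computed_population_variance(self):
        stats = [
            CameraStats(camera_id=f"C{i}", n_images=10, class_counts={"a": 10 * (i + 1)})
            for i in range(3)
        ]
        assignment = {"C0": "train", "C1": "val", "C2": "test"}
        res = partition_objective(assignment, stats)
        # subset rates 1, 2, 3 -> population variance 2/3; no size or day terms
        assert res.sigma_n2 == pytest.approx(2 / 3)
        assert res.sigma_s2 == 0.0 and res.sigma_r2 == 0.0
        assert res.objective == pytest.approx(res.sigma_n2 + res.sigma_s2 + res.sigma_r2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        stats = random_stats(rng, 5)
        assignment = {"C00": "train", "C01": "train", "C02": "val", "C03": "test", "C04": "test"}
        res = partition_objective(assignment, stats)
        assert res.objective == pytest.approx(oracle_objective(assignment, stats), abs=1e-12)

    def test_empty_subset_rejected(self):
        stats = identical_stats(3)
        with pytest.raises(ValueError, match="empty"):
            partition_objective({"C0": "train", "C1": "train", "C2": "val"}, stats)

    def test_incomplete_assignment_rejected(self):
        stats = identical_stats(3)
        with pytest.raises(ValueError, match="cover"):
            partition_objective({"C0": "train", "C1": "val"}, stats)


class TestOptimizePartition:
    def test_candidate_count_with_forced_camera(self):
        # 10 cameras, sizes (6, 2, 2), one forced to train: C(9,5) * C(4,2) = 756
        stats = identical_stats(10)
        res = optimize_partition(stats, (6, 2, 2), {"C0": "train"}, max_fraction=1.0)
        assert res.n_candidates == 756

    def test_degenerate_case_zero_objective_and_tie_break(self):
        stats = identical_stats(5)
        res = optimize_partition(stats, (3, 1, 1), max_fraction=1.0)
        assert res.objective == 0.0
        # lexicographically first assignment wins the tie
        assert res.cameras("train") == ["C0", "C1", "C2"]
        assert res.cameras("val") == ["C3"] and res.cameras("test") == ["C4"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_winner(self, seed):
        rng = np.random.default_rng(100 + seed)
        stats = random_stats(rng, 6)
        res = optimize_partition(stats, (4, 1, 1), max_fraction=0.5)
        # independent brute force with the loop oracle
        cams = [s.camera_id for s in stats]
        total = sum(s.n_images for s in stats)
        best = np.inf
        for val_test in itertools.permutations(cams, 2):
            assignment = {c: "train" for c in cams}
            assignment[val_test[0]] = "val"
            assignment[val_test[1]] = "test"
            imgs = {s.camera_id: s.n_images for s in stats}
            if imgs[val_test[0]] > 0.5 * total or imgs[val_test[1]] > 0.5 * total:
                continue
            best = min(best, oracle_objective(assignment, stats))
        assert res.objective == pytest.approx(best, abs=1e-12)

    def test_forced_placements_honoured(self, rng):
        stats = random_stats(rng, 6)
        res = optimize_partition(stats, (4, 1, 1), {"C03": "val"}, max_fraction=1.0)
        assert res.assignment["C03"] == "val"

    def test_image_cap_enforced(self):
        stats = identical_stats(4)
        stats[0] = CameraStats(camera_id="C0", n_images=1000, class_counts={"a": 150},
                               day_counts={"a": 100}, night_counts={"a": 50})
        res = optimize_partition(stats, (2, 1, 1), max_fraction=0.25)
        assert res.assignment["C0"] == "train"  # too big for val or test

    def test_infeasible_raises_naming_constraint(self):
        stats = identical_stats(3)
        with pytest.raises(ValueError, match="image cap"):
            optimize_partition(stats, (1, 1, 1), max_fraction=0.1)

    def test_sizes_must_sum_to_camera_count(self):
        with pytest.raises(ValueError, match="sum"):
            optimize_partition(identical_stats(4), (2, 1, 2))

    def test_group_mixing_recovery(self, rng):
        # three camera groups with divergent class rates: the optimal (3,3,3)
        # partition puts one camera of each group in each subset, beating the
        # group-aligned assignment
        stats = []
        for g, rate in enumerate([1.0, 5.0, 9.0]):
            for j in range(3):
                n = 100
                count = int(rate * n + rng.integers(-10, 10))
                stats.append(
                    CameraStats(camera_id=f"G{g}J{j}", n_images=n, class_counts={"a": count},
                                day_counts={"a": count})
                )
        res = optimize_partition(stats, (3, 3, 3), max_fraction=0.5)
        aligned = {f"G{g}J{j}": sub for g, sub in enumerate(("train", "val", "test"))
                   for j in range(3)}
        aligned_obj = partition_objective(aligned, stats).objective
        assert res.objective < aligned_obj
        for sub in ("train", "val", "test"):
            groups = {c[:2] for c in res.cameras(sub)}
            assert len(groups) == 3  # one camera of each rate group

    def test_estimator_facade(self, rng):
        stats = random_stats(rng, 5)
        part = CameraPartitioner(subset_sizes=(3, 1, 1), max_fraction=1.0).fit(stats)
        assert set(part.assignment_) == {s.camera_id for s in stats}
        assert part.predict(stats) == [part.assignment_[s.camera_id] for s in stats]
        assert part.objective_ == part.result_.objective
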