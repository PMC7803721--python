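import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

from strokedti.atlas import LabelVolume, RegionMask, region_mask
from strokedti.errors import (
    EmptyRegionError,
    GridError,
    IncompleteSeriesError,
    ParameterError,
)
from strokedti.lesion import (
    LesionMask,
    affected_regions,
    consolidation_slope,
    incidence_map,
    lesion_volume,
    percent_infarct,
    ward_cluster,
)


def _random_mask(rng, shape, p=0.3, subject="s1", day=1):
    return LesionMask(rng.random(shape) < p, subject, day)


class TestLesionVolume:
    def test_empty_mask_zero(self, random_labels):
        labels = random_labels(0)
        mask = LesionMask(np.zeros(labels.shape, bool), "s", 1)
        assert lesion_volume(mask, labels) == 0.0

    def test_thousand_voxels_at_point_one_mm(self, ontology):
        labels = LabelVolume(np.zeros((10, 10, 10), np.int32), (0.1, 0.1, 0.1),
                             midline_index=5)
        grid = np.zeros((10, 10, 10), bool)
        grid[:] = True
        assert lesion_volume(LesionMask(grid, "s", 1), labels) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_equals_count_oracle(self, random_labels, seed):
        labels = random_labels(seed)
        rng = np.random.default_rng(seed)
        mask = _random_mask(rng, labels.shape)
        count = sum(
            1
            for x, y, z in itertools.product(*(range(s) for s in labels.shape))
            if mask.grid[x, y, z]
        )
        assert lesion_volume(mask, labels) == pytest.approx(
            count * labels.voxel_volume_mm3)

    def test_shape_mismatch(self, random_labels):
        labels = random_labels(0)
        with pytest.raises(GridError):
            lesion_volume(LesionMask(np.zeros((4, 4, 4), bool), "s", 1), labels)


class TestAffectedRegions:
    def test_single_region_mask(self, ontology):
        grid = np.zeros((10, 10, 10), np.int32)
        grid[6:9, 2:5, 2:5] = ontology.by_acronym("MOp").region_id
        labels = LabelVolume(grid, (0.1,) * 3, midline_index=5)
        lesion = LesionMask(grid > 0, "s", 1)
        assert affected_regions(lesion, labels, ontology) == {"MOp"}

    def test_empty_mask_empty_set(self, ontology, random_labels):
        labels = random_labels(1)
        lesion = LesionMask(np.zeros(labels.shape, bool), "s", 1)
        assert affected_regions(lesion, labels, ontology) == set()

    @pytest.mark.parametrize("seed", range(3))
    def test_random_equals_overlap_count_oracle(self, ontology, random_labels, seed):
        labels = random_labels(seed)
        rng = np.random.default_rng(100 + seed)
        lesion = _random_mask(rng, labels.shape, p=0.2)
        got = affected_regions(lesion, labels, ontology, min_voxels=5)
        expect = set()
        for r in ontology.leaves():
            n = 0
            for x, y, z in itertools.product(*(range(s) for s in labels.shape)):
                if (x > labels.midline_index and lesion.grid[x, y, z]
                        and labels.grid[x, y, z] == r.region_id):
                    n += 1
            if n >= 5:
                expect.add(r.acronym)
        assert got == expect

    def test_min_voxels_validated(self, ontology, random_labels):
        labels = random_labels(0)
        lesion = LesionMask(np.zeros(labels.shape, bool), "s", 1)
        with pytest.raises(ParameterError):
            affected_regions(lesion, labels, ontology, min_voxels=0)


class TestIncidenceMap:
    def _cohort(self, ontology, labels, affected_ids):
        masks = []
        for i, hit in enumerate(affected_ids):
            grid = np.zeros(labels.shape, bool)
            if hit:
                sel = labels.grid == ontology.by_acronym("MOp").region_id
                sel &= labels.hemisphere_selector("right")
                grid |= sel
            masks.append(LesionMask(grid, f"s{i}", 1))
        return masks

    def test_all_subjects_affected(self, ontology, random_labels):
        labels = random_labels(3)
        masks = self._cohort(ontology, labels, [True] * 4)
        table = incidence_map(masks, labels, ontology, day=1)
        assert table.loc[table.region == "MOp", "fraction"].item() == 1.0

    def test_half_affected(self, ontology, random_labels):
        labels = random_labels(3)
        masks = self._cohort(ontology, labels, [True, True, False, False])
        table = incidence_map(masks, labels, ontology, day=1)
        assert table.loc[table.region == "MOp", "fraction"].item() == 0.5
        assert (table.n_subjects == 4).all()

    def test_random_cohort_equals_recount_oracle(self, ontology, random_labels):
        labels = random_labels(4)
        rng = np.random.default_rng(0)
        masks = [_random_mask(rng, labels.shape, p=0.15, subject=f"s{i}")
                 for i in range(5)]
        table = incidence_map(masks, labels, ontology, day=1).set_index("region")
        for r in ontology.leaves():
            n_hit = sum(
                1 for m in masks
                if affected_regions(m, labels, ontology) >= {r.acronym}
            )
            assert table.loc[r.acronym, "fraction"] == pytest.approx(n_hit / 5)

    def test_no_subjects_at_day(self, ontology, random_labels):
        labels = random_labels(4)
        with pytest.raises(IncompleteSeriesError):
            incidence_map([], labels, ontology, day=1)


class TestPercentInfarct:
    def _region(self, shape, sl):
        grid = np.zeros(shape, bool)
        grid[sl] = True
        return RegionMask(grid, "MOp", "both")

    def test_superset_is_100(self):
        region = self._region((10, 10, 10), np.s_[2:5, 2:5, 2:5])
        mask = LesionMask(np.ones((10, 10, 10), bool), "s", 1)
        assert percent_infarct(mask, region) == 100.0

    def test_disjoint_is_0(self):
        region = self._region((10, 10, 10), np.s_[2:5, 2:5, 2:5])
        mask = LesionMask(np.zeros((10, 10, 10), bool), "s", 1)
        assert percent_infarct(mask, region) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_random_equals_voxel_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (20, 20, 20)
        region = RegionMask(rng.random(shape) < 0.4, "MOp", "both")
        mask = _random_mask(rng, shape)
        inter = denom = 0
        for x, y, z in itertools.product(range(20), repeat=3):
            if region.grid[x, y, z]:
                denom += 1
                inter += bool(mask.grid[x, y, z])
        assert percent_infarct(mask, region) == pytest.approx(100 * inter / denom)

    def test_monotone_under_mask_growth(self):
        rng = np.random.default_rng(7)
        shape = (12, 12, 12)
        region = RegionMask(rng.random(shape) < 0.5, "MOp", "both")
        small = rng.random(shape) < 0.2
        grown = small | (rng.random(shape) < 0.2)
        assert percent_infarct(LesionMask(grown, "s", 1), region) >= percent_infarct(
            LesionMask(small, "s", 1), region)

    def test_empty_region_guarded(self):
        region = RegionMask(np.zeros((5, 5, 5), bool), "MOp", "both")
        with pytest.raises(EmptyRegionError):
            percent_infarct(LesionMask(np.ones((5, 5, 5), bool), "s", 1), region)


class TestConsolidationSlope:
    def test_no_change_is_zero(self):
        assert consolidation_slope(42.0, 42.0) == 0.0

    def test_sixty_to_thirty_is_minus_five_per_day(self):
        assert consolidation_slope(60.0, 30.0) == pytest.approx(-5.0)

    def test_cohort_matches_difference_over_six(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p1, p7 = rng.uniform(0, 100, 2)
            assert consolidation_slope(p1, p7) == pytest.approx((p7 - p1) / 6)

    def test_missing_timepoint(self):
        with pytest.raises(IncompleteSeriesError):
            consolidation_slope(50.0, float("nan"))


def ward_oracle_merges(X):
    """Greedy exhaustive Ward merging; heights on the scipy (unsquared) scale."""
    X = np.asarray(X, float)
    clusters = [frozenset([i]) for i in range(len(X))]
    centroids = {frozenset([i]): X[i].copy() for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            na, nb = len(a), len(b)
            d2 = np.sum((centroids[a] - centroids[b]) ** 2)
            h = np.sqrt(2.0 * na * nb / (na + nb) * d2)
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merged = a | b
        centroids[merged] = (len(a) * centroids[a] + len(b) * centroids[b]) / len(merged)
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
        merges.append((h, merged))
    return merges


class TestWardCluster:
    def test_two_separated_clouds_perfectly_split(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(50, 0.1, (6, 2))])
        res = ward_cluster(X, k=2)
        a = set(res.assignments[:5])
        b = set(res.assignments[5:])
        assert len(a) == len(b) == 1 and a != b
        assert res.inter_cluster_distance > 10 * res.intra_cluster_distance

    def test_identical_rows_zero_intra(self):
        X = np.ones((6, 3))
        res = ward_cluster(X, k=2)
        assert res.intra_cluster_distance == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_merge_sequence_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 2))
        Z = ward_cluster(X, k=2).linkage_matrix
        oracle = ward_oracle_merges(X)
        # reconstruct merged sets from the scipy linkage
        sets = [frozenset([i]) for i in range(6)]
        for step, row in enumerate(Z):
            merged = sets[int(row[0])] | sets[int(row[1])]
            sets.append(merged)
            h_oracle, set_oracle = oracle[step]
            assert merged == set_oracle
            assert row[2] == pytest.approx(h_oracle)

    def test_inter_distance_is_final_merge_height(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        res = ward_cluster(X, k=2)
        Z = linkage(X, method="ward")
        assert res.inter_cluster_distance == pytest.approx(Z[-1, 2])
        assert res.intra_cluster_distance == pytest.approx(Z[-2, 2])

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError):
            ward_cluster(np.zeros((3, 2)), k=5)


class TestProfileInvariant:
    def test_leaf_percent_volume_sum_bounded_by_lesion_volume(
            self, ontology, atlas48):
        """Sum over leaves of percent x region volume cannot exceed the
        lesion volume (the lesion may also hit unlabeled voxels)."""
        from strokedti.synthetic import StudyDesign, make_lesions

        _, labels = atlas48
        subjects = make_lesions(StudyDesign(rng_seed=2), atlas48)
        mask = subjects["large_01"].masks[(1, "T2WI")]
        total = lesion_volume(mask, labels)
        acc = 0.0
        for r in ontology.leaves():
            rm = region_mask(labels, ontology, r.acronym, "ipsi", "right")
            if rm.n_voxels == 0:
                continue
            pct = percent_infarct(mask, rm)
            acc += pct / 100.0 * rm.n_voxels * labels.voxel_volume_mm3
        assert acc <= total + 1e-9
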