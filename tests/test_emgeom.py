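"""Immunogold geometry: distances, zones, clusters, and group statistics."""

import math

import numpy as np
import pytest

import spinenano as sn
from spinenano.emgeom import welch_p_from_summaries


def square_contour(side=1000.0):
    return sn.MembraneContour(
        [[0, 0], [side, 0], [side, side], [0, side]]
    )


@pytest.fixture(scope="module")
def square_spine():
    """1 um square spine with the PSD on the top edge's middle section."""
    # vertices densified along the top edge so the PSD arc is addressable
    top = [[x, 1000.0] for x in np.linspace(1000, 0, 21)]
    verts = [[0, 0], [1000, 0], [1000, 1000]] + top[1:-1] + [[0, 1000]]
    contour = sn.MembraneContour(verts)
    # PSD spans x in [350, 650] on the top edge
    xs = np.array([v[0] for v in verts])
    on_top = np.flatnonzero(np.array([v[1] for v in verts]) == 1000.0)
    idx = on_top[(xs[on_top] <= 650) & (xs[on_top] >= 350)]
    return sn.SpineAnnotation(contour, sn.PsdSegment(int(idx[0]), int(idx[-1])))


class TestPointToContourDistance:
    def test_point_on_vertex_is_zero(self):
        c = square_contour()
        assert sn.point_to_contour_distance((0.0, 0.0), c) == 0.0

    def test_point_to_segment_not_vertex(self):
        c = sn.MembraneContour([[-100, 0], [100, 0], [0, -100]])
        assert sn.point_to_contour_distance((0, 10), c) == pytest.approx(10.0)

    def test_matches_densified_brute_force(self, wt_spine):
        _, ann, _ = wt_spine
        contour = ann.contour
        # brute force: sample the contour every 0.1 nm
        cum = contour.cumulative_lengths()
        s = np.arange(0, cum[-1], 0.1)
        from spinenano.synthgen import _interp_on_contour

        dense, _ = _interp_on_contour(contour, s)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-300, 300, (300, 2))
        d_fast = sn.point_to_contour_distance(pts, contour)
        for p, df in zip(pts, d_fast):
            db = np.min(np.hypot(dense[:, 0] - p[0], dense[:, 1] - p[1]))
            assert abs(df - db) < 0.1


class TestAssignZone:
    def test_particle_under_psd_midpoint_is_synaptic(self, square_spine):
        assert sn.assign_zone((500, 970), square_spine) == "synaptic"

    def test_particle_under_lateral_membrane_is_extrasynaptic(self, square_spine):
        # nearest membrane point well off the PSD arc
        assert sn.assign_zone((150, 990), square_spine) == "extrasynaptic"

    def test_deep_particle_is_cytoplasm(self, square_spine):
        assert sn.assign_zone((500, 500), square_spine) == "cytoplasm"

    def test_particle_outside_contour(self, square_spine):
        assert sn.assign_zone((500, 1200), square_spine) == "outside"

    def test_shaft_annotation_uses_nonsynaptic_zone(self):
        ann = sn.SpineAnnotation(square_contour(), compartment="dendrite-shaft")
        assert sn.assign_zone((500, 990), ann) == "nonsynaptic-shaft"

    def test_spine_without_psd_is_an_error(self):
        ann = sn.SpineAnnotation(square_contour())
        with pytest.raises(ValueError, match="PSD"):
            sn.assign_zone((500, 990), ann)

    def test_zone_partition_covers_all_in_contour_particles(self, wt_spine):
        _, ann, _ = wt_spine
        table = sn.zone_table(ann)
        zones = [z for _, z, _ in table]
        assert len(zones) == len(ann.particles)
        assert set(zones) <= {"synaptic", "extrasynaptic", "cytoplasm"}

    def test_generator_truth_zones_recovered(self, wt_spine):
        _, ann, truth = wt_spine
        truth_zone = {r["id"]: r["zone"] for r in truth["particles"]}
        table = sn.zone_table(ann)
        agree = sum(1 for p, z, _ in table if truth_zone[p.id] == z)
        assert agree == len(table)

    def test_zone_means_recover_generator_models(self, wt_spine):
        # synaptic 34 +/- 18 nm, extrasynaptic 13 +/- 5 nm (truncated)
        params, ann, truth = wt_spine
        table = sn.zone_table(ann)
        offsets = {r["id"]: r["offset"] for r in truth["particles"]}
        for zone in ("synaptic", "extrasynaptic"):
            d = np.array([dd for p, z, dd in table if z == zone])
            true_mean = np.mean(
                [offsets[p.id] for p, z, _ in table if z == zone]
            )
            se = d.std(ddof=1) / math.sqrt(len(d))
            assert abs(d.mean() - true_mean) < 3 * se + 0.1


class TestNearestNeighborDistances:
    def test_pair_is_symmetric(self):
        d = sn.nearest_neighbor_distances([[0, 0], [30, 0]])
        assert d.tolist() == [30.0, 30.0]

    def test_equilateral_triangle(self):
        pts = [[0, 0], [50, 0], [25, 25 * math.sqrt(3)]]
        np.testing.assert_allclose(sn.nearest_neighbor_distances(pts), 50.0)

    def test_subset_smaller_than_two_is_an_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            sn.nearest_neighbor_distances([[0, 0]])

    def test_poisson_mean_nnd_is_half_inverse_sqrt_intensity(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1000, (500, 2))
        lam = 500 / 1000**2
        mean_nnd = sn.nearest_neighbor_distances(pts).mean()
        assert mean_nnd == pytest.approx(0.5 / math.sqrt(lam), rel=0.05)

    def test_order_reversal_preserves_multiset(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 500, (100, 2))
        d1 = np.sort(sn.nearest_neighbor_distances(pts))
        d2 = np.sort(sn.nearest_neighbor_distances(pts[::-1]))
        np.testing.assert_allclose(d1, d2)

    def test_hard_core_process_respects_exclusion_radius(self):
        # sequential-inhibition field with 30 nm hard core
        rng = np.random.default_rng(4)
        pts: list = []
        while len(pts) < 200:
            cand = rng.uniform(0, 2000, 2)
            if not pts or np.min(
                np.hypot(*(np.array(pts) - cand).T)
            ) >= 30:
                pts.append(cand)
        assert sn.nearest_neighbor_distances(np.array(pts)).min() >= 30.0


class TestDetectGoldClusters:
    def test_isolated_particle_is_no_cluster(self):
        assert sn.detect_gold_clusters(np.array([[0.0, 0.0]]), min_size=3) == ()

    def test_two_far_groups_give_two_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.normal((0, 0), 20, (10, 2))
        b = rng.normal((1000, 0), 20, (10, 2))
        clusters = sn.detect_gold_clusters(np.vstack([a, b]), min_size=3)
        assert len(clusters) == 2

    def test_disc_cluster_diameters_in_observed_range(self):
        # 200 nm discs of particles: detected diameters within 100-300 nm
        rng = np.random.default_rng(6)
        discs = []
        for cx in (0, 1000, 2000):
            r = 100 * np.sqrt(rng.uniform(size=20))
            th = rng.uniform(0, 2 * math.pi, 20)
            discs.append(np.column_stack([cx + r * np.cos(th), r * np.sin(th)]))
        clusters = sn.detect_gold_clusters(np.vstack(discs))
        assert len(clusters) == 3
        for c in clusters:
            assert 100.0 <= c.diameter <= 300.0


class TestSummaries:
    def test_cv_of_synaptic_zone_summary(self):
        # mean 34, SD 18 => CV 0.53
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1.0, 2000)
        x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, sd 1
        s = sn.summarize_distances(34.0 + 18.0 * x)
        assert round(s.cv, 2) == 0.53

    def test_constant_vector_has_zero_sd_and_cv(self):
        s = sn.summarize_distances([7.0] * 5)
        assert s.sd == 0.0 and s.cv == 0.0

    def test_quartiles_are_ordered(self, wt_spine):
        _, ann, _ = wt_spine
        d = [dd for _, _, dd in sn.zone_table(ann)]
        s = sn.summarize_distances(d)
        assert s.p25 <= s.median <= s.p75

    def test_truncated_normal_sample_summary_within_3_se(self):
        from scipy import stats

        a, b = (0 - 34) / 18, (100 - 34) / 18
        rng = np.random.default_rng(8)
        x = stats.truncnorm.rvs(a, b, loc=34, scale=18, size=10_000,
                                random_state=rng)
        s = sn.summarize_distances(x)
        true_mean = stats.truncnorm.mean(a, b, loc=34, scale=18)
        se = stats.truncnorm.std(a, b, loc=34, scale=18) / 100.0
        assert abs(s.mean - true_mean) < 3 * se


class TestZoneLabelFractions:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"synaptic": 180, "extrasynaptic": 309},
             {"synaptic": 37, "extrasynaptic": 63}),
            ({"synaptic": 222, "extrasynaptic": 403},
             {"synaptic": 36, "extrasynaptic": 64}),
            ({"synaptic": 0, "extrasynaptic": 10},
             {"synaptic": 0, "extrasynaptic": 100}),
        ],
    )
    def test_percentages(self, counts, expected):
        out = sn.zone_label_fractions(counts)
        assert {z: v["percent"] for z, v in out.items()} == expected

    def test_raw_values_are_retained(self):
        out = sn.zone_label_fractions({"synaptic": 222, "extrasynaptic": 403})
        assert out["synaptic"]["raw"] == pytest.approx(35.52)
        assert out["extrasynaptic"]["raw"] == pytest.approx(64.48)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            sn.zone_label_fractions({"synaptic": 0})


class TestEndosomeLabelFraction:
    @staticmethod
    def _cohort(n_spines, labeled_fraction, seed):
        return [
            sn.gen_em_spine(
                sn.EmSimParams(
                    seed=seed + i,
                    zone_counts={"synaptic": 0, "extrasynaptic": 0},
                    organelle_count=7,
                    organelle_labeled_fraction=labeled_fraction,
                )
            )[0]
            for i in range(n_spines)
        ]

    def test_single_spine_fraction(self):
        orgs = tuple(
            sn.OrganelleRecord(i, "large vesicle", i < 6) for i in range(7)
        )
        ann = sn.SpineAnnotation(square_contour(), organelles=orgs)
        per_spine, mean, _ = sn.endosome_label_fraction([ann])
        assert per_spine[0] == pytest.approx(6 / 7 * 100, abs=0.05)

    @pytest.mark.parametrize(
        "frac,n,seed", [(0.86, 27, 100), (0.45, 20, 300)]
    )
    def test_cohort_mean_recovers_labeled_fraction(self, frac, n, seed):
        cohort = self._cohort(n, frac, seed)
        _, mean, sd = sn.endosome_label_fraction(cohort)
        se = math.sqrt(frac * (1 - frac) / 7 / n) * 100
        assert abs(mean - 100 * frac) < 3 * se

    def test_empty_spines_are_excluded(self):
        orgs = (sn.OrganelleRecord(0, "large vesicle", True),)
        full = sn.SpineAnnotation(square_contour(), organelles=orgs)
        empty = sn.SpineAnnotation(square_contour())
        per_spine, mean, _ = sn.endosome_label_fraction([full, empty])
        assert len(per_spine) == 1 and mean == 100.0


class TestCompareGroups:
    def test_identical_groups_are_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert sn.compare_groups(g, g)["p"] >= 0.99

    def test_exact_rank_sum_on_disjoint_triples(self):
        out = sn.compare_groups([1, 2, 3], [4, 5, 6])
        assert out["p"] == pytest.approx(0.1)

    def test_synaptic_zone_models_separate_significantly(self):
        # 34 +/- 18 (n=180) vs 45 +/- 25 (n=222), truncated to the zone:
        # always significant, and p < 1e-4 in the large majority of runs
        from scipy import stats

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            a = stats.truncnorm.rvs(
                -34 / 18, 66 / 18, loc=34, scale=18, size=180, random_state=rng
            )
            b = stats.truncnorm.rvs(
                -45 / 25, 55 / 25, loc=45, scale=25, size=222, random_state=rng
            )
            p = sn.compare_groups(a, b)["p"]
            assert p < 0.01
            hits += p < 1e-4
        assert hits >= 15

    def test_multi_group_paths_return_pairwise_pvalues(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 5, 40) for m in (13, 12, 15)]
        for test in ("kruskal-wallis", "anova-tukey"):
            out = sn.compare_groups(*groups, test=test)
            assert set(out["pairwise_p"]) == {"0-1", "0-2", "1-2"}
            assert all(0 <= p <= 1 for p in out["pairwise_p"].values())

    def test_small_groups_are_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            sn.compare_groups([1.0], [2.0, 3.0])


class TestConformationClassification:
    def test_psd_geometry_is_vertical_extended(self):
        # N-terminus 11 +/- 3 nm vs C-terminus 20 +/- 8 nm
        assert (
            sn.conformation_classification((11, 3, 275), (20, 8, 212))
            == "vertical-extended"
        )

    def test_extrasynaptic_geometry_is_parallel_or_compact(self):
        assert (
            sn.conformation_classification((16, 5, 301), (15, 5, 175))
            == "parallel-or-compact"
        )

    def test_equal_summaries_are_parallel_or_compact(self):
        assert (
            sn.conformation_classification((15, 5, 100), (15, 5, 100))
            == "parallel-or-compact"
        )

    def test_welch_test_gates_the_vertical_call(self):
        # ratio 1.6 but tiny n and huge spread: not significant
        out = sn.conformation_classification((10, 12, 10), (16, 14, 10))
        assert out == "parallel-or-compact"
        assert welch_p_from_summaries(16, 14, 10, 10, 12, 10) >= 0.05

    def test_zero_mean_is_an_error(self):
        with pytest.raises(ValueError, match="mean"):
            sn.conformation_classification((0, 1, 20), (10, 1, 20))


class TestRigidMotionInvariance:
    def test_distances_and_zones_survive_rotation(self, wt_spine):
        _, ann, _ = wt_spine
        theta = 1.1
        R = np.array(
            [[math.cos(theta), -math.sin(theta)],
             [math.sin(theta), math.cos(theta)]]
        )
        shift = np.array([500.0, -200.0])
        contour2 = sn.MembraneContour(ann.contour.vertices @ R.T + shift)
        xy2 = ann.particle_xy() @ R.T + shift
        particles2 = tuple(
            sn.GoldParticle(float(x), float(y), id=p.id)
            for (x, y), p in zip(xy2, ann.particles)
        )
        ann2 = sn.SpineAnnotation(contour2, ann.psd, particles2)
        t1 = sn.zone_table(ann)
        t2 = sn.zone_table(ann2)
        for (_, z1, d1), (_, z2, d2) in zip(t1, t2):
            assert z1 == z2
            assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-9)
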