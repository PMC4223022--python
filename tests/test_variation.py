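"""COV, paired t tests, coverage/median surface, SD_local and report assembly."""

import numpy as np
import pytest
from scipy import stats

from trifuse.errors import EmptyInputError, InputError, ParameterError
from trifuse.masks import MaskSet
from trifuse.surfaces import extract_surface
from trifuse.variation import (
    DistanceCap,
    aggregate_sd_local,
    analyze_median_surface,
    cov,
    coverage_volume,
    median_surface,
    octant_labels,
    paired_t_two_tailed,
    sd_local,
    signed_normal_distance,
    variation_report,
)
from trifuse.volumes import GridSpec, GTVMask

import conftest
from conftest import make_sphere_mask


# ---------------------------------------------------------------------------
# COV
# ---------------------------------------------------------------------------

class TestCov:
    @pytest.mark.parametrize(
        "values,expected",
        [((19.91, 22.72, 20.47), 0.07), ((2.96, 2.92, 1.82), 0.25)],
    )
    def test_published_volume_rows_reproduce_at_two_decimals(self, values, expected):
        assert round(cov(values).cov, 2) == expected

    def test_identical_values_give_zero(self):
        assert cov((5.0, 5.0, 5.0)).cov == 0.0

    def test_sample_convention_discriminates_from_population(self):
        """The n-1 (sample) SD reproduces the printed per-patient COVs; the n
        (population) convention fails at least one row."""
        values = (19.91, 22.72, 20.47)
        assert round(cov(values, ddof=1).cov, 2) == 0.07
        assert round(cov(values, ddof=0).cov, 2) == 0.06  # not the printed 0.07

    def test_all_published_covs_reproduce_with_sample_sd(self):
        for patient, vals in conftest.VOLUMES_DUAL.items():
            assert round(cov(vals).cov, 2) == conftest.COV_DUAL_PRINTED[patient]
        for patient, vals in conftest.VOLUMES_TRI.items():
            assert round(cov(vals).cov, 2) == conftest.COV_TRI_PRINTED[patient]

    def test_mean_zero_is_flagged_undefined(self):
        report = cov((-1.0, 1.0))
        assert report.undefined and np.isnan(report.cov)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(InputError):
            cov((3.0,))


# ---------------------------------------------------------------------------
# Paired t test
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_identical_sequences_are_degenerate_not_significant(self):
        r = paired_t_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.degenerate and r.p is None and r.mean_diff == 0.0
        assert not r.significant

    def test_hand_computed_t_statistic(self):
        # d = (1, 2, 3): mean 2, SD 1, SE = 1/sqrt(3), t = 2*sqrt(3)
        r = paired_t_two_tailed([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-10)
        assert r.df == 2

    def test_p_value_against_t_distribution_oracle(self, rng):
        a = rng.normal(1.0, 1.0, 12)
        b = rng.normal(0.5, 1.0, 12)
        r = paired_t_two_tailed(a, b)
        p_oracle = 2.0 * stats.t.sf(abs(r.t), df=r.df)
        assert r.p == pytest.approx(p_oracle, abs=1e-8)

    def test_ci_symmetric_about_mean_difference(self, rng):
        a = rng.normal(0.0, 1.0, 9)
        b = rng.normal(0.2, 1.0, 9)
        r = paired_t_two_tailed(a, b)
        assert (r.ci_low + r.ci_high) / 2.0 == pytest.approx(r.mean_diff, abs=1e-12)
        assert r.ci_low < r.mean_diff < r.ci_high

    def test_published_intra_observer_ci_rounds_correctly(self):
        """The nine repeat-contour COV pairs give a 95% CI that rounds to
        [0.01, 0.06]."""
        r = paired_t_two_tailed(conftest.INTRA_COV_DUAL, conftest.INTRA_COV_TRI)
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (0.01, 0.06)
        assert r.p < 0.05

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            paired_t_two_tailed([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Coverage volume and median surface
# ---------------------------------------------------------------------------

def block_mask(grid, xlo, xhi):
    data = np.zeros(grid.shape, bool)
    data[xlo:xhi, 4:12, 4:12] = True
    return GTVMask(data, grid)


class TestCoverage:
    def test_identical_masks_give_that_mask(self):
        m = make_sphere_mask(6.0, n=24)
        out = coverage_volume([m, m, m])
        np.testing.assert_array_equal(out.data, m.data)

    def test_majority_semantics_two_of_three(self):
        grid = GridSpec((16, 16, 16), (1, 1, 1))
        masks = [block_mask(grid, 0, 8), block_mask(grid, 4, 12), block_mask(grid, 6, 14)]
        out = coverage_volume(masks)
        counts = np.sum([m.data for m in masks], axis=0)
        np.testing.assert_array_equal(out.data, counts >= 2)
        # voxels in exactly 2 of 3 are inside; exactly 1 of 3 outside
        assert out.data[(counts == 2)].all()
        assert not out.data[(counts == 1)].any()

    def test_tie_at_fifty_percent_kept_with_four_masks(self):
        grid = GridSpec((16, 16, 16), (1, 1, 1))
        masks = [
            block_mask(grid, 0, 8),
            block_mask(grid, 0, 8),
            block_mask(grid, 8, 14),
            block_mask(grid, 8, 14),
        ]
        out = coverage_volume(masks)
        counts = np.sum([m.data for m in masks], axis=0)
        assert out.data[counts == 2].all()  # 2/4 = 50%: included

    def test_monotone_in_threshold_union_and_intersection_limits(self, rng):
        grid = GridSpec((12, 12, 12), (1, 1, 1))
        masks = [GTVMask(rng.random(grid.shape) < 0.5, grid) for _ in range(3)]
        prev = None
        for thr in (1e-9, 0.34, 0.5, 0.67, 1.0):
            out = coverage_volume(masks, thr)
            if prev is not None:
                assert not np.any(out.data & ~prev)  # shrinks as thr grows
            prev = out.data
        union = np.logical_or.reduce([m.data for m in masks])
        inter = np.logical_and.reduce([m.data for m in masks])
        np.testing.assert_array_equal(coverage_volume(masks, 1e-9).data, union)
        np.testing.assert_array_equal(coverage_volume(masks, 1.0).data, inter)

    def test_fewer_than_two_masks_rejected(self):
        m = make_sphere_mask(6.0, n=16)
        with pytest.raises(InputError):
            coverage_volume([m])


class TestMedianSurface:
    def test_identical_masks_median_equals_individual_mesh(self):
        m = make_sphere_mask(8.0, n=24)
        med = median_surface([m, m, m])
        ind = extract_surface(m)
        np.testing.assert_allclose(med.vertices, ind.vertices)
        np.testing.assert_array_equal(med.faces, ind.faces)

    def test_concentric_spheres_median_tracks_middle_radius(self):
        masks = [make_sphere_mask(r) for r in (8.0, 10.0, 12.0)]
        med = median_surface(masks)
        radii = np.linalg.norm(med.vertices, axis=1)
        assert radii.mean() == pytest.approx(10.0, rel=0.03)

    def test_half_shifted_blocks_majority_region(self):
        grid = GridSpec((16, 16, 16), (1, 1, 1))
        masks = [block_mask(grid, 2, 10), block_mask(grid, 2, 10), block_mask(grid, 6, 14)]
        med_mask = coverage_volume(masks)
        # majority region = first two blocks (identical): voxel-count oracle
        assert med_mask.n_voxels == masks[0].n_voxels

    def test_empty_median_raises(self):
        grid = GridSpec((12, 12, 12), (1, 1, 1))
        disjoint = [
            block_mask(grid, 0, 3),
            block_mask(grid, 4, 7),
            block_mask(grid, 8, 11),
        ]
        with pytest.raises(EmptyInputError):
            median_surface(disjoint)


# ---------------------------------------------------------------------------
# Signed normal distances and SD_local
# ---------------------------------------------------------------------------

class TestSignedDistance:
    def test_self_distance_is_zero(self):
        mesh = extract_surface(make_sphere_mask(8.0, n=24))
        for i in (0, len(mesh.vertices) // 2):
            assert signed_normal_distance(mesh, i, mesh) == pytest.approx(
                0.0, abs=1e-7
            )

    def test_concentric_spheres_signed_offsets(self):
        med = extract_surface(make_sphere_mask(10.0))
        bigger = extract_surface(make_sphere_mask(12.0))
        smaller = extract_surface(make_sphere_mask(8.0))
        # +2 mm = +0.2 cm toward the larger sphere, -0.2 cm toward the smaller
        i = len(med.vertices) // 3
        assert signed_normal_distance(med, i, bigger) == pytest.approx(0.2, abs=0.06)
        assert signed_normal_distance(med, i, smaller) == pytest.approx(-0.2, abs=0.06)


class TestSdLocal:
    def test_identical_masks_give_zero_everywhere(self):
        m = make_sphere_mask(8.0, n=24)
        res = analyze_median_surface([m, m, m])
        assert np.all(res.sd_local_cm == 0.0)
        assert res.overall_mean_cm == 0.0

    def test_concentric_spheres_match_closed_form(self):
        """Observer radii 8/10/12 mm: distances (-2, 0, +2) mm per vertex, so
        SD_local should be 2 mm = 0.2 cm everywhere (within 10%)."""
        masks = [make_sphere_mask(r) for r in (8.0, 10.0, 12.0)]
        res = analyze_median_surface(masks)
        expected = float(np.std([-2.0, 0.0, 2.0], ddof=1)) / 10.0
        assert res.overall_mean_cm == pytest.approx(expected, rel=0.10)
        per_vertex_ok = np.abs(res.sd_local_cm - expected) / expected < 0.35
        assert per_vertex_ok.mean() > 0.9  # discretization outliers allowed

    def test_invariant_under_common_translation_of_all_masks(self, rng):
        masks = [make_sphere_mask(r) for r in (8.0, 10.0, 12.0)]
        res0 = analyze_median_surface(masks)
        shifted = []
        for m in masks:
            g = m.grid
            shifted.append(
                GTVMask(m.data, GridSpec(g.shape, g.spacing,
                                         tuple(o + d for o, d in zip(g.origin, (13.0, -4.0, 6.0)))))
            )
        res1 = analyze_median_surface(shifted)
        np.testing.assert_allclose(res1.sd_local_cm, res0.sd_local_cm, atol=1e-9)

    def test_needs_at_least_two_observers(self):
        mesh = extract_surface(make_sphere_mask(8.0, n=24))
        with pytest.raises(InputError):
            sd_local(mesh, [mesh])

    def test_sd_local_attached_as_vertex_attribute(self):
        masks = [make_sphere_mask(r, n=30) for r in (8.0, 9.0, 10.0)]
        res = analyze_median_surface(masks)
        attr = res.median_mesh.vertex_attributes["sd_local"]
        np.testing.assert_array_equal(attr, res.sd_local_cm)


class TestOctants:
    def test_all_positive_vertex_gets_label_one(self):
        masks = [make_sphere_mask(8.0, n=24)] * 3
        med = median_surface(masks)
        labels = octant_labels(med, masks)
        v = med.vertices
        sel = (v[:, 0] > 0.5) & (v[:, 1] > 0.5) & (v[:, 2] > 0.5)
        assert sel.any() and np.all(labels[sel] == 1)

    def test_sphere_splits_evenly_into_octants(self):
        masks = [make_sphere_mask(10.0)] * 3
        med = median_surface(masks)
        labels = octant_labels(med, masks)
        frac = np.bincount(labels, minlength=9)[1:] / len(labels)
        assert np.all(np.abs(frac - 0.125) < 0.05)

    def test_labels_partition_all_vertices(self):
        masks = [make_sphere_mask(r) for r in (8.0, 10.0, 12.0)]
        med = median_surface(masks)
        labels = octant_labels(med, masks)
        assert labels.shape == (len(med.vertices),)
        assert set(np.unique(labels)) <= set(range(1, 9))

    def test_aggregate_uniform_field_and_weighted_identity(self):
        masks = [make_sphere_mask(r) for r in (8.0, 10.0, 12.0)]
        res = analyze_median_surface(masks)
        # overall mean equals the vertex-count-weighted mean of octant means
        counts = np.bincount(res.octant_label, minlength=9)[1:]
        occupied = counts > 0
        weighted = np.nansum(res.octant_mean_cm[occupied] * counts[occupied]) / counts.sum()
        assert res.overall_mean_cm == pytest.approx(weighted, abs=1e-12)
        # a constant field aggregates to that constant in every octant
        res.sd_local_cm = np.full_like(res.sd_local_cm, 0.3)
        res = aggregate_sd_local(res)
        np.testing.assert_allclose(res.octant_mean_cm[occupied], 0.3)
        assert res.overall_mean_cm == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

class TestVariationReport:
    def test_published_tables_reproduce(self, tmp_path):
        report = variation_report(
            volumes_by_scheme={"dual": conftest.VOLUMES_DUAL, "tri": conftest.VOLUMES_TRI},
            adsc_by_scheme={"dual": conftest.ADSC_DUAL, "tri": conftest.ADSC_TRI},
        )
        vt = report.volume_table.set_index(["scheme", "patient"])
        for patient, expected in conftest.COV_DUAL_PRINTED.items():
            assert round(vt.loc[("dual", patient), "cov"], 2) == expected
        for patient, expected in conftest.COV_TRI_PRINTED.items():
            assert round(vt.loc[("tri", patient), "cov"], 2) == expected
        at = report.adsc_table.set_index(["scheme", "patient"])
        for (scheme, patient), (mean, sd) in conftest.ADSC_PRINTED.items():
            assert round(at.loc[(scheme, patient), "mean"], 2) == mean
            assert round(at.loc[(scheme, patient), "sd"], 2) == sd
        assert len(report.tests) == 2
        out = tmp_path / "report.csv"
        report.to_csv(out)
        assert "# volumes" in out.read_text()

    def test_single_observer_flagged_not_computable(self):
        report = variation_report(
            volumes_by_scheme={"dual": {"p1": [10.0]}, "tri": {"p1": [9.0]}},
        )
        row = report.volume_table.iloc[0]
        assert not row["computable"] and np.isnan(row["cov"])

    def test_mismatched_patients_rejected(self):
        with pytest.raises(InputError):
            variation_report(
                volumes_by_scheme={
                    "dual": {"p1": [1.0, 2.0]},
                    "tri": {"p2": [1.0, 2.0]},
                }
            )

    def test_sdlocal_section_from_masks(self):
        masks = MaskSet([make_sphere_mask(r, n=30) for r in (8.0, 9.0, 10.0)])
        report = variation_report(
            volumes_by_scheme={"s": {"p1": [1.0, 2.0, 3.0]}},
            masks_by_scheme={"s": {"p1": masks}},
        )
        assert report.sdlocal_table is not None
        assert "overall" in report.sdlocal_table.columns
        assert report.sdlocal_table["overall"].iloc[0] > 0


def test_distance_cap_must_be_positive():
    with pytest.raises(ParameterError):
        DistanceCap(0.0)
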