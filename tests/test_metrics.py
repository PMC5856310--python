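"""Plan-level metrics: pooling, indices, normalization, the full panel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srsqa.core import DoseGrid, Structure
from srsqa.dvh import compute_cumulative_dvh, dose_at_volume, volume_at_dose
from srsqa.metrics import (
    compute_plan_metrics,
    conformity_volumes,
    gradient_index,
    homogeneity_index,
    normalize_plan,
    paddick_ci,
    pooled_target_mask,
    relative_dose_grid,
    total_target,
)
from srsqa.synthetic import build_structures, render_dose

from conftest import quiet_profile


def make_target(mask, rx=18.0, name="t"):
    return Structure(name, "target", mask, prescription_dose=rx)


class TestTotalTarget:
    def test_disjoint_union(self):
        m1 = np.zeros((5, 5, 5), dtype=bool)
        m2 = np.zeros((5, 5, 5), dtype=bool)
        m1.flat[:10] = True
        m2.flat[20:30] = True
        tt = total_target([make_target(m1), make_target(m2)])
        assert tt.voxel_count == 20
        assert tt.role == "target"
        assert tt.prescription_dose == 18.0

    def test_idempotent_union(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m.flat[:10] = True
        tt = total_target([make_target(m), make_target(m.copy())])
        assert tt.voxel_count == 10

    def test_overlapping_union_inclusion_exclusion(self):
        m1 = np.zeros((5, 5, 5), dtype=bool)
        m2 = np.zeros((5, 5, 5), dtype=bool)
        m1.flat[0:10] = True
        m2.flat[6:16] = True  # shares 4 voxels with m1
        tt = total_target([make_target(m1), make_target(m2)])
        assert tt.voxel_count == 16

    def test_mixed_prescriptions_rejected(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m.flat[:5] = True
        with pytest.raises(ValueError, match="mixed"):
            total_target([make_target(m, rx=18.0), make_target(m, rx=20.0)])

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError, match="no target"):
            total_target([Structure("o", "oar", np.ones((2, 2, 2), dtype=bool))])


class TestHomogeneityIndex:
    @pytest.mark.parametrize(
        "d2,d98,rx,expected",
        [(15.0, 15.0, 15.0, 0.0), (16.0, 14.0, 15.0, 2.0 / 15.0), (18.0, 15.0, 15.0, 0.2)],
    )
    def test_defining_formula(self, d2, d98, rx, expected):
        assert homogeneity_index(d2, d98, rx) == pytest.approx(expected)

    def test_inverted_ordering_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            homogeneity_index(10.0, 12.0, 15.0)


class TestPaddickCI:
    def test_perfect_conformity(self):
        assert paddick_ci(10.0, 10.0, 10.0) == 1.0

    def test_arithmetic(self):
        assert paddick_ci(10.0, 20.0, 10.0) == pytest.approx(0.5)

    def test_intersection_exceeding_volume_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            paddick_ci(10.0, 20.0, 11.0)

    def test_concentric_spheres_match_voxel_counting(self):
        # target sphere r=10 mm inside a prescription isodose sphere r=12 mm
        # on a 1 mm grid; the index from the formula must equal the index
        # recomputed from brute-force voxel counts
        n = 31
        c = (n - 1) / 2
        idx = np.indices((n, n, n))
        r = np.sqrt(((idx - c) ** 2).sum(axis=0))
        target = r <= 10.0
        piv = r <= 12.0
        grid = DoseGrid(np.where(piv, 20.0, 5.0), (1, 1, 1))
        rel = DoseGrid(grid.values / 20.0 * 100.0, (1, 1, 1))
        tv, piv_cc, inter, _ = conformity_volumes(rel, target)
        vox = 1e-3
        assert tv == pytest.approx(target.sum() * vox)
        assert piv_cc == pytest.approx(piv.sum() * vox)
        assert inter == pytest.approx((target & piv).sum() * vox)
        expected = (target & piv).sum() ** 2 / (target.sum() * piv.sum())
        assert paddick_ci(tv, piv_cc, inter) == pytest.approx(expected)

    @given(
        tv=st.floats(0.1, 100.0),
        piv=st.floats(0.1, 100.0),
        frac=st.floats(0.01, 1.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_geometric_mean_bound(self, tv, piv, frac):
        inter = frac * min(tv, piv)
        pci = paddick_ci(tv, piv, inter)
        assert 0.0 <= pci <= 1.0 + 1e-12
        assert pci <= min(inter / tv, inter / piv) + 1e-12


class TestGradientIndex:
    def test_infinitely_sharp_falloff(self):
        assert gradient_index(10.0, 10.0) == 1.0

    def test_arithmetic(self):
        assert gradient_index(50.0, 10.0) == pytest.approx(5.0)

    def test_nesting_violation_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            gradient_index(5.0, 10.0)

    def test_decreases_with_steeper_falloff(self, fixed_patient, fixed_patient_prebuilt):
        gis = []
        for lam in (2.0, 4.0, 8.0):
            grid, structures = render_dose(
                fixed_patient, quiet_profile(falloff_length=lam),
                prebuilt=fixed_patient_prebuilt,
            )
            rel = relative_dose_grid(grid, structures)
            union = pooled_target_mask(structures)
            _, piv, _, v_half = conformity_volumes(rel, union)
            gis.append(gradient_index(v_half, piv))
        assert gis[0] < gis[1] < gis[2]


class TestNormalizePlan:
    def test_fixed_point(self, rendered_plan):
        grid, structures = rendered_plan
        rel = relative_dose_grid(grid, structures)
        pooled = Structure(
            "tt", "target", pooled_target_mask(structures), prescription_dose=100.0
        )
        result = normalize_plan(rel, pooled)
        assert result.scale == pytest.approx(1.0, abs=1e-3)

    def test_uniform_plan_edge_case(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        values = np.where(mask, 30.0, 0.0)  # uniform at 2x prescription
        grid = DoseGrid(values, (2, 2, 2))
        target = make_target(mask, rx=15.0)
        result = normalize_plan(grid, target)
        assert result.scale == pytest.approx(0.5, abs=0.01)
        assert result.achieved_coverage_pct >= 95.0
        assert not result.converged  # plateau: exact 95% unattainable

    def test_graded_falloff_reaches_target_coverage(self, fixed_patient,
                                                    fixed_patient_prebuilt):
        grid, structures = render_dose(
            fixed_patient, quiet_profile(noise_sd=0.03),
            prebuilt=fixed_patient_prebuilt, normalize=False,
        )
        target = total_target([s for s in structures if s.role == "target"])
        result = normalize_plan(grid, target)
        dvh = compute_cumulative_dvh(result.grid, target)
        assert volume_at_dose(dvh, 18.0) == pytest.approx(95.0, abs=0.1)

    def test_idempotent(self, fixed_patient, fixed_patient_prebuilt):
        grid, structures = render_dose(
            fixed_patient, quiet_profile(noise_sd=0.03),
            prebuilt=fixed_patient_prebuilt, normalize=False,
        )
        target = total_target([s for s in structures if s.role == "target"])
        once = normalize_plan(grid, target)
        twice = normalize_plan(once.grid, target)
        assert abs(twice.scale - 1.0) < 1e-4

    def test_zero_dose_rejected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        grid = DoseGrid(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="zero dose"):
            normalize_plan(grid, make_target(mask))


class TestComputePlanMetrics:
    def _ideal_plan(self):
        shape = (10, 10, 10)
        brain = np.zeros(shape, dtype=bool)
        brain[1:9, 1:9, 1:9] = True
        target = np.zeros(shape, dtype=bool)
        target[4:6, 4:6, 4:6] = True
        values = np.where(target, 18.0, 0.0)
        grid = DoseGrid(values, (2, 2, 2))
        structures = [
            Structure("brain", "oar", brain),
            make_target(target, rx=18.0),
        ]
        return grid, structures

    def test_ideal_plan(self):
        grid, structures = self._ideal_plan()
        rec = compute_plan_metrics(grid, structures)
        # D2/D98 interpolate across one bin at the uniform-dose cliff, so
        # HI vanishes only to within bin_width / prescription
        assert rec.hi == pytest.approx(0.0, abs=1e-4)
        assert rec.pci == pytest.approx(1.0)
        assert rec.gi == pytest.approx(1.0)
        assert rec.brain_v4_cc == 0.0
        assert rec.v100_pct == pytest.approx(100.0)

    def test_missing_brain_rejected(self):
        grid, structures = self._ideal_plan()
        with pytest.raises(ValueError, match="brain"):
            compute_plan_metrics(grid, [structures[1]])

    def test_no_dose_above_4gy_in_healthy_brain(self):
        grid, structures = self._ideal_plan()
        rec = compute_plan_metrics(grid, structures)
        assert rec.brain_v4_cc == 0.0

    def test_matches_independent_recomputation(self, rendered_plan):
        """Every target/brain field agrees with direct voxel arithmetic."""
        grid, structures = rendered_plan
        rec = compute_plan_metrics(grid, structures)
        rel = relative_dose_grid(grid, structures)
        union = pooled_target_mask(structures)
        n = union.sum()
        vox = grid.voxel_volume_cc
        rel_target = np.sort(rel.values[union])

        # D98: minimum dose of the hottest 98% = the 2nd-percentile voxel
        k = int(np.ceil(0.98 * n))
        d98_oracle = rel_target[n - k]
        assert rec.d98_pct == pytest.approx(d98_oracle, abs=0.05)
        # coverage and conformity by counting
        assert rec.v100_pct == pytest.approx(
            100.0 * (rel_target >= 100.0).sum() / n, abs=100.0 / n
        )
        piv_mask = rel.values >= 100.0
        assert rec.pci == pytest.approx(
            (piv_mask & union).sum() ** 2 / (n * piv_mask.sum()), rel=1e-9
        )
        assert rec.gi == pytest.approx(
            (rel.values >= 50.0).sum() / piv_mask.sum(), rel=1e-9
        )
        # healthy brain V4 by counting
        healthy = next(s for s in structures if s.role == "healthy_brain")
        v4_oracle = (grid.values[healthy.mask] >= 4.0).sum() * vox
        assert rec.brain_v4_cc == pytest.approx(v4_oracle, abs=2 * vox)
        assert rec.brain_mean_gy == pytest.approx(grid.values[healthy.mask].mean())

    def test_coverage_nesting_invariant(self, rendered_plan):
        grid, structures = rendered_plan
        rec = compute_plan_metrics(grid, structures)
        assert rec.v110_pct <= rec.v100_pct <= rec.v90_pct

    def test_joint_rescaling_invariance(self):
        """PCI, GI and HI are invariant under a joint dose/prescription rescale."""
        grid, structures = self._ideal_plan()
        noisy = DoseGrid(
            grid.values + np.random.default_rng(3).uniform(0, 2.0, grid.shape),
            grid.spacing,
        )
        rec1 = compute_plan_metrics(noisy, structures)
        scaled_structs = [
            Structure(s.name, s.role, s.mask,
                      None if s.prescription_dose is None else s.prescription_dose * 2)
            for s in structures
        ]
        rec2 = compute_plan_metrics(noisy.scaled(2.0), scaled_structs)
        assert rec2.pci == pytest.approx(rec1.pci, rel=1e-6)
        assert rec2.gi == pytest.approx(rec1.gi, rel=1e-6)
        assert rec2.hi == pytest.approx(rec1.hi, abs=1e-3)


class TestRelativeDoseGrid:
    def test_single_prescription_is_global_division(self):
        values = np.full((3, 3, 3), 9.0)
        grid = DoseGrid(values, (1, 1, 1))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        rel = relative_dose_grid(grid, [make_target(mask, rx=18.0)])
        np.testing.assert_allclose(rel.values, 50.0)

    def test_nearest_lesion_assignment(self):
        # two point lesions with different prescriptions: each half of the
        # grid normalizes by its nearer lesion's prescription
        values = np.full((1, 1, 10), 10.0)
        grid = DoseGrid(values, (1, 1, 1))
        m1 = np.zeros((1, 1, 10), dtype=bool)
        m2 = np.zeros((1, 1, 10), dtype=bool)
        m1[0, 0, 1] = True
        m2[0, 0, 8] = True
        rel = relative_dose_grid(
            grid, [make_target(m1, rx=10.0, name="a"), make_target(m2, rx=20.0, name="b")]
        )
        assert rel.values[0, 0, 0] == pytest.approx(100.0)
        assert rel.values[0, 0, 9] == pytest.approx(50.0)
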