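"""Slab liver-lung interface simulation: phantom, blur, profiles, intervals."""

import numpy as np
import pytest

from y90dose import (
    DoseMap,
    Profile1D,
    SlabSpec,
    VoxelGrid,
    agreement_intervals,
    blur_activity,
    combine_ls,
    extract_profile,
    make_slab,
    percent_difference,
)
from y90dose.interface import TRANSPORT_AWARE, _noncompliance_depth


class TestMakeSlab:
    def test_liver_compartment_activity_pattern(self):
        spec = SlabSpec()
        act, rho = make_slab(spec, "liver")
        z = spec.z_world(range(act.dims[2]))
        liver_side = act.values[:, :, z <= 0]
        lung_side = act.values[:, :, z > 0]
        assert np.all(lung_side == 0)
        assert len(np.unique(liver_side)) == 1 and liver_side.min() > 0

    def test_density_straddles_interface(self):
        spec = SlabSpec()
        _, rho = make_slab(spec, "lung")
        nx, ny, nz = rho.dims
        z = spec.z_world(range(nz))
        k_minus = int(np.argmin(np.abs(z + 2.4)))
        k_plus = int(np.argmin(np.abs(z - 2.4)))
        assert rho.values[nx // 2, ny // 2, k_minus] == 1.04
        assert rho.values[nx // 2, ny // 2, k_plus] == 0.26

    def test_activity_conserved_exactly(self):
        spec = SlabSpec(total_activity_bq=3.7e9)
        for compartment in ("liver", "lung"):
            act, _ = make_slab(spec, compartment)
            assert act.total() == pytest.approx(3.7e9, rel=1e-12)

    def test_margin_must_cover_lung_range(self):
        with pytest.raises(ValueError, match="margin"):
            SlabSpec(margin_voxels=5)


class TestBlur:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        a = VoxelGrid(rng.random((8, 8, 8)), (4.8,) * 3)
        assert np.array_equal(blur_activity(a, 0.0).values, a.values)

    def test_conserves_total_activity(self):
        a = np.zeros((31, 31, 31))
        a[10:21, 10:21, 10:21] = 1.0
        g = VoxelGrid(a, (4.8,) * 3)
        blurred = blur_activity(g, 20.0)
        assert blurred.total() == pytest.approx(g.total(), rel=1e-6)

    def test_impulse_response_width_matches_fwhm(self):
        n = 41
        a = np.zeros((n, n, n))
        a[n // 2, n // 2, n // 2] = 1.0
        g = VoxelGrid(a, (1.0,) * 3)  # 1 mm voxels resolve the width
        b = blur_activity(g, 20.0).values[n // 2, n // 2, :]
        half = b.max() / 2.0
        # sub-voxel half-maximum crossings by linear interpolation
        idx = np.arange(n, dtype=float)
        above = np.flatnonzero(b >= half)
        i0, i1 = above[0], above[-1]
        left = np.interp(half, [b[i0 - 1], b[i0]], [idx[i0 - 1], idx[i0]])
        right = np.interp(half, [b[i1 + 1], b[i1]], [idx[i1 + 1], idx[i1]])
        assert right - left == pytest.approx(20.0, abs=0.5)

    def test_rejects_negative_fwhm(self):
        g = VoxelGrid(np.ones((4, 4, 4)), (4.8,) * 3)
        with pytest.raises(ValueError):
            blur_activity(g, -1.0)


class TestCombineLS:
    def _pair(self):
        g = VoxelGrid(np.ones((4, 4, 4)), (4.8,) * 3)
        liver = DoseMap(g.with_values(np.full((4, 4, 4), 2.0)), "RT")
        lung = DoseMap(g.with_values(np.full((4, 4, 4), 10.0)), "RT")
        return liver, lung

    def test_boundaries(self):
        liver, lung = self._pair()
        assert np.all(combine_ls(liver, lung, 0.0).values == liver.values)
        assert np.all(combine_ls(liver, lung, 1.0).values == lung.values)

    def test_weights_are_activity_fractions(self):
        liver, lung = self._pair()
        combined = combine_ls(liver, lung, 0.2)
        assert np.allclose(combined.values, 0.8 * 2.0 + 0.2 * 10.0)

    def test_rejects_ls_outside_unit_interval(self):
        liver, lung = self._pair()
        with pytest.raises(ValueError):
            combine_ls(liver, lung, 1.2)


class TestExtractProfile:
    def test_uniform_dose_gives_constant_profile(self):
        g = VoxelGrid(np.full((9, 9, 5), 3.0), (4.8,) * 3)
        prof = extract_profile(g)
        assert np.allclose(prof.values, 3.0)
        assert len(prof) == 5

    def test_default_study_profile_has_61_positions(self, interface_result):
        prof = next(iter(interface_result.dose_profiles.values()))
        assert len(prof) == 61

    def test_mirrored_map_gives_mirrored_profile(self):
        rng = np.random.default_rng(1)
        v = rng.random((9, 9, 7))
        g = VoxelGrid(v, (1.0,) * 3)
        mirrored = VoxelGrid(v[:, :, ::-1], (1.0,) * 3)
        assert np.allclose(
            extract_profile(g).values, extract_profile(mirrored).values[::-1]
        )

    def test_rejects_narrow_grid(self):
        g = VoxelGrid(np.ones((5, 9, 9)), (4.8,) * 3)
        with pytest.raises(ValueError, match="7 voxels"):
            extract_profile(g)


class TestPercentDifference:
    def _truth(self):
        z = np.arange(-30.0, 31.0, 4.8)
        return Profile1D(z, np.full(z.size, 8.0))

    def test_identity_gives_zeros(self):
        t = self._truth()
        assert np.allclose(percent_difference(t, t).values, 0.0)

    def test_deep_lung_equilibrium_ratio(self):
        t = self._truth()
        p = Profile1D(t.positions, 0.25 * t.values)
        assert np.allclose(percent_difference(p, t).values, -75.0)

    def test_positive_scaling(self):
        t = self._truth()
        p = Profile1D(t.positions, 1.1 * t.values)
        assert np.allclose(percent_difference(p, t).values, 10.0)

    def test_rejects_zero_truth(self):
        t = self._truth()
        bad = Profile1D(t.positions, np.where(t.positions > 0, 0.0, 1.0))
        with pytest.raises(ValueError, match="positive"):
            percent_difference(t, bad)


class TestAgreementIntervals:
    def test_truth_vs_itself_is_full_line(self):
        z = np.arange(-100.0, 101.0, 4.8)
        iv = agreement_intervals(Profile1D(z, np.zeros(z.size)))
        assert iv.intervals == ((-np.inf, np.inf),)

    def test_constructed_lung_violation(self):
        """|pd| > 10 only inside (0, 26) -> (-inf, 0) U (26, inf)."""
        z = np.arange(-50.0, 51.0, 1.0)
        v = np.where((z > 0) & (z < 26), 50.0, 0.0)
        iv = agreement_intervals(Profile1D(z, v))
        assert len(iv.intervals) == 2
        (lo1, hi1), (lo2, hi2) = iv.intervals
        assert lo1 == -np.inf and hi1 == pytest.approx(0.0, abs=1.0)
        assert lo2 == pytest.approx(26.0, abs=1.0) and hi2 == np.inf

    def test_looser_threshold_contains_tighter(self, interface_result):
        pd = interface_result.percent_diffs[("SKD", 20.0, 0.2)]
        iv5 = agreement_intervals(pd, threshold=5.0)
        iv10 = agreement_intervals(pd, threshold=10.0)
        probe = np.arange(-140.0, 140.0, 1.0)
        ok5 = np.array([iv5.covers(z) for z in probe])
        ok10 = np.array([iv10.covers(z) for z in probe])
        assert np.all(ok10 | ~ok5)  # compliant at 5% implies compliant at 10%

    def test_rejects_one_sided_profile(self):
        z = np.arange(1.0, 30.0, 1.0)
        with pytest.raises(ValueError):
            agreement_intervals(Profile1D(z, np.zeros(z.size)))


class TestStudyInvariants:
    def test_ls_superposition_is_linear_in_profiles(self, interface_result):
        """Profiles at LS 0.10 are the average of dose components' weights.

        Superposition linearity: P(ls) = (1-ls) P_liver + ls P_lung implies
        P(0.10) lies on the line between P(0.01) and P(0.20).
        """
        res = interface_result
        for engine in res.engines:
            p1 = res.dose_profiles[(engine, 20.0, 0.01)].values
            p2 = res.dose_profiles[(engine, 20.0, 0.10)].values
            p3 = res.dose_profiles[(engine, 20.0, 0.20)].values
            w = (0.10 - 0.01) / (0.20 - 0.01)
            assert np.allclose(p2, (1 - w) * p1 + w * p3, rtol=1e-9)

    def test_truth_dose_monotone_in_ls(self, interface_result):
        """Deep-lung truth dose rises with LS; deep-liver dose falls."""
        res = interface_result
        deep_lung = {}
        deep_liver = {}
        for ls in (0.01, 0.10, 0.20):
            prof = res.dose_profiles[("RT", 0.0, ls)]
            deep_lung[ls] = prof.values[prof.positions > 50].mean()
            deep_liver[ls] = prof.values[prof.positions < -50].mean()
        assert deep_lung[0.01] < deep_lung[0.10] < deep_lung[0.20]
        assert deep_liver[0.01] > deep_liver[0.10] > deep_liver[0.20]

    def test_zero_fwhm_reference_is_identically_zero(self, interface_result):
        for ls in (0.01, 0.10, 0.20):
            pd = interface_result.percent_diffs[("RT", 0.0, ls)]
            assert np.allclose(pd.values, 0.0)

    def test_liver_spillout_deficit_grows_with_fwhm(self, interface_result):
        """The liver-side non-compliance depth is monotone in the blur."""
        res = interface_result
        depths = [
            res.noncompliance_depth("liver", fwhm, engines=("SKD",))
            for fwhm in (0.0, 10.0, 20.0)
        ]
        assert depths[0] <= depths[1] <= depths[2]

    def test_deep_asymptotes_transport_aware_engines_agree(self, interface_result):
        """Beyond the lung range + blur, RT, SKD, LD agree within 2%."""
        res = interface_result
        for engine in TRANSPORT_AWARE:
            pd = res.percent_diffs[(engine, 20.0, 0.20)]
            deep = pd.values[pd.positions > 70]
            assert np.all(np.abs(deep) < 2.0)

    def test_noncompliance_depth_helper(self):
        z = np.arange(-50.0, 51.0, 1.0)
        v = np.where((z >= -12) & (z <= 0), 20.0, 0.0)
        pd = Profile1D(z, v)
        assert _noncompliance_depth(pd, "liver") == pytest.approx(12.0)
        assert _noncompliance_depth(pd, "lung") == 0.0
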