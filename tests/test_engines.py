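"""The activity chain and the four dose engines."""

import numpy as np
import pytest

from y90dose import (
    Y90,
    VoxelGrid,
    activity_to_disintegrations,
    counts_to_activity,
    dose_ld,
    dose_rt,
    dose_sk,
    dose_skd,
    global_energy,
)


def grid_of(values, spacing=4.8):
    return VoxelGrid(np.asarray(values, dtype=float), (spacing,) * 3)


class TestSelfCalibration:
    def test_total_activity_equals_administered(self):
        rng = np.random.default_rng(1)
        counts = grid_of(rng.random((8, 8, 8)))
        a = counts_to_activity(counts, administered_bq=2.81e9)
        assert a.total() == pytest.approx(2.81e9, rel=1e-12)

    def test_invariant_under_counts_scale(self):
        rng = np.random.default_rng(2)
        counts = rng.random((5, 5, 5))
        a1 = counts_to_activity(grid_of(counts), 1e9)
        a2 = counts_to_activity(grid_of(counts * 2.0), 1e9)
        assert np.allclose(a1.values, a2.values)

    def test_single_voxel_gets_everything(self):
        counts = np.zeros((4, 4, 4))
        counts[1, 2, 3] = 7.0
        a = counts_to_activity(grid_of(counts), 5e8)
        assert a.values[1, 2, 3] == pytest.approx(5e8)
        assert a.total() == pytest.approx(5e8)

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            counts_to_activity(grid_of(np.zeros((3, 3, 3))), 1e9)


class TestDisintegrations:
    def test_one_becquerel(self):
        n = activity_to_disintegrations(grid_of(np.ones((1, 1, 1))))
        assert n.values[0, 0, 0] == pytest.approx(3.3292e5, rel=1e-4)

    def test_linear_scaling_to_gbq(self):
        n = activity_to_disintegrations(grid_of(np.full((1, 1, 1), 1e9)))
        assert n.values[0, 0, 0] == pytest.approx(3.3292e14, rel=1e-4)

    def test_zero_maps_to_zero(self):
        n = activity_to_disintegrations(grid_of(np.zeros((2, 2, 2))))
        assert np.all(n.values == 0)

    def test_rejects_negative_activity(self):
        with pytest.raises(ValueError):
            activity_to_disintegrations(grid_of(np.full((1, 1, 1), -1.0)))


class TestLocalDeposition:
    def test_reference_value(self):
        n = grid_of(np.full((1, 1, 1), 1e6))
        rho = grid_of(np.full((1, 1, 1), 1.04))
        assert dose_ld(n, rho).values[0, 0, 0] == pytest.approx(1.305e-3, rel=1e-3)

    def test_inverse_density_linearity(self):
        n = grid_of(np.full((2, 2, 2), 1e6))
        d_soft = dose_ld(n, grid_of(np.full((2, 2, 2), 1.04)))
        d_lung = dose_ld(n, grid_of(np.full((2, 2, 2), 0.26)))
        assert np.allclose(d_lung.values, 4.0 * d_soft.values)

    def test_zero_everywhere(self):
        n = grid_of(np.zeros((3, 3, 3)))
        assert np.all(dose_ld(n, grid_of(np.ones((3, 3, 3)))).values == 0)

    def test_rejects_zero_density_at_active_voxel(self):
        n = grid_of(np.ones((2, 2, 2)))
        rho = np.full((2, 2, 2), 1.04)
        rho[0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="density"):
            dose_ld(n, grid_of(rho))

    def test_energy_identity(self):
        rng = np.random.default_rng(3)
        n = grid_of(rng.random((6, 6, 6)) * 1e6)
        rho = grid_of(rng.uniform(0.3, 1.5, (6, 6, 6)))
        d = dose_ld(n, rho)
        assert global_energy(d, rho) == pytest.approx(
            n.values.sum() * Y90.e_avg_mev, rel=1e-12
        )


class TestKernelConvolution:
    def test_single_source_energy_is_e_avg(self, kern48):
        n = np.zeros((15, 15, 15))
        n[7, 7, 7] = 1e6
        d = dose_sk(grid_of(n), kern48)
        rho = grid_of(np.full((15, 15, 15), Y90.rho_ref))
        assert global_energy(d, rho) == pytest.approx(
            1e6 * Y90.e_avg_mev, rel=1e-6
        )

    def test_uniform_lung_is_quarter_of_ld(self, kern48):
        n = grid_of(np.full((15, 15, 15), 1e6))
        rho = grid_of(np.full((15, 15, 15), 0.26))
        c = 7
        sk = dose_sk(n, kern48).values[c, c, c]
        ld = dose_ld(n, rho).values[c, c, c]
        assert sk == pytest.approx(0.25 * ld, rel=0.005)

    def test_rejects_voxel_size_mismatch(self, kern48):
        with pytest.raises(ValueError, match="mismatch"):
            dose_sk(grid_of(np.ones((5, 5, 5)), spacing=2.4), kern48)

    def test_rejects_anisotropic_grid(self, kern48):
        g = VoxelGrid(np.ones((5, 5, 5)), (4.8, 4.8, 2.4))
        with pytest.raises(ValueError, match="isotropic"):
            dose_sk(g, kern48)


class TestDensityCorrection:
    def test_uniform_lung_equals_ld_exactly(self, kern48):
        n = grid_of(np.full((15, 15, 15), 1e6))
        rho = grid_of(np.full((15, 15, 15), 0.26))
        c = 7
        skd = dose_skd(n, kern48, rho).values[c, c, c]
        ld = dose_ld(n, rho).values[c, c, c]
        assert skd == pytest.approx(ld, rel=0.005)

    def test_reference_density_reduces_to_sk_bit_exactly(self, kern48):
        rng = np.random.default_rng(4)
        n = grid_of(rng.random((9, 9, 9)) * 1e5)
        rho = grid_of(np.full((9, 9, 9), 1.04))
        assert np.array_equal(
            dose_skd(n, kern48, rho).values, dose_sk(n, kern48).values
        )

    def test_voxelwise_ratio_is_density_correction(self, kern48):
        rng = np.random.default_rng(5)
        n = grid_of(rng.random((9, 9, 9)) * 1e5)
        rho = grid_of(rng.uniform(0.2, 2.0, (9, 9, 9)))
        sk = dose_sk(n, kern48).values
        skd = dose_skd(n, kern48, rho).values
        sel = sk > 0
        assert np.allclose(skd[sel] / sk[sel], 1.04 / rho.values[sel])

    def test_rejects_zero_density(self, kern48):
        n = grid_of(np.ones((3, 3, 3)))
        rho = np.ones((3, 3, 3))
        rho[1, 1, 1] = 0.0
        with pytest.raises(ValueError):
            dose_skd(n, kern48, grid_of(rho))


class TestReferenceTransport:
    @pytest.mark.parametrize("rho_u", [1.04, 0.26])
    def test_uniform_medium_equilibrium(self, dpk, rho_u):
        """Interior RT dose equals LD in uniform media of any density."""
        size = 15 if rho_u == 1.04 else 25
        n = grid_of(np.full((size,) * 3, 1e6))
        rho = grid_of(np.full((size,) * 3, rho_u))
        c = size // 2
        mask = np.zeros((size,) * 3, dtype=bool)
        mask[c, c, c] = True
        rt = dose_rt(n, rho, dpk, target_mask=mask).values[c, c, c]
        ld = dose_ld(n, rho).values[c, c, c]
        assert rt == pytest.approx(ld, rel=0.01)

    def test_reaches_beyond_geometric_soft_tissue_range_in_lung(self, dpk):
        """Dose reaches geometrically beyond 11 mm when the path is mostly lung.

        The source voxel center sits 2.4 mm below the interface; the target
        31.2 mm into the lung.  Geometric distance 33.6 mm far exceeds the
        11 mm soft-tissue range, but the radiological path 2.4 + 31.2 * 0.25
        = 10.2 mm stays inside the kernel support, so the dose is positive
        (the lung range is 44 mm).
        """
        nz = 24
        rho = np.full((9, 9, nz), 1.04)
        rho[:, :, 8:] = 0.26  # interface between k=7 and k=8
        n = np.zeros((9, 9, nz))
        n[4, 4, 7] = 1e6  # source voxel center 2.4 mm below the interface
        mask = np.zeros((9, 9, nz), dtype=bool)
        mask[4, 4, 14] = True  # ~30 mm into the lung on the source axis
        d = dose_rt(grid_of(n), grid_of(rho), dpk, target_mask=mask)
        assert d.values[4, 4, 14] > 0.0

    def test_linearity(self, dpk):
        rng = np.random.default_rng(6)
        n1 = rng.random((9, 9, 9)) * 1e5
        n2 = rng.random((9, 9, 9)) * 1e5
        rho = grid_of(rng.uniform(0.2, 1.5, (9, 9, 9)))
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        d = {}
        for name, n in (("a", n1), ("b", n2), ("ab", 2 * n1 + 3 * n2)):
            d[name] = dose_rt(grid_of(n), rho, dpk, target_mask=mask).values[4, 4, 4]
        assert d["ab"] == pytest.approx(2 * d["a"] + 3 * d["b"], rel=1e-9)

    def test_rejects_nonpositive_density(self, dpk):
        n = grid_of(np.ones((3, 3, 3)))
        rho = np.ones((3, 3, 3))
        rho[0, 0, 0] = 0.0
        with pytest.raises(ValueError):
            dose_rt(n, grid_of(rho), dpk)


class TestEngineLinearity:
    def test_ld_sk_skd_exact(self, kern48):
        rng = np.random.default_rng(7)
        n1 = rng.random((9, 9, 9)) * 1e5
        n2 = rng.random((9, 9, 9)) * 1e5
        rho = grid_of(rng.uniform(0.2, 1.5, (9, 9, 9)))
        for engine in (
            lambda n: dose_ld(n, rho),
            lambda n: dose_sk(n, kern48),
            lambda n: dose_skd(n, kern48, rho),
        ):
            da = engine(grid_of(n1)).values
            db = engine(grid_of(n2)).values
            dab = engine(grid_of(2 * n1 + 3 * n2)).values
            assert np.allclose(dab, 2 * da + 3 * db, rtol=1e-9, atol=1e-12)


class TestGlobalEnergyConservation:
    """Every engine deposits sum(N) * E_avg for fully contained sources."""

    def _compact_source(self, size=21, margin=7):
        rng = np.random.default_rng(8)
        n = np.zeros((size,) * 3)
        core = slice(margin, size - margin)
        n[core, core, core] = rng.random((size - 2 * margin,) * 3) * 1e6
        return grid_of(n)

    def test_ld_exact(self):
        n = self._compact_source()
        rho = grid_of(np.full(n.dims, 1.04))
        assert global_energy(dose_ld(n, rho), rho) == pytest.approx(
            n.values.sum() * Y90.e_avg_mev, rel=1e-12
        )

    def test_sk_and_skd_within_half_percent(self, kern48):
        n = self._compact_source()
        rho = grid_of(np.full(n.dims, 1.04))
        expected = n.values.sum() * Y90.e_avg_mev
        assert global_energy(dose_sk(n, kern48), rho) == pytest.approx(
            expected, rel=0.005
        )
        assert global_energy(dose_skd(n, kern48, rho), rho) == pytest.approx(
            expected, rel=0.005
        )

    def test_rt_within_half_percent(self, dpk):
        n = self._compact_source(size=15, margin=4)
        rho = grid_of(np.full(n.dims, 1.04))
        d = dose_rt(n, rho, dpk)
        assert global_energy(d, rho) == pytest.approx(
            n.values.sum() * Y90.e_avg_mev, rel=0.005
        )

    def test_zero_dose_zero_energy(self):
        g = grid_of(np.zeros((4, 4, 4)))
        rho = grid_of(np.ones((4, 4, 4)))
        assert global_energy(g, rho) == 0.0
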