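"""DVH, HI, COIN, intersection, summation, uncertainty: oracles and identities."""

import numpy as np
import pytest

from imrtqa.dose_metrics import (
    DoseGrid,
    LatticeMismatchError,
    StructureMask,
    beam_intersects_chamber,
    combined_uncertainty,
    conformity_index,
    cumulative_dvh,
    dose_at_volume,
    expand_mask,
    homogeneity_index,
    intersection_fraction,
    percent_rms_difference,
    read_dose_raster,
    sum_beam_doses,
    write_dose_raster,
)

from conftest import full_mask, uniform_grid


def brute_dx(doses: np.ndarray, pct: float) -> float:
    """Descending-sort rank oracle for D_x%."""
    s = np.sort(doses)[::-1]
    k = int(np.ceil(s.size * pct / 100.0)) - 1
    return float(s[k])


class TestDvh:
    def test_uniform_dose_step_function(self):
        grid = uniform_grid(2.0)
        dvh = cumulative_dvh(grid, full_mask(grid))
        assert dvh.dose_edges.tolist() == [2.0]
        assert dvh.cum_volume_fraction.tolist() == [1.0]
        assert dose_at_volume(dvh, 50.0) == 2.0

    def test_four_level_fractions(self):
        grid = uniform_grid(0.0, dims=(4, 1, 1))
        grid.values[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        dvh = cumulative_dvh(grid, full_mask(grid))
        assert dvh.dose_edges.tolist() == [1.0, 2.0, 3.0, 4.0]
        assert dvh.cum_volume_fraction.tolist() == [1.0, 0.75, 0.5, 0.25]

    def test_monotone_and_starts_at_one(self, rng):
        grid = uniform_grid(0.0, dims=(6, 6, 6))
        grid.values[:] = rng.random(grid.dims)
        dvh = cumulative_dvh(grid, full_mask(grid))
        assert dvh.cum_volume_fraction[0] == 1.0
        assert np.all(np.diff(dvh.cum_volume_fraction) <= 0)

    def test_scale_equivariance(self, rng):
        grid = uniform_grid(0.0, dims=(5, 5, 5))
        grid.values[:] = rng.random(grid.dims)
        scaled = DoseGrid(grid.origin, grid.spacing, grid.values * 3.0)
        d1 = cumulative_dvh(grid, full_mask(grid))
        d2 = cumulative_dvh(scaled, full_mask(scaled))
        np.testing.assert_allclose(d2.dose_edges, 3.0 * d1.dose_edges)
        np.testing.assert_array_equal(d2.cum_volume_fraction, d1.cum_volume_fraction)

    def test_empty_mask_raises(self):
        grid = uniform_grid(1.0)
        mask = full_mask(grid)
        mask.voxels[:] = False
        with pytest.raises(ValueError, match="empty"):
            cumulative_dvh(grid, mask)


class TestDoseAtVolume:
    def test_hundred_voxel_ranks(self):
        grid = uniform_grid(0.0, dims=(100, 1, 1))
        grid.values[:, 0, 0] = np.arange(1, 101)
        dvh = cumulative_dvh(grid, full_mask(grid))
        assert dose_at_volume(dvh, 2.0) == 99.0
        assert dose_at_volume(dvh, 98.0) == 3.0
        assert dose_at_volume(dvh, 100.0) == 1.0  # minimum voxel dose

    @pytest.mark.parametrize("pct", [1, 2, 10, 50, 90, 98, 100])
    def test_matches_sort_oracle_random(self, pct, rng):
        doses = rng.integers(0, 50, size=333).astype(float)
        grid = DoseGrid((0, 0, 0), (1, 1, 1), doses.reshape(333, 1, 1))
        dvh = cumulative_dvh(grid, full_mask(grid))
        assert dose_at_volume(dvh, pct) == brute_dx(doses, pct)


class TestHomogeneityIndex:
    def test_uniform_dose_is_zero(self):
        grid = uniform_grid(5.0)
        assert homogeneity_index(grid, full_mask(grid)) == 0.0

    def test_hundred_voxel_worked_example(self):
        grid = uniform_grid(0.0, dims=(100, 1, 1))
        grid.values[:, 0, 0] = np.arange(1, 101)
        hi = homogeneity_index(grid, full_mask(grid))
        assert hi == pytest.approx((99.0 - 3.0) / 50.5)
        assert hi == pytest.approx(1.9010, abs=5e-5)

    def test_scale_invariance(self, rng):
        grid = uniform_grid(0.0, dims=(8, 8, 8))
        grid.values[:] = rng.random(grid.dims) + 0.1
        scaled = DoseGrid(grid.origin, grid.spacing, grid.values * 7.5)
        assert homogeneity_index(scaled, full_mask(scaled)) == pytest.approx(
            homogeneity_index(grid, full_mask(grid)), rel=1e-12
        )

    def test_zero_average_raises(self):
        grid = uniform_grid(0.0)
        with pytest.raises(ValueError, match="zero"):
            homogeneity_index(grid, full_mask(grid))


class TestExpandMask:
    def _single_voxel_mask(self, dims=(7, 7, 7), spacing=(1.0, 1.0, 1.0)):
        voxels = np.zeros(dims, dtype=bool)
        voxels[3, 3, 3] = True
        return StructureMask("pt", (0, 0, 0), spacing, voxels)

    def test_zero_margin_is_identity(self):
        mask = self._single_voxel_mask()
        out = expand_mask(mask, 0.0)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_one_spacing_margin_gives_face_cross(self):
        mask = self._single_voxel_mask()
        out = expand_mask(mask, 1.0)
        # brute-force: voxel centers within 1.0 of center (3,3,3)
        idx = np.indices(mask.voxels.shape).reshape(3, -1).T
        dist = np.linalg.norm(idx - np.array([3, 3, 3]), axis=1)
        expected = (dist <= 1.0 + 1e-9).reshape(mask.voxels.shape)
        np.testing.assert_array_equal(out.voxels, expected)
        assert out.n_voxels == 7  # 3D face-neighbor cross

    def test_anisotropic_spacing_brute_force(self):
        mask = self._single_voxel_mask(spacing=(0.5, 1.0, 2.0))
        out = expand_mask(mask, 1.2)
        idx = np.indices(mask.voxels.shape).reshape(3, -1).T.astype(float)
        delta = (idx - np.array([3, 3, 3])) * np.array([0.5, 1.0, 2.0])
        expected = (np.linalg.norm(delta, axis=1) <= 1.2 + 1e-9).reshape(mask.voxels.shape)
        np.testing.assert_array_equal(out.voxels, expected)

    def test_superset_and_monotone_in_margin(self):
        mask = self._single_voxel_mask()
        prev = mask.voxels
        for margin in (0.0, 0.7, 1.4, 2.1):
            out = expand_mask(mask, margin).voxels
            assert np.all(prev <= out)
            prev = out


class TestConformityIndex:
    def test_ideal_coverage_is_one(self):
        grid = uniform_grid(0.0, dims=(6, 6, 6))
        chamber = np.zeros(grid.dims, dtype=bool)
        chamber[2:4, 2:4, 2:4] = True
        grid.values[chamber] = 2.0  # isodose exactly the chamber
        cm = StructureMask("ch", grid.origin, grid.spacing, chamber)
        shell = expand_mask(cm, 1.5)
        assert conformity_index(grid, cm, shell) == 1.0

    def test_half_shell_coverage_worked_example(self):
        # chamber 100 voxels all >= RI; shell 400 of which 200 >= RI -> 0.5
        grid = uniform_grid(0.0, dims=(20, 20, 1))
        voxels = np.zeros(grid.dims, dtype=bool)
        voxels[5:15, 5:15, 0] = True  # 100-voxel chamber
        cm = StructureMask("ch", grid.origin, grid.spacing, voxels)
        shell_voxels = np.zeros(grid.dims, dtype=bool)
        shell_voxels[:, :, 0] = True  # 400-voxel shell (superset)
        shell = StructureMask("sh", grid.origin, grid.spacing, shell_voxels)
        grid.values[voxels] = 2.0
        outside = shell_voxels & ~voxels  # 300 voxels; cover 100 of them
        oi = np.argwhere(outside)[:100]
        grid.values[tuple(oi.T)] = 2.0
        assert conformity_index(grid, cm, shell) == pytest.approx(1.0 * 100 / 200)

    def test_scale_invariance(self, rng):
        grid = uniform_grid(0.0, dims=(10, 10, 10))
        grid.values[:] = rng.random(grid.dims) + 0.05
        voxels = np.zeros(grid.dims, dtype=bool)
        voxels[4:6, 4:6, 4:6] = True
        cm = StructureMask("ch", grid.origin, grid.spacing, voxels)
        shell = expand_mask(cm, 2.0)
        scaled = DoseGrid(grid.origin, grid.spacing, grid.values * 11.0)
        assert conformity_index(scaled, cm, shell) == conformity_index(grid, cm, shell)


class TestIntersection:
    def _offset_beam_grid(self, offset):
        grid = uniform_grid(0.0, dims=(21, 5, 5))
        x = np.arange(21)[:, None, None]
        grid.values[:] = np.exp(-0.5 * ((x - 10 - offset) / 2.0) ** 2)
        return grid

    def _center_mask(self, grid):
        voxels = np.zeros(grid.dims, dtype=bool)
        voxels[10, 2, 2] = True
        return StructureMask("ch", grid.origin, grid.spacing, voxels)

    def test_centered_beam_intersects(self):
        grid = self._offset_beam_grid(0)
        assert beam_intersects_chamber(grid, self._center_mask(grid))

    def test_far_offset_beam_does_not(self):
        grid = self._offset_beam_grid(9)
        assert not beam_intersects_chamber(grid, self._center_mask(grid))

    def test_threshold_sweep_is_monotone(self):
        grid = self._offset_beam_grid(3)
        mask = self._center_mask(grid)
        results = [
            beam_intersects_chamber(grid, mask, frac)
            for frac in (0.05, 0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        # once it stops intersecting at some threshold it never resumes
        assert results == sorted(results, reverse=True)

    def test_zero_dose_beam_is_false(self):
        grid = uniform_grid(0.0, dims=(5, 5, 5))
        mask = full_mask(grid)
        assert not beam_intersects_chamber(grid, mask)

    def test_fraction_counts(self):
        grids = [self._offset_beam_grid(0)] * 5 + [self._offset_beam_grid(9)] * 2
        mask = self._center_mask(grids[0])
        assert intersection_fraction(grids, mask) == pytest.approx(5 / 7)
        assert intersection_fraction(grids[:5], mask) == 1.0
        assert intersection_fraction(grids[5:], mask) == 0.0


class TestSumBeams:
    def test_two_identical_grids_double(self, rng):
        grid = uniform_grid(0.0, dims=(4, 4, 4))
        grid.values[:] = rng.random(grid.dims)
        total = sum_beam_doses([grid, grid])
        np.testing.assert_array_equal(total.values, 2.0 * grid.values)

    def test_permutation_invariance(self, rng):
        grids = []
        for _ in range(5):
            g = uniform_grid(0.0, dims=(4, 4, 4))
            g.values[:] = rng.random(g.dims)
            grids.append(g)
        a = sum_beam_doses(grids)
        order = rng.permutation(5)
        b = sum_beam_doses([grids[i] for i in order])
        np.testing.assert_allclose(a.values, b.values, rtol=1e-14)

    def test_lattice_mismatch_raises(self):
        g1 = uniform_grid(1.0, dims=(4, 4, 4))
        g2 = uniform_grid(1.0, dims=(4, 4, 5))
        with pytest.raises(LatticeMismatchError):
            sum_beam_doses([g1, g2])


class TestCombinedUncertainty:
    def test_single_beam_passthrough(self):
        assert combined_uncertainty([0.4]) == pytest.approx(0.4)

    def test_four_equal_beams_worked_example(self):
        assert combined_uncertainty([0.6] * 4) == pytest.approx(0.3)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_equal_uncertainty_scaling(self, n):
        i = 0.45
        brute = np.sqrt(sum(i**2 for _ in range(n))) / n
        assert combined_uncertainty([i] * n, n) == pytest.approx(i / np.sqrt(n))
        assert combined_uncertainty([i] * n) == pytest.approx(brute)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            combined_uncertainty([])


class TestPercentRms:
    def test_equal_pairs_zero(self):
        assert percent_rms_difference([(1.0, 1.0), (2.5, 2.5)]) == 0.0

    def test_single_pair(self):
        assert percent_rms_difference([(1.02, 1.00)]) == pytest.approx(2.0)

    def test_symmetric_three_percent(self):
        assert percent_rms_difference([(1.03, 1.00), (0.97, 1.00)]) == pytest.approx(3.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            percent_rms_difference([(1.0, 0.0)])


class TestRasterIO:
    def test_round_trip(self, tmp_path, rng):
        grid = DoseGrid(
            origin=(-1.5, 0.0, 2.25),
            spacing=(0.3, 0.3, 0.5),
            values=rng.random((4, 5, 6)),
            rel_uncertainty_pct=0.37,
        )
        path = tmp_path / "beam.raster"
        write_dose_raster(grid, path)
        again = read_dose_raster(path)
        np.testing.assert_array_equal(again.values, grid.values)
        assert again.origin == grid.origin
        assert again.spacing == grid.spacing
        assert again.rel_uncertainty_pct == grid.rel_uncertainty_pct

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "x.raster"
        path.write_text("not a raster\n")
        with pytest.raises(ValueError, match="raster"):
            read_dose_raster(path)


class TestDicomReaders:
    def _write_rtdose(self, path, values_xyz, spacing_cm=(0.2, 0.3, 0.5)):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        nx, ny, nz = values_xyz.shape
        scaling = 1e-4
        raw = np.round(values_xyz / scaling).astype(np.uint32)
        ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
        ds.BitsAllocated = ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.DoseGridScaling = scaling
        ds.PixelSpacing = [spacing_cm[1] * 10, spacing_cm[0] * 10]  # mm: row(y), col(x)
        ds.GridFrameOffsetVector = [k * spacing_cm[2] * 10 for k in range(nz)]
        ds.ImagePositionPatient = [0.0, 0.0, 0.0]  # mm, first voxel center
        ds.PixelData = np.ascontiguousarray(raw.transpose(2, 1, 0)).tobytes()
        ds.save_as(str(path), enforce_file_format=True)
        return scaling

    def test_rtdose_round_trip(self, tmp_path, rng):
        from imrtqa.dose_metrics import read_rtdose

        values = np.round(rng.random((4, 3, 2)), 3)
        scaling = self._write_rtdose(tmp_path / "dose.dcm", values)
        grid = read_rtdose(tmp_path / "dose.dcm")
        assert grid.dims == (4, 3, 2)
        np.testing.assert_allclose(grid.values, values, atol=scaling)
        assert grid.spacing == pytest.approx((0.2, 0.3, 0.5))
        # origin is the grid corner: first voxel center minus half spacing
        assert grid.origin == pytest.approx((-0.1, -0.15, -0.25))

    def test_rtstruct_square_contour_mask(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid
        from imrtqa.dose_metrics import mask_from_rtstruct

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset("s", {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTSTRUCT"
        roi = Dataset()
        roi.ROIName = "chamber"
        roi.ROINumber = 1
        ds.StructureSetROISequence = [roi]
        rc = Dataset()
        rc.ReferencedROINumber = 1
        contour = Dataset()
        contour.ContourGeometricType = "CLOSED_PLANAR"
        z_mm = 2.5  # cm 0.25 -> slice index 0 on a 0.5 cm-z grid
        square_cm = [(1.0, 1.0), (3.0, 1.0), (3.0, 3.0), (1.0, 3.0)]
        contour.ContourData = [v for (x, y) in square_cm for v in (x * 10, y * 10, z_mm)]
        contour.NumberOfContourPoints = 4
        rc.ContourSequence = [contour]
        ds.ROIContourSequence = [rc]
        ds.save_as(str(tmp_path / "ss.dcm"), enforce_file_format=True)

        grid = DoseGrid((0, 0, 0), (0.5, 0.5, 0.5), np.zeros((8, 8, 2)))
        mask = mask_from_rtstruct(tmp_path / "ss.dcm", grid, "chamber")
        # voxel centers strictly inside [1,3]x[1,3] cm: x,y in {1.25,...,2.75}
        assert mask.voxels[:, :, 1].sum() == 0
        inside = mask.voxels[:, :, 0]
        assert inside.sum() == 16
        assert inside[2:6, 2:6].all()

    def test_rtstruct_missing_roi_raises(self, tmp_path):
        from imrtqa.dose_metrics import mask_from_rtstruct

        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.zeros((2, 2, 2)))
        # reuse the rtdose file as a dataset without structure sequences
        self._write_rtdose(tmp_path / "notss.dcm", np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="chamber"):
            mask_from_rtstruct(tmp_path / "notss.dcm", grid, "chamber")
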