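"""Indexing, assembly, reorientation and diffusion-table extraction."""

import logging

import numpy as np
import pytest
from helpers_oracles import world_coordinates

from petmrbids import (
    PhantomSpec,
    assemble_volume,
    extract_diffusion_tables,
    index_dicom_tree,
    make_structural_phantom,
    reorient,
    reorient_bvecs,
    write_synthetic_dicom,
)
from petmrbids.dicom_ingest import DicomIngestError, DiffusionTables


class TestIndexDicomTree:
    def test_synthetic_tree_grouped_by_manifest(self, tmp_path):
        """2 subjects × 1 session × 3 series → 6 records with correct labels."""
        spec = PhantomSpec(grid=(16, 16, 4), semi_axes_vox=(5, 5, 1.5), seed=0)
        stack, _ = make_structural_phantom(spec)
        expected = set()
        uid = 0
        for sub in ("01", "02"):
            for seq in ("t1", "t2", "flair"):
                write_synthetic_dicom(
                    stack, tmp_path / f"sub-{sub}" / "ses-01" / seq, seq,
                    subject=sub, uid_seed=uid,
                )
                uid += 1
                expected.add((sub, "01", seq))
        records = index_dicom_tree(tmp_path)
        got = {(r.subject_label, r.session_label, r.series_description) for r in records}
        assert got == expected
        assert all(len(r.file_paths) == 4 for r in records)

    def test_empty_directory_yields_empty_list(self, tmp_path, caplog):
        with caplog.at_level(logging.WARNING):
            assert index_dicom_tree(tmp_path) == []
        assert "no DICOM files" in caplog.text

    def test_missing_root_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            index_dicom_tree(tmp_path / "nope")

    def test_two_sessions_carry_session_labels(self, tmp_path):
        spec = PhantomSpec(grid=(16, 16, 4), semi_axes_vox=(5, 5, 1.5), seed=0)
        stack, _ = make_structural_phantom(spec)
        for ses in ("01", "02"):
            write_synthetic_dicom(
                stack, tmp_path / "sub-04" / f"ses-{ses}" / "t2", "t2",
                subject="04", uid_seed=int(ses),
            )
        records = index_dicom_tree(tmp_path)
        assert sorted(r.session_label for r in records) == ["01", "02"]

    def test_non_dicom_files_skipped_with_warning(self, tmp_path, caplog):
        spec = PhantomSpec(grid=(16, 16, 4), semi_axes_vox=(5, 5, 1.5), seed=0)
        stack, _ = make_structural_phantom(spec)
        write_synthetic_dicom(stack, tmp_path / "sub-01" / "ses-01" / "t1", "t1", subject="01")
        (tmp_path / "sub-01" / "ses-01" / "t1" / "notes.txt").write_text("hello")
        with caplog.at_level(logging.WARNING):
            records = index_dicom_tree(tmp_path)
        assert len(records) == 1 and len(records[0].file_paths) == 4
        assert "notes.txt" in caplog.text

    def test_mixed_dimensions_flagged_invalid_not_merged(self, tmp_path):
        import pydicom

        spec = PhantomSpec(grid=(16, 16, 4), semi_axes_vox=(5, 5, 1.5), seed=0)
        stack, _ = make_structural_phantom(spec)
        paths = write_synthetic_dicom(
            stack, tmp_path / "sub-01" / "ses-01" / "t1", "t1", subject="01"
        )
        ds = pydicom.dcmread(paths[0])
        ds.Rows, ds.Columns = 8, 8
        ds.PixelData = np.zeros((8, 8), dtype=np.int16).tobytes()
        ds.save_as(paths[0], enforce_file_format=True)
        (record,) = index_dicom_tree(tmp_path)
        assert not record.valid
        assert "dimensions" in record.invalid_reason
        with pytest.raises(DicomIngestError):
            assemble_volume(record)


class TestAssembleVolume:
    def test_slice_stack_shape_and_bit_exact_roundtrip(self, tmp_path):
        """127 single-echo slices assemble to (Nx, Ny, 127), bit-exact."""
        spec = PhantomSpec(grid=(16, 16, 127), semi_axes_vox=(5, 5, 60), seed=3)
        stack, _ = make_structural_phantom(spec)
        write_synthetic_dicom(stack, tmp_path / "s" / "t1", "t1", subject="01")
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        vol = assemble_volume(record)
        assert vol.spatial_shape == (16, 16, 127)
        assert vol.voxels.ndim == 3
        assert np.array_equal(vol.voxels, stack.voxels)

    def test_multi_echo_interleaved_series(self, tmp_path):
        """2 echoes × 64 slices in one series → (Nx, Ny, 64, 2), echoes ascending."""
        spec = PhantomSpec(
            grid=(8, 8, 64), semi_axes_vox=(3, 3, 30), seed=4,
            echo_times_s=(0.005, 0.015),
        )
        stack, _ = make_structural_phantom(spec)
        write_synthetic_dicom(stack, tmp_path / "s" / "me", "me", subject="01")
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        assert record.echo_times == [0.005, 0.015]
        vol = assemble_volume(record)
        assert vol.voxels.shape == (8, 8, 64, 2)
        assert vol.echo_times == (0.005, 0.015)
        assert np.array_equal(vol.voxels, stack.voxels)

    def test_single_slice_is_a_legal_3d_volume(self, tmp_path):
        spec = PhantomSpec(grid=(16, 16, 1), semi_axes_vox=(5, 5, 0.4), seed=5)
        stack, _ = make_structural_phantom(spec)
        write_synthetic_dicom(stack, tmp_path / "s" / "one", "one", subject="01")
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        vol = assemble_volume(record)
        assert vol.spatial_shape == (16, 16, 1)

    def test_missing_position_and_instance_number_is_an_error(self, tmp_path):
        import pydicom

        spec = PhantomSpec(grid=(16, 16, 4), semi_axes_vox=(5, 5, 1.5), seed=6)
        stack, _ = make_structural_phantom(spec)
        paths = write_synthetic_dicom(
            stack, tmp_path / "s" / "t1", "t1", subject="01",
            dropout=["ImagePositionPatient"], force=True,
        )
        for p in paths:
            ds = pydicom.dcmread(p)
            del ds.InstanceNumber
            ds.save_as(p, enforce_file_format=True)
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        with pytest.raises(DicomIngestError, match="neither spatial position"):
            assemble_volume(record)

    def test_instance_number_fallback_when_positions_dropped(self, tmp_path):
        spec = PhantomSpec(grid=(16, 16, 4), semi_axes_vox=(5, 5, 1.5), seed=6)
        stack, _ = make_structural_phantom(spec)
        write_synthetic_dicom(
            stack, tmp_path / "s" / "t1", "t1", subject="01",
            dropout=["ImagePositionPatient"], force=True,
        )
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        vol = assemble_volume(record)
        assert np.array_equal(vol.voxels, stack.voxels)

    def test_inconsistent_pixel_spacing_is_an_error(self, tmp_path):
        import pydicom

        spec = PhantomSpec(grid=(16, 16, 4), semi_axes_vox=(5, 5, 1.5), seed=7)
        stack, _ = make_structural_phantom(spec)
        paths = write_synthetic_dicom(stack, tmp_path / "s" / "t1", "t1", subject="01")
        ds = pydicom.dcmread(paths[2])
        ds.PixelSpacing = ["3.0", "3.0"]
        ds.save_as(paths[2], enforce_file_format=True)
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        with pytest.raises(DicomIngestError, match="pixel spacing"):
            assemble_volume(record)

    def test_multiframe_and_classic_exports_assemble_identically(self, tmp_path):
        from petmrbids import make_dynamic_pet
        from petmrbids.synthetic_fixtures import H2O_SCHEDULE

        spec = PhantomSpec(
            grid=(16, 16, 8), semi_axes_vox=(5, 5, 3), seed=8,
            tac=(500.0, 10.0, 3.0, 6.0), frame_schedule=H2O_SCHEDULE,
        )
        stack, _, _ = make_dynamic_pet(spec)
        write_synthetic_dicom(
            stack, tmp_path / "a" / "pet", "pet", modality="PT", subject="01",
            multiframe=True,
        )
        write_synthetic_dicom(
            stack, tmp_path / "b" / "pet", "pet", modality="PT", subject="01",
            multiframe=False, uid_seed=1,
        )
        rec_a = index_dicom_tree(tmp_path / "a", layout=("series",))
        rec_b = index_dicom_tree(tmp_path / "b", layout=("series",))
        vol_a = assemble_volume(rec_a[0])
        vol_b = assemble_volume(rec_b[0])
        assert vol_a.voxels.shape == (16, 16, 8, 26)
        assert np.array_equal(vol_a.voxels, vol_b.voxels)
        assert np.allclose(vol_a.affine, vol_b.affine)


class TestReorient:
    def test_rsa_to_rpi_flips_axes_consistently(self, small_phantom):
        stack, _ = small_phantom
        rsa = reorient(stack, "RSA")
        rpi = reorient(rsa, "RPI")
        assert rsa.orientation_code == "RSA"
        assert rpi.orientation_code == "RPI"
        # same anatomy: world positions of the voxel extremes must agree
        corners = np.array([[0, 0, 0], [1, 1, 1]])
        for vol in (rsa, rpi):
            assert vol.voxels.sum() == stack.voxels.sum()

    def test_identity_target_leaves_voxels_unchanged(self, small_phantom):
        stack, _ = small_phantom
        same = reorient(stack, stack.orientation_code)
        assert np.array_equal(same.voxels, stack.voxels)
        assert np.allclose(same.affine, stack.affine)

    def test_round_trip_reproduces_voxels_exactly(self, small_phantom):
        stack, _ = small_phantom
        for code in ("RSA", "RPI", "LAS", "SPR"):
            there = reorient(stack, code)
            back = reorient(there, stack.orientation_code)
            assert np.array_equal(back.voxels, stack.voxels), code

    def test_composition_equals_direct_reorientation(self, small_phantom):
        stack, _ = small_phantom
        via = reorient(reorient(stack, "RSA"), "RPI")
        direct = reorient(stack, "RPI")
        assert np.array_equal(via.voxels, direct.voxels)
        assert np.allclose(via.affine, direct.affine)

    def test_marker_keeps_its_world_position(self):
        """An asymmetric marker must stay at the same anatomical spot,
        checked through an independent coordinate-mapping oracle."""
        vox = np.zeros((6, 5, 4), dtype=np.int16)
        marker = (5, 0, 3)
        vox[marker] = 77
        affine = np.diag([-2.0, -2.0, 2.0, 1.0])
        from petmrbids import VolumeStack
        import nibabel as nib

        stack = VolumeStack(
            voxels=vox, spacing_mm=[2, 2, 2], affine=affine,
            orientation_code="".join(nib.orientations.aff2axcodes(affine)),
        )
        world_before = world_coordinates(stack.affine, np.array([marker]))[0]
        for code in ("RPI", "RSA", "ASL"):
            moved = reorient(stack, code)
            new_marker = np.argwhere(moved.voxels == 77)[0]
            world_after = world_coordinates(moved.affine, new_marker[None, :])[0]
            assert np.allclose(world_after, world_before), code

    def test_oblique_affine_warns_and_snaps(self, small_phantom):
        from petmrbids import VolumeStack
        import nibabel as nib
        from scipy.spatial.transform import Rotation

        stack, _ = small_phantom
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        affine = stack.affine.copy()
        affine[:3, :3] = rot @ affine[:3, :3]
        oblique = VolumeStack(
            voxels=stack.voxels, spacing_mm=stack.spacing_mm, affine=affine,
            orientation_code="".join(nib.orientations.aff2axcodes(affine)),
        )
        with pytest.warns(UserWarning, match="oblique"):
            snapped = reorient(oblique, "RPI")
        assert snapped.orientation_code == "RPI"

    def test_invalid_code_rejected(self, small_phantom):
        stack, _ = small_phantom
        with pytest.raises(ValueError):
            reorient(stack, "RRZ")


class TestDiffusionTables:
    def _write_dwi(self, tmp_path, bvals, bvecs, seed=9):
        spec = PhantomSpec(grid=(8, 8, 4), semi_axes_vox=(3, 3, 1.5), seed=seed)
        stack, _ = make_structural_phantom(spec)
        from petmrbids import VolumeStack

        frames = len(bvals)
        vox = np.stack([stack.voxels] * frames, axis=3)
        dyn = VolumeStack(
            voxels=vox, spacing_mm=stack.spacing_mm, affine=stack.affine,
            orientation_code=stack.orientation_code,
            frame_times_s=tuple(range(frames)),
        )
        write_synthetic_dicom(
            dyn, tmp_path / "s" / "dwi", "dwi", subject="01",
            sidecar_truth={"bvals": bvals, "bvecs": bvecs},
        )
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        return record

    def test_b0_plus_six_directions(self, tmp_path):
        bvals = [0.0] + [1000.0] * 6
        bvecs = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                 [0.70710678, 0.70710678, 0], [0.70710678, 0, 0.70710678],
                 [0, 0.70710678, 0.70710678]]
        record = self._write_dwi(tmp_path, bvals, bvecs)
        tables = extract_diffusion_tables(record)
        assert np.allclose(tables.bvals, bvals)
        assert np.allclose(tables.bvecs[0], 0)
        norms = np.linalg.norm(tables.bvecs[1:], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-3)

    def test_all_b0_series_gives_zero_tables(self, tmp_path):
        record = self._write_dwi(tmp_path, [0.0, 0.0], [[0, 0, 0], [0, 0, 0]], seed=10)
        tables = extract_diffusion_tables(record)
        assert np.all(tables.bvals == 0)
        assert np.all(tables.bvecs == 0)

    def test_missing_gradient_tags_point_at_config_fallback(self, tmp_path):
        spec = PhantomSpec(grid=(8, 8, 4), semi_axes_vox=(3, 3, 1.5), seed=11)
        stack, _ = make_structural_phantom(spec)
        write_synthetic_dicom(stack, tmp_path / "s" / "dwi", "dwi", subject="01")
        (record,) = index_dicom_tree(tmp_path, layout=("subject", "series"))
        with pytest.raises(DicomIngestError, match="config fallback"):
            extract_diffusion_tables(record)

    def test_reoriented_bvecs_stay_unit_norm(self):
        bvecs = np.array([[0, 0, 0], [1, 0, 0], [0.6, 0.8, 0.0]])
        tables = DiffusionTables(bvals=np.array([0, 1000, 1000.0]), bvecs=bvecs)
        rotated = reorient_bvecs(tables, "LPS", "RPI")
        norms = np.linalg.norm(rotated.bvecs, axis=1)
        assert np.allclose(norms, [0, 1, 1], atol=1e-12)
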