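"""Presets, dataset layout, metadata sidecars and processing-input writers."""

import numpy as np
import pytest
import tifffile

from edpilot.experiment_io import (
    AcquisitionMetadata,
    DetectorGeometry,
    ExperimentIOError,
    OpticalPreset,
    PresetStore,
    next_dataset_path,
    parse_keyword_file,
    persist_settings,
    read_metadata_sidecar,
    restore_settings,
    write_dials_import,
    write_frames,
    write_pets2,
    write_xds_inp,
)
from edpilot.tracking import RecordConfig, TrackingError, record_trajectory_images
from edpilot.virtual_microscope import DetectorFrame, VirtualMicroscope


def table1_metadata(**over):
    """The published 121°/116-frame acquisition at 120 kV."""
    kw = dict(
        voltage=120.0, tilt_start=-60.5, tilt_end=60.5, rotation_speed=2.0,
        exposure=500.0, n_frames=116, aperture=19.0, beam_size=550.0,
        convergence_semi_angle=40.0, fluence=0.6,
    )
    kw.update(over)
    return AcquisitionMetadata.from_acquisition(**kw)


class TestPresets:
    def test_store_load_round_trip(self, tmp_path):
        store = PresetStore(tmp_path / "presets.json")
        preset = OpticalPreset("imaging", aperture=300.0, convergence_semi_angle=5.0,
                               beam_size=9000.0)
        store.store(preset)
        assert PresetStore(tmp_path / "presets.json").load("imaging") == preset

    def test_imaging_and_diffraction_apertures_coexist(self):
        # the published drug-crystal run: 300 µm imaging, 19 µm diffraction
        store = PresetStore()
        store.store(OpticalPreset("imaging", aperture=300.0, convergence_semi_angle=5.0))
        store.store(OpticalPreset("diffraction", aperture=19.0, convergence_semi_angle=40.0))
        assert store.load("imaging").aperture == 300.0
        assert store.load("diffraction").aperture == 19.0

    def test_record_refuses_without_imaging_preset(self, crystal_scene):
        scope = VirtualMicroscope(crystal_scene)
        with pytest.raises(TrackingError):
            record_trajectory_images(
                scope, RecordConfig(-10, 10, image_interval=2.0), presets=PresetStore()
            )

    def test_apply_pushes_preset_onto_scope(self, crystal_scene):
        scope = VirtualMicroscope(crystal_scene)
        store = PresetStore()
        store.store(OpticalPreset("diffraction", aperture=19.0,
                                  convergence_semi_angle=40.0, camera_length=800.0))
        store.apply(scope, "diffraction")
        assert scope.beam.mode == "diffraction"
        assert scope.beam.aperture == 19.0
        assert scope.camera_length == 800.0


class TestDatasetPaths:
    def test_first_crystal_is_one(self, tmp_path):
        ds = next_dataset_path(tmp_path, "op", "lamotrigine", "2025-01-15")
        assert ds.crystal_number == 1
        assert ds.path.is_dir()
        assert ds.path == tmp_path / "op" / "lamotrigine" / "2025-01-15" / "1"

    def test_increments_sequentially(self, tmp_path):
        for expected in (1, 2, 3):
            ds = next_dataset_path(tmp_path, "op", "s", "2025-01-15")
            assert ds.crystal_number == expected

    def test_gaps_never_reused(self, tmp_path):
        next_dataset_path(tmp_path, "op", "s", "2025-01-15")
        ds3 = next_dataset_path(tmp_path, "op", "s", "2025-01-15")
        (tmp_path / "op" / "s" / "2025-01-15" / str(ds3.crystal_number - 1)).rmdir()
        assert next_dataset_path(tmp_path, "op", "s", "2025-01-15").crystal_number == 3

    def test_independent_per_sample_and_date(self, tmp_path):
        next_dataset_path(tmp_path, "op", "a", "2025-01-15")
        assert next_dataset_path(tmp_path, "op", "b", "2025-01-15").crystal_number == 1
        assert next_dataset_path(tmp_path, "op", "a", "2025-01-16").crystal_number == 1


class TestSettingsPersistence:
    DEFAULTS = {"rotation_speed": 1.0, "exposure": 250.0}

    def test_same_day_restore_is_identity(self, tmp_path):
        path = tmp_path / "settings.json"
        saved = {"rotation_speed": 2.0, "exposure": 500.0}
        persist_settings(path, saved, date="2025-03-01")
        restored, notice = restore_settings(path, self.DEFAULTS, today="2025-03-01")
        assert restored == saved and notice is None

    def test_stale_settings_fall_back_to_defaults(self, tmp_path):
        path = tmp_path / "settings.json"
        persist_settings(path, {"rotation_speed": 2.0}, date="2025-03-01")
        restored, notice = restore_settings(path, self.DEFAULTS, today="2025-03-02")
        assert restored == self.DEFAULTS and notice is not None

    def test_corrupt_file_never_crashes(self, tmp_path):
        path = tmp_path / "settings.json"
        path.write_text('{"saved_on": "2025-03-01", "settings": [tr')
        restored, notice = restore_settings(path, self.DEFAULTS, today="2025-03-01")
        assert restored == self.DEFAULTS and "unreadable" in notice


class TestMetadata:
    def test_oscillation_consistent_with_published_rounding(self):
        meta = table1_metadata()
        assert meta.tilt_range == pytest.approx(121.0)
        assert f"{meta.oscillation:.2f}" == "1.04"
        assert meta.oscillation * meta.n_frames == pytest.approx(meta.tilt_range)

    def test_total_time_includes_dead_time(self):
        # 116 frames × (500 + 21) ms ≈ the printed 60.43 s wall time
        assert table1_metadata(frame_overhead=21.0).total_time_s == pytest.approx(
            60.43, abs=0.01
        )

    def test_wavelength_voltage_consistency_enforced(self):
        with pytest.raises(ValueError):
            AcquisitionMetadata(
                voltage=120.0, wavelength=0.0251, tilt_start=0, tilt_end=10,
                rotation_speed=2.0, exposure=500.0, n_frames=10,
            )

    def test_sidecar_round_trip_field_identical(self):
        meta = table1_metadata(operator="md", sample="lamotrigine", mode="cRED")
        assert AcquisitionMetadata.from_sidecar_text(meta.to_sidecar_text()) == meta


class TestWriteFrames:
    def frames(self, n, shape=(32, 32)):
        rng = np.random.default_rng(1)
        return [
            DetectorFrame(pixels=rng.poisson(100, shape).astype(np.uint16),
                          exposure=500.0, stage_alpha_at_exposure=float(i))
            for i in range(n)
        ]

    def test_numbered_one_based_zero_padded(self, tmp_path):
        meta = table1_metadata(n_frames=5)
        written = write_frames(self.frames(5), meta, tmp_path / "ds")
        assert [p.name for p in written] == [
            f"frame_{i:05d}.tif" for i in range(1, 6)
        ]
        assert (tmp_path / "ds" / "metadata.txt").exists()
        assert tifffile.imread(written[0]).dtype == np.uint16

    def test_sidecar_round_trip(self, tmp_path):
        meta = table1_metadata(n_frames=3, operator="op", sample="mof")
        write_frames(self.frames(3), meta, tmp_path / "ds")
        assert read_metadata_sidecar(tmp_path / "ds" / "metadata.txt") == meta

    def test_empty_stack_rejected(self, tmp_path):
        with pytest.raises(ExperimentIOError):
            write_frames([], table1_metadata(), tmp_path / "ds")

    def test_inconsistent_shapes_rejected_before_writing(self, tmp_path):
        frames = self.frames(2) + self.frames(1, shape=(16, 16))
        with pytest.raises(ExperimentIOError):
            write_frames(frames, table1_metadata(n_frames=3), tmp_path / "ds")
        assert not (tmp_path / "ds" / "frame_00001.tif").exists()


class TestProcessingInputs:
    GEOM = DetectorGeometry()

    def test_xds_inp_published_values(self):
        text = write_xds_inp(table1_metadata(), self.GEOM)
        kv = parse_keyword_file(text)
        assert kv["X-RAY_WAVELENGTH"] == "0.0335"
        assert kv["DATA_RANGE"] == "1 116"
        assert float(kv["OSCILLATION_RANGE"]) == 121.0 / 116.0  # full precision
        assert kv["STARTING_ANGLE"] == "-60.5"
        for key in ("NAME_TEMPLATE_OF_DATA_FRAMES", "DETECTOR_DISTANCE", "ORGX",
                    "NX", "QX", "ROTATION_AXIS"):
            assert key in kv

    def test_xds_rejects_incomplete_geometry(self):
        with pytest.raises(ExperimentIOError):
            write_xds_inp(table1_metadata(), DetectorGeometry(nx=0))

    def test_pets2_header_and_imagelist(self):
        meta = table1_metadata()
        names = [f"frame_{i:05d}.tif" for i in range(1, 117)]
        text = write_pets2(meta, names)
        assert "lambda 0.0335" in text
        body = text.split("\nimagelist\n")[1].split("\nendimagelist")[0].splitlines()
        assert len(body) == 116
        angles = [float(line.split()[1]) for line in body]
        spacings = np.diff(angles)
        np.testing.assert_allclose(spacings, meta.oscillation, rtol=1e-12)
        assert angles == sorted(angles)

    def test_pets2_rejects_mismatched_frame_list(self):
        with pytest.raises(ExperimentIOError):
            write_pets2(table1_metadata(), ["a.tif"])

    def test_dials_oscillation_matches_xds_bit_for_bit(self):
        meta = table1_metadata()
        xds_kv = parse_keyword_file(write_xds_inp(meta, self.GEOM))
        dials = write_dials_import(meta, self.GEOM)
        dials_osc = next(
            line.split("=")[1] for line in dials.splitlines()
            if line.startswith("geometry.scan.oscillation")
        )
        assert dials_osc.split(",")[1] == xds_kv["OSCILLATION_RANGE"]
        assert dials_osc.split(",")[0] == xds_kv["STARTING_ANGLE"]
        wl = next(line.split("=")[1] for line in dials.splitlines()
                  if line.startswith("geometry.beam.wavelength"))
        assert wl == xds_kv["X-RAY_WAVELENGTH"]

    def test_downhill_scan_flips_rotation_axis(self):
        up = parse_keyword_file(write_xds_inp(table1_metadata(), self.GEOM))
        down = parse_keyword_file(
            write_xds_inp(table1_metadata(tilt_start=60.5, tilt_end=-60.5), self.GEOM)
        )
        assert up["ROTATION_AXIS"] == "0.0 1.0 0.0"
        assert down["ROTATION_AXIS"] == "-0.0 -1.0 -0.0"
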