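"""Image, stack and annotation I/O contracts."""

import json

import numpy as np
import pandas as pd
import pytest
import tifffile

from clearquant.errors import AnnotationError, FormatError
from clearquant.image_io import (
    Image2D,
    LandmarkSegment,
    RoiRect,
    load_annotations,
    load_annotated_pair,
    load_image,
    load_stack,
    write_image,
    write_results_table,
)
from clearquant.synthetic_data import SceneGroundTruth, generate_grating_scene


class TestLoadImage:
    def test_grayscale_identity_round_trip(self, tmp_path):
        data = np.array([[0, 100], [200, 300]], dtype=np.uint16)
        tifffile.imwrite(tmp_path / "img.tif", data)
        img = load_image(tmp_path / "img.tif", pixel_size_um=2.0)
        np.testing.assert_array_equal(img.pixels, data)
        assert img.pixel_size_um == 2.0 and img.bit_depth == 16

    def test_rgb_converts_by_channel_mean(self, tmp_path):
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        rgb[0, 0] = (30, 60, 90)
        tifffile.imwrite(tmp_path / "rgb.tif", rgb, photometric="rgb")
        img = load_image(tmp_path / "rgb.tif", pixel_size_um=1.0)
        assert img.pixels[0, 0] == pytest.approx(60.0)

    def test_synthetic_scene_round_trips_bit_identically(self, tmp_path, noiseless_scene):
        write_image(noiseless_scene.post_image, tmp_path / "post.tif")
        reloaded = load_image(tmp_path / "post.tif", pixel_size_um=5.0)
        np.testing.assert_array_equal(
            reloaded.pixels, np.asarray(noiseless_scene.post_image.pixels)
        )

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_image(tmp_path / "absent.tif", 1.0)

    def test_invariants_enforced(self):
        with pytest.raises(FormatError):
            Image2D(np.array([[0, 300]]), pixel_size_um=1.0, bit_depth=8)
        with pytest.raises(FormatError):
            Image2D(np.array([[-1.0, 2.0]]), pixel_size_um=1.0)


class TestLoadStack:
    def test_pages_become_z_slices(self, tmp_path):
        data = np.arange(3 * 4 * 4, dtype=np.uint16).reshape(3, 4, 4)
        tifffile.imwrite(tmp_path / "s.tif", data)
        stack = load_stack(tmp_path / "s.tif", (0.2, 0.1, 0.1))
        assert stack.shape == (3, 4, 4)
        np.testing.assert_array_equal(stack.voxels, data)

    def test_single_page_is_degenerate_stack(self, tmp_path):
        tifffile.imwrite(tmp_path / "s.tif", np.ones((4, 4), dtype=np.uint8))
        assert load_stack(tmp_path / "s.tif", (1, 1, 1)).shape == (1, 4, 4)

    def test_ragged_pages_rejected(self, tmp_path):
        with tifffile.TiffWriter(tmp_path / "ragged.tif") as tw:
            tw.write(np.zeros((4, 4), dtype=np.uint8))
            tw.write(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(FormatError, match="ragged"):
            load_stack(tmp_path / "ragged.tif", (1, 1, 1))


def _write_annotation(tmp_path, mutate=None):
    scene = generate_grating_scene(SceneGroundTruth(seed=2))
    write_image(scene.pre_image, tmp_path / "pre.tif")
    write_image(scene.post_image, tmp_path / "post.tif")
    doc = {
        "specimen_id": "#45",
        "treatment": "Rapiclear1.52_E",
        "pre_image": "pre.tif",
        "post_image": "post.tif",
        "pixel_size_um": 5.0,
        "rois": [
            {"label": lab, "x0": r.x0, "y0": r.y0, "width": r.width, "height": r.height}
            for lab, r in sorted(scene.rois_post.items())
        ],
        "landmarks": {
            "brain_length_pre": [list(scene.brain_length_pre.p1),
                                 list(scene.brain_length_pre.p2)],
            "brain_length_post": [list(scene.brain_length_post.p1),
                                  list(scene.brain_length_post.p2)],
            "medulla_height_pre": [list(scene.medulla_height_pre.p1),
                                   list(scene.medulla_height_pre.p2)],
        },
    }
    if mutate:
        mutate(doc)
    path = tmp_path / "ann.json"
    path.write_text(json.dumps(doc))
    return path


class TestAnnotations:
    def test_valid_document_loads_four_rois(self, tmp_path):
        doc = load_annotations(_write_annotation(tmp_path))
        assert sorted(r.label for r in doc.rois) == ["a", "b", "c", "d"]
        pair = load_annotated_pair(tmp_path / "ann.json")
        assert pair.specimen_id == "#45"

    def test_duplicate_roi_label_rejected(self, tmp_path):
        def mutate(doc):
            doc["rois"][1]["label"] = "a"

        with pytest.raises(AnnotationError, match="a,b,c,d"):
            load_annotations(_write_annotation(tmp_path, mutate))

    def test_out_of_bounds_roi_names_offender(self, tmp_path):
        def mutate(doc):
            doc["rois"][2]["x0"] = 10_000

        path = _write_annotation(tmp_path, mutate)
        with pytest.raises(AnnotationError, match="'c'"):
            load_annotated_pair(path)

    def test_degenerate_landmark_rejected(self, tmp_path):
        def mutate(doc):
            doc["landmarks"]["brain_length_pre"] = [[5.0, 5.0], [5.0, 5.0]]

        with pytest.raises(AnnotationError, match="p1 == p2"):
            load_annotations(_write_annotation(tmp_path, mutate))

    def test_landmark_endpoints_identical_in_segment(self):
        with pytest.raises(AnnotationError):
            LandmarkSegment(p1=(1.0, 2.0), p2=(1.0, 2.0))

    def test_roi_invariants(self):
        with pytest.raises(AnnotationError):
            RoiRect(x0=0, y0=0, width=0, height=5, label="a")


class TestResultsTable:
    ROW = {
        "specimen_id": "#45", "treatment": "MS_P", "c_brain": 0.17452281,
        "c_ctrl": 0.50104518, "t": 0.34831751, "h_um": 1380.289,
        "h_max_um": 1494.1692, "t_norm": 0.32177001, "d_pre_um": 2764.7655,
        "d_post_um": 1924.4184, "retained_size": 0.69605123,
    }

    def test_single_row(self, tmp_path):
        write_results_table([self.ROW], tmp_path / "r.csv")
        lines = (tmp_path / "r.csv").read_text().strip().splitlines()
        assert len(lines) == 2 and lines[0].startswith("specimen_id,treatment")

    def test_empty_list_writes_header_only(self, tmp_path):
        write_results_table([], tmp_path / "r.csv")
        assert len((tmp_path / "r.csv").read_text().strip().splitlines()) == 1

    def test_round_trip_preserves_six_significant_figures(self, tmp_path):
        write_results_table([self.ROW], tmp_path / "r.csv")
        back = pd.read_csv(tmp_path / "r.csv").iloc[0]
        for key, val in self.ROW.items():
            if isinstance(val, float):
                assert back[key] == pytest.approx(val, rel=1e-6)
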