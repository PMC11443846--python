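import numpy as np
import pytest
import imageio.v3 as iio

from fociquant import discover_batch, load_gray_image, write_label_image, write_overlay
from fociquant.batchio import PALETTE, label_colors
from fociquant.errors import (
    BatchMismatchError,
    EmptyBatchError,
    InvalidInputError,
    ShapeMismatchError,
)

from conftest import gray


class TestLoadGrayImage:
    def test_black_rgb_png_loads_as_zeros(self, tmp_path):
        path = tmp_path / "black.png"
        iio.imwrite(path, np.zeros((2, 2, 3), dtype=np.uint8))
        img = load_gray_image(path)
        assert img.pixels.shape == (2, 2)
        assert (img.pixels == 0).all()
        assert img.source_name == "black.png"

    def test_full_scale_16bit_tiff_maps_to_255(self, tmp_path):
        path = tmp_path / "bright.tif"
        iio.imwrite(path, np.full((3, 3), 65535, dtype=np.uint16))
        assert (load_gray_image(path).pixels == 255).all()

    def test_rgb_luminance_weighting(self, tmp_path):
        """Pure R/G/B pixels map to the rounded BT.601 luminances."""
        rgb = np.array([[(255, 0, 0), (0, 255, 0), (0, 0, 255)]], dtype=np.uint8)
        path = tmp_path / "rgb.png"
        iio.imwrite(path, rgb)
        assert load_gray_image(path).pixels.tolist() == [[76, 150, 29]]

    @pytest.mark.parametrize("ext", [".png", ".tif", ".jpg"])
    def test_grayscale_formats_load(self, tmp_path, rng, ext):
        arr = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        path = tmp_path / f"img{ext}"
        iio.imwrite(path, arr)
        loaded = load_gray_image(path).pixels
        if ext == ".jpg":  # lossy, but still 8x8 uint8
            assert loaded.shape == (8, 8)
        else:
            assert (loaded == arr).all()

    def test_load_write_load_roundtrip(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        first = tmp_path / "a.png"
        second = tmp_path / "b.png"
        iio.imwrite(first, arr)
        img = load_gray_image(first)
        iio.imwrite(second, img.pixels)
        assert (load_gray_image(second).pixels == img.pixels).all()

    def test_unreadable_file_names_the_file(self, tmp_path):
        bad = tmp_path / "junk.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(Exception) as err:
            load_gray_image(bad)
        assert "junk.png" in str(err.value)


class TestDiscoverBatch:
    def _write(self, directory, names, shape=(10, 10), value=0):
        directory.mkdir(exist_ok=True)
        for name in names:
            iio.imwrite(directory / name, np.full(shape, value, dtype=np.uint8))

    def test_pairs_by_sorted_rank(self, tmp_path):
        self._write(tmp_path / "m", ["b.png", "a.png"])
        self._write(tmp_path / "d", ["a.png", "b.png"])
        batch = discover_batch(tmp_path / "m", tmp_path / "d")
        assert [m.source_name for m, _ in batch.pairs] == ["a.png", "b.png"]
        assert [d.source_name for _, d in batch.pairs] == ["a.png", "b.png"]

    def test_unequal_counts_reports_both(self, tmp_path):
        self._write(tmp_path / "m", ["1.tif", "2.tif", "3.tif"])
        self._write(tmp_path / "d", ["1.tif", "2.tif"])
        with pytest.raises(BatchMismatchError, match="3.*2"):
            discover_batch(tmp_path / "m", tmp_path / "d")

    def test_shape_mismatch_names_both_files(self, tmp_path):
        self._write(tmp_path / "m", ["x.png"], shape=(100, 100))
        self._write(tmp_path / "d", ["y.png"], shape=(100, 120))
        with pytest.raises(ShapeMismatchError, match="x.png.*y.png"):
            discover_batch(tmp_path / "m", tmp_path / "d")

    def test_empty_directory_raises(self, tmp_path):
        (tmp_path / "m").mkdir()
        self._write(tmp_path / "d", ["a.png"])
        with pytest.raises(EmptyBatchError):
            discover_batch(tmp_path / "m", tmp_path / "d")


class TestLabelAndOverlayImages:
    def test_all_zero_labels_written_black(self, tmp_path):
        path = tmp_path / "lab.png"
        write_label_image(np.zeros((5, 5), dtype=np.int32), path)
        assert (iio.imread(path) == 0).all()

    def test_two_labels_give_three_distinct_colors(self, tmp_path):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[1:3, 1:3] = 1
        labels[4:6, 4:6] = 2
        path = tmp_path / "lab.png"
        write_label_image(labels, path)
        colors = np.unique(iio.imread(path).reshape(-1, 3), axis=0)
        assert len(colors) == 3

    def test_roundtrip_preserves_distinct_color_count(self, tmp_path, rng):
        labels = rng.integers(0, 5, size=(20, 20)).astype(np.int32)
        path = tmp_path / "lab.png"
        write_label_image(labels, path)
        reloaded = iio.imread(path)
        n_colors = len(np.unique(reloaded.reshape(-1, 3), axis=0))
        expected = len(np.unique(label_colors(labels).reshape(-1, 3), axis=0))
        assert n_colors == expected

    def test_overlay_without_labels_is_gray_render(self, tmp_path, rng):
        raw = gray(rng.integers(0, 256, size=(9, 9), dtype=np.uint8))
        path = tmp_path / "ov.png"
        write_overlay(raw, np.zeros((9, 9), dtype=np.int32), path)
        out = iio.imread(path)
        assert (out == raw.pixels[:, :, None]).all()

    def test_overlay_recolors_exactly_the_focus_pixels(self, tmp_path):
        raw = gray(np.full((8, 8), 100, dtype=np.uint8))
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:4, 2:4] = 1  # one 4-px focus
        path = tmp_path / "ov.png"
        write_overlay(raw, labels, path)
        out = iio.imread(path)
        non_gray = (out != 100).any(axis=2)
        assert int(non_gray.sum()) == 4
        assert (out[labels == 1] == PALETTE[0]).all()

    def test_full_frame_label_leaves_no_gray(self, tmp_path):
        raw = gray(np.full((4, 4), 50, dtype=np.uint8))
        labels = np.ones((4, 4), dtype=np.int32)
        path = tmp_path / "ov.png"
        write_overlay(raw, labels, path)
        assert (iio.imread(path) == PALETTE[0]).all()

    def test_overlay_shape_mismatch_rejected(self, tmp_path):
        raw = gray(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(InvalidInputError):
            write_overlay(raw, np.zeros((5, 5), dtype=np.int32), tmp_path / "x.png")
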