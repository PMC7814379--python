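"""Bean detection, reading-order numbering, spectrum extraction, side pairing."""

import numpy as np
import pytest

from cocoahsi.errors import PairingError, SegmentationError
from cocoahsi.hypercube import Hypercube
from cocoahsi.segmentation import (LabelMap, extract_mean_spectra, pair_sides,
                                   segment_beans)


def grid_cube(values_by_cell=None, rows=40, cols=50, bands=6, bg=0.05, fg=0.4):
    """2x5 grid of 6x4 rectangles on a dark background."""
    data = np.full((rows, cols, bands), bg)
    labels = np.zeros((rows, cols), dtype=int)
    k = 0
    for gr in range(2):
        for gc in range(5):
            k += 1
            r0, c0 = 5 + gr * 20, 3 + gc * 10
            val = fg if values_by_cell is None else values_by_cell[k - 1]
            data[r0:r0 + 6, c0:c0 + 4, :] = val
            labels[r0:r0 + 6, c0:c0 + 4] = k
    return Hypercube(data, np.linspace(1000, 1500, bands), "reflectance"), labels


class TestSegmentBeans:
    def test_synthetic_scene_centroids(self, noise_free_study):
        nf = noise_free_study
        lab = segment_beans(nf["cube"])
        st = nf["scene_truth"]
        assert lab.n_objects == 10
        for k in range(1, 11):
            true_centroid = np.mean(np.argwhere(st.labels == k), axis=0)
            assert np.abs(lab.centroids[k - 1] - true_centroid).max() < 1.0

    def test_reading_order_is_row_major(self):
        cube, _ = grid_cube()
        lab = segment_beans(cube)
        assert lab.n_objects == 10
        # centroid columns increase within each stage row
        for row in (0, 1):
            cols = lab.centroids[lab.rows == row][:, 1]
            assert (np.diff(cols) > 0).all()
        assert (lab.rows == np.repeat([0, 1], 5)).all()

    def test_uniform_cube_raises(self):
        cube = Hypercube(np.full((10, 10, 3), 0.2), np.arange(3.0), "reflectance")
        with pytest.raises(SegmentationError):
            segment_beans(cube)

    def test_one_pixel_gap_healed_by_closing(self):
        data = np.full((20, 20, 3), 0.05)
        data[5:15, 4:9] = 0.5
        data[5:15, 10:15] = 0.5   # 1-px gap at column 9
        cube = Hypercube(data, np.arange(3.0), "reflectance")
        lab = segment_beans(cube, min_area=10)
        assert lab.n_objects == 1

    def test_min_area_drops_specks(self):
        data = np.full((30, 30, 3), 0.05)
        data[5:15, 5:15] = 0.5
        data[25, 25] = 0.5        # single-pixel speck
        cube = Hypercube(data, np.arange(3.0), "reflectance")
        lab = segment_beans(cube)
        assert lab.n_objects == 1

    def test_illumination_scaling_invariance(self, noise_free_study):
        cube = noise_free_study["cube"]
        scaled = Hypercube(cube.data * 0.37, cube.wavelengths, "reflectance")
        assert np.array_equal(segment_beans(cube).labels,
                              segment_beans(scaled).labels)

    def test_pixel_partition(self, noise_free_study):
        lab = segment_beans(noise_free_study["cube"])
        total = lab.labels.size
        assert lab.pixel_counts.sum() + (lab.labels == 0).sum() == total

    def test_border_touching_flag(self):
        data = np.full((20, 20, 3), 0.05)
        data[0:6, 5:10] = 0.5     # touches top border
        data[12:18, 5:10] = 0.5
        cube = Hypercube(data, np.arange(3.0), "reflectance")
        lab = segment_beans(cube, min_area=5)
        assert lab.border_touching[0]
        assert not lab.border_touching[1]


class TestExtractMeanSpectra:
    def test_homogeneous_object_mean_is_pixel(self):
        cube, truth_labels = grid_cube()
        lab = segment_beans(cube)
        table = extract_mean_spectra(cube, lab)
        assert np.allclose(table.X, 0.4, atol=1e-12)
        assert (table.meta["n_pixels"] == 24).all()

    def test_two_pixel_arithmetic_mean(self):
        data = np.full((1, 2, 3), 0.2)
        data[0, 1] = 0.4
        cube = Hypercube(data, np.arange(3.0), "reflectance")
        lab = LabelMap(labels=np.array([[1, 1]]), centroids=np.array([[0.0, 0.5]]),
                       pixel_counts=np.array([2]), rows=np.array([0]),
                       border_touching=np.array([True]))
        table = extract_mean_spectra(cube, lab, stat="arithmetic")
        assert np.allclose(table.X[0], 0.3)

    def test_geometric_mean_is_mean_absorbance(self):
        data = np.full((1, 2, 3), 0.2)
        data[0, 1] = 0.4
        cube = Hypercube(data, np.arange(3.0), "reflectance")
        lab = LabelMap(labels=np.array([[1, 1]]), centroids=np.array([[0.0, 0.5]]),
                       pixel_counts=np.array([2]), rows=np.array([0]),
                       border_touching=np.array([True]))
        table = extract_mean_spectra(cube, lab)
        assert np.allclose(table.X[0], np.sqrt(0.2 * 0.4))

    def test_truth_masks_reproduce_rendered_spectra(self, noise_free_study):
        """Segmentation-based extraction matches the renderer's own masks."""
        nf = noise_free_study
        lab = segment_beans(nf["cube"])
        table = extract_mean_spectra(nf["cube"], lab)
        from cocoahsi.synthetic import mean_spectra_from_truth
        expected = mean_spectra_from_truth(nf["cube"], nf["scene_truth"])
        assert np.allclose(table.X, expected, rtol=1e-10)

    def test_shape_mismatch_raises(self, noise_free_study):
        cube = noise_free_study["cube"]
        lab = LabelMap(labels=np.zeros((3, 3), dtype=int),
                       centroids=np.empty((0, 2)), pixel_counts=np.array([]),
                       rows=np.array([]), border_touching=np.array([]))
        with pytest.raises(ValueError):
            extract_mean_spectra(cube, lab)


class TestPairSides:
    def _label_map(self, order_cols):
        """2x5 grid label map with given centroid column order per row."""
        centroids = np.array([[5.0, c] for c in order_cols[:5]]
                             + [[20.0, c] for c in order_cols[5:]])
        return LabelMap(labels=np.zeros((30, 50), dtype=int),
                        centroids=centroids,
                        pixel_counts=np.full(10, 24),
                        rows=np.repeat([0, 1], 5),
                        border_touching=np.zeros(10, dtype=bool))

    def test_identity_mapping(self):
        a = self._label_map([3, 13, 23, 33, 43] * 2)
        mapping = pair_sides(a, a, bean_ids=np.arange(101, 111))
        assert np.array_equal(mapping, np.arange(101, 111))

    def test_mirror_flip_reverses_within_rows(self):
        a = self._label_map([3, 13, 23, 33, 43] * 2)
        mapping = pair_sides(a, a, bean_ids=np.arange(1, 11), mirror_flip=True)
        assert np.array_equal(mapping, [5, 4, 3, 2, 1, 10, 9, 8, 7, 6])

    def test_unequal_counts_raise_with_both_counts(self):
        a = self._label_map([3, 13, 23, 33, 43] * 2)
        b = LabelMap(labels=np.zeros((3, 3), dtype=int),
                     centroids=np.array([[1.0, 1.0]]),
                     pixel_counts=np.array([4]), rows=np.array([0]),
                     border_touching=np.array([False]))
        with pytest.raises(PairingError, match="10.*1"):
            pair_sides(a, b)
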