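import numpy as np
import pytest
from scipy import ndimage

from dewetsim import (
    decompose_traction,
    equal_pixel_split,
    morphometrics,
    ring_kymograph,
    ring_labels,
    subdomain_timeseries,
)
from dewetsim.traction import BinaryMask, RingLabels, VectorField2D, inward_normals


def disk_mask(radius_px: int, pixel_size: float = 1.0, pad: int = 10) -> BinaryMask:
    n = 2 * radius_px + 2 * pad
    rows, cols = np.indices((n, n))
    c = (n - 1) / 2.0
    return BinaryMask((rows - c) ** 2 + (cols - c) ** 2 <= radius_px**2, pixel_size)


@pytest.fixture(scope="module")
def disk200():
    return disk_mask(200)


def centripetal_field(mask: BinaryMask, magnitude: float = 1.0) -> VectorField2D:
    rows, cols = np.indices(mask.data.shape)
    r0, c0 = rows[mask.data].mean(), cols[mask.data].mean()
    dx, dy = c0 - cols, r0 - rows
    nrm = np.hypot(dx, dy)
    nrm[nrm == 0] = 1.0
    m = np.where(mask.data, magnitude, 0.0)
    return VectorField2D(tx=m * dx / nrm, ty=m * dy / nrm)


class TestMorphometrics:
    def test_disk_matches_analytic_circle(self, disk200):
        rec = morphometrics(disk200)
        assert rec.area == pytest.approx(np.pi * 200**2, rel=0.01)
        assert rec.circularity >= 0.99
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.01)
        assert rec.major_diameter == pytest.approx(400.0, rel=0.02)

    def test_square_circularity(self):
        sq = np.zeros((220, 220), dtype=bool)
        sq[10:210, 10:210] = True
        rec = morphometrics(BinaryMask(sq, 1.0))
        assert rec.circularity == pytest.approx(np.pi / 4.0, rel=0.01)

    def test_ellipse_aspect_ratio(self):
        rows, cols = np.indices((300, 500))
        ell = ((cols - 250) / 200.0) ** 2 + ((rows - 150) / 100.0) ** 2 <= 1.0
        rec = morphometrics(BinaryMask(ell, 1.0))
        assert rec.aspect_ratio == pytest.approx(2.0, rel=0.01)

    def test_pixel_size_scales_area(self):
        small = disk_mask(50, pixel_size=3.0)
        rec = morphometrics(small)
        assert rec.area == pytest.approx(np.pi * 150.0**2, rel=0.02)

    def test_rejects_bad_masks(self):
        with pytest.raises(ValueError):
            morphometrics(BinaryMask(np.zeros((5, 5), dtype=bool)))
        two = np.zeros((20, 20), dtype=bool)
        two[2:5, 2:5] = True
        two[12:15, 12:15] = True
        with pytest.raises(ValueError):
            morphometrics(BinaryMask(two))


class TestRings:
    def test_thin_line_is_single_ring(self):
        line = np.zeros((10, 30), dtype=bool)
        line[5, 5:25] = True
        rl = ring_labels(BinaryMask(line))
        assert rl.n_rings == 1
        assert np.all(rl.labels[line] == 1)

    def test_disk_ring_count_matches_radius(self):
        rl = ring_labels(disk_mask(10))
        assert abs(rl.n_rings - 10) <= 1

    def test_rings_partition_mask(self, disk200):
        rl = ring_labels(disk200)
        assert rl.ring_counts().sum() == disk200.n_foreground
        assert np.all((rl.labels > 0) == disk200.data)
        counts = rl.ring_counts()
        assert counts[0] > counts[-1]  # outer ring holds more pixels than the core

    def test_equal_split_balance(self, disk200):
        rl = ring_labels(disk200)
        split = equal_pixel_split(rl)
        assert not np.any(split.outer & split.inner)
        assert np.array_equal(split.outer | split.inner, disk200.data)
        imbalance = abs(int(split.outer.sum()) - int(split.inner.sum()))
        assert imbalance <= rl.ring_counts().max()

    def test_equal_split_euclidean_depth(self, disk200):
        """With ideal annular rings the equal-area cut sits at depth
        (1 − 1/√2)·R ≈ 0.293·R from the edge."""
        d = ndimage.distance_transform_edt(disk200.data)
        ideal = np.ceil(d).astype(np.int32)
        split = equal_pixel_split(RingLabels(labels=ideal))
        depth = split.m / ideal.max()
        assert depth == pytest.approx(1.0 - 1.0 / np.sqrt(2.0), abs=0.02)

    def test_two_equal_rings(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, :2] = 1
        labels[1, :2] = 2
        split = equal_pixel_split(RingLabels(labels=labels))
        assert split.m == 1
        assert split.outer.sum() == split.inner.sum() == 2

    def test_single_ring_warns(self):
        labels = np.zeros((3, 3), dtype=np.int32)
        labels[1, 1] = 1
        with pytest.warns(RuntimeWarning):
            split = equal_pixel_split(RingLabels(labels=labels))
        assert split.inner.sum() == 0


class TestDecomposition:
    def test_sign_convention(self, disk200):
        inward = centripetal_field(disk200)
        tp, _ = decompose_traction(inward, disk200)
        rim = ring_labels(disk200).labels == 1
        assert np.all(tp[rim] > 0)  # toward the interior: positive
        outward = VectorField2D(tx=-inward.tx, ty=-inward.ty)
        tp_out, _ = decompose_traction(outward, disk200)
        assert np.all(tp_out[rim] < 0)

    def test_tangent_field_has_zero_perpendicular(self, disk200):
        nx, ny = inward_normals(disk200)
        tangent = VectorField2D(tx=-ny, ty=nx)
        tp, tl = decompose_traction(tangent, disk200)
        fg = disk200.data
        assert np.abs(tp[fg]).max() < 1e-12
        assert np.allclose(np.abs(tl[fg]), 1.0)

    def test_norm_preservation(self, disk200, rng):
        field = VectorField2D(
            tx=rng.normal(size=disk200.data.shape), ty=rng.normal(size=disk200.data.shape)
        )
        tp, tl = decompose_traction(field, disk200)
        fg = disk200.data
        mag2 = field.tx[fg] ** 2 + field.ty[fg] ** 2
        assert np.abs(tp[fg] ** 2 + tl[fg] ** 2 - mag2).max() <= 1e-10 * mag2.max()

    def test_shape_mismatch(self, disk200):
        with pytest.raises(ValueError):
            decompose_traction(
                VectorField2D(tx=np.zeros((3, 3)), ty=np.zeros((3, 3))), disk200
            )


class TestKymograph:
    def test_uniform_field_uniform_column(self, disk200):
        rl = ring_labels(disk200)
        tp = np.where(disk200.data, 2.5, 0.0)
        ky = ring_kymograph([tp], [rl])
        col = ky.data[:, 0]
        assert np.allclose(col[np.isfinite(col)], 2.5)
        assert ky.edge_trace[0] == rl.n_rings

    def test_zero_field(self, disk200):
        rl = ring_labels(disk200)
        ky = ring_kymograph([np.zeros(disk200.data.shape)], [rl])
        assert np.nanmax(np.abs(ky.data)) == 0.0

    def test_rim_peaked_field_peaks_at_ring_one(self, disk200):
        rl = ring_labels(disk200)
        d = ndimage.distance_transform_edt(disk200.data)
        tp = np.where(disk200.data, np.exp(-d / 10.0), 0.0)
        ky = ring_kymograph([tp], [rl])
        assert np.nanargmax(ky.data[:, 0]) == 0  # ring 1

    def test_frame_mismatch(self, disk200):
        rl = ring_labels(disk200)
        with pytest.raises(ValueError):
            ring_kymograph([np.zeros((3, 3))], [rl])
        with pytest.raises(ValueError):
            ring_kymograph([np.zeros(disk200.data.shape)], [])


class TestSubdomainStats:
    def test_uniform_field_equal_domains(self, disk200):
        field = VectorField2D(
            tx=np.where(disk200.data, 3.0, 0.0), ty=np.zeros(disk200.data.shape)
        )
        df = subdomain_timeseries([field], [disk200])
        med = df.set_index("domain")["median_mag"]
        assert med["whole"] == med["outer"] == med["inner"] == pytest.approx(3.0)

    def test_rim_peaked_outer_exceeds_inner(self, disk200):
        d = ndimage.distance_transform_edt(disk200.data)
        m = np.where(disk200.data, np.exp(-d / 20.0), 0.0)
        field = VectorField2D(tx=m, ty=np.zeros_like(m))
        df = subdomain_timeseries([field], [disk200])
        med = df.set_index("domain")["median_mag"]
        assert med["outer"] > med["inner"]
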