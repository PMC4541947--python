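import numpy as np
import pytest

from fearsense.geometry import BilinearTransform, Point2D, Rect, apply_transform
from fearsense.synthetic import default_face_features, gen_face_scene
from fearsense.thermal_face import (
    ROI_NAMES,
    FacialFeatureSet,
    NostrilDetectionError,
    ROIConfig,
    ThermalFrame,
    define_rois,
    detect_nostrils,
    map_rois_to_thermal,
    read_features,
    roi_temperature,
    session_ft,
    write_features,
)

from conftest import random_transform


def _flip_features(f: FacialFeatureSet, width: float) -> FacialFeatureSet:
    def fx(p: Point2D) -> Point2D:
        return Point2D(width - p.x, p.y)

    def frect(r: Rect) -> Rect:
        return Rect(width - r.x1, r.y0, width - r.x0, r.y1)

    nostrils = None
    if f.nostrils:
        a, b = (fx(f.nostrils[1]), fx(f.nostrils[0]))
        nostrils = (a, b)
    return FacialFeatureSet(
        face_box=frect(f.face_box),
        left_eye=fx(f.right_eye),
        right_eye=fx(f.left_eye),
        nose_box=frect(f.nose_box),
        nostrils=nostrils,
    )


class TestNostrils:
    def test_synthetic_nostrils_recovered(self, face_features):
        vis, _, _ = gen_face_scene(face_features, roi_levels={})
        (left, right), center = detect_nostrils(vis, face_features.nose_box)
        nl, nr = face_features.nostrils
        assert abs(left.x - nl.x) < 1 and abs(left.y - nl.y) < 1
        assert abs(right.x - nr.x) < 1 and abs(right.y - nr.y) < 1
        assert center.x == pytest.approx((left.x + right.x) / 2)

    def test_uniform_patch_fails(self):
        with pytest.raises(NostrilDetectionError):
            detect_nostrils(np.full((100, 100), 200.0), Rect(10, 10, 90, 90))

    def test_symmetric_blobs_give_central_nose_center(self):
        img = np.full((60, 80), 200.0)
        img[28:33, 30:35] = 10.0
        img[28:33, 45:50] = 10.0
        _, center = detect_nostrils(img, Rect(0, 0, 80, 60))
        assert center.x == pytest.approx(39.5)
        assert center.y == pytest.approx(30.0)


class TestDefineRois:
    def test_five_named_regions(self, face_features):
        rois = define_rois(face_features)
        assert set(dict(rois.items())) == set(ROI_NAMES)

    def test_mirror_symmetry(self, face_features):
        """A horizontally flipped face yields the mirrored region layout."""
        width = 320.0
        rois = define_rois(face_features)
        flipped = define_rois(_flip_features(face_features, width))
        mirror_of = {"left_eye": "right_eye", "right_eye": "left_eye",
                     "left_cheek": "right_cheek", "right_cheek": "left_cheek",
                     "middle_forehead": "middle_forehead"}
        for name, twin in mirror_of.items():
            a, b = rois[name], flipped[twin]
            assert b.x0 == pytest.approx(width - a.x1)
            assert b.x1 == pytest.approx(width - a.x0)
            assert (b.y0, b.y1) == pytest.approx((a.y0, a.y1))

    def test_scale_equivariance(self, face_features):
        f = face_features
        scaled = FacialFeatureSet(
            face_box=Rect(2 * f.face_box.x0, 2 * f.face_box.y0, 2 * f.face_box.x1, 2 * f.face_box.y1),
            left_eye=Point2D(2 * f.left_eye.x, 2 * f.left_eye.y),
            right_eye=Point2D(2 * f.right_eye.x, 2 * f.right_eye.y),
            nose_box=Rect(2 * f.nose_box.x0, 2 * f.nose_box.y0, 2 * f.nose_box.x1, 2 * f.nose_box.y1),
            nostrils=tuple(Point2D(2 * p.x, 2 * p.y) for p in f.nostrils),
        )
        for name in ROI_NAMES:
            a, b = define_rois(f)[name], define_rois(scaled)[name]
            assert (b.x0, b.y0, b.x1, b.y1) == pytest.approx(
                (2 * a.x0, 2 * a.y0, 2 * a.x1, 2 * a.y1)
            )

    def test_deterministic(self, face_features):
        a, b = define_rois(face_features), define_rois(face_features)
        assert dict(a.items()) == dict(b.items())

    def test_coincident_eyes_rejected(self, face_features):
        f = face_features
        with pytest.raises(ValueError):
            define_rois(
                FacialFeatureSet(
                    face_box=f.face_box,
                    left_eye=f.left_eye,
                    right_eye=f.left_eye,
                    nose_box=f.nose_box,
                )
            )


class TestMapRois:
    def test_identity_keeps_rois(self, face_features):
        rois = define_rois(face_features)
        mapped = map_rois_to_thermal(rois, BilinearTransform.identity(), (320, 240))
        for name in ROI_NAMES:
            a, b = rois[name], mapped[name]
            assert (b.x0, b.y0, b.x1, b.y1) == pytest.approx(
                (max(a.x0, 0), max(a.y0, 0), min(a.x1, 320), min(a.y1, 240))
            )

    def test_translation_shifts_uniformly(self, face_features):
        rois = define_rois(face_features)
        t = BilinearTransform(1, 0, 0, 7.0, 0, 1, 0, -3.0)
        mapped = map_rois_to_thermal(rois, t, (1000, 1000))
        for name in ROI_NAMES:
            a, b = rois[name], mapped[name]
            assert (b.x0 - a.x0, b.y0 - a.y0) == pytest.approx((7.0, -3.0))

    def test_mapped_box_contains_all_corner_images(self, face_features, rng):
        rois = define_rois(face_features)
        t = random_transform(rng)
        mapped = map_rois_to_thermal(rois, t, (10_000, 10_000))
        for name in ROI_NAMES:
            box = mapped[name]
            for corner in rois[name].corners():
                img = apply_transform(t, corner)
                assert box.x0 - 1e-9 <= img.x <= box.x1 + 1e-9
                assert box.y0 - 1e-9 <= img.y <= box.y1 + 1e-9

    def test_all_outside_rejected(self, face_features):
        rois = define_rois(face_features)
        push_out = BilinearTransform(1, 0, 0, 5000.0, 0, 1, 0, 5000.0)
        with pytest.raises(ValueError):
            map_rois_to_thermal(rois, push_out, (320, 240))


class TestRoiTemperature:
    def test_uniform_frame(self):
        frame = ThermalFrame(counts=np.full((60, 80), 15000.0))
        assert roi_temperature(frame, Rect(5, 5, 25, 25)) == 15000.0

    def test_even_split(self):
        counts = np.full((40, 40), 15000.0)
        counts[:, 20:] = 15100.0
        frame = ThermalFrame(counts=counts)
        assert roi_temperature(frame, Rect(10, 10, 30, 30)) == pytest.approx(15050.0)

    def test_matches_pixel_loop(self, rng):
        counts = rng.uniform(14000, 16000, (50, 70))
        frame = ThermalFrame(counts=counts)
        roi = Rect(3, 7, 48, 31)
        acc = [counts[y, x] for y in range(7, 31) for x in range(3, 48)]
        assert roi_temperature(frame, roi) == pytest.approx(np.mean(acc), rel=1e-15)

    def test_empty_roi_rejected(self):
        frame = ThermalFrame(counts=np.full((10, 10), 100.0))
        with pytest.raises(ValueError):
            roi_temperature(frame, Rect(20, 20, 30, 30))


class TestSessionFT:
    LEVELS = {
        "middle_forehead": 15101.0,
        "left_eye": 15119.0,
        "right_eye": 15112.0,
        "left_cheek": 15105.0,
        "right_cheek": 15116.71,
    }

    def test_constant_fields_recovered_exactly(self, face_features):
        _, frame, truth = gen_face_scene(face_features, roi_levels=self.LEVELS)
        result = session_ft([frame], truth["rois"])
        for name, level in self.LEVELS.items():
            assert result.per_roi_mean[name] == pytest.approx(level, abs=1e-9)
        assert result.all_regions_mean == pytest.approx(np.mean(list(self.LEVELS.values())))

    def test_translation_equivariance(self, face_features):
        """Lowering every pixel by k lowers every reported mean by exactly k."""
        _, frame, truth = gen_face_scene(face_features, roi_levels=self.LEVELS)
        shifted = ThermalFrame(counts=frame.counts - 50.0)
        base = session_ft([frame], truth["rois"])
        moved = session_ft([shifted], truth["rois"])
        for name in ROI_NAMES:
            assert moved.per_roi_mean[name] == pytest.approx(
                base.per_roi_mean[name] - 50.0, abs=1e-9
            )
        assert moved.all_regions_mean == pytest.approx(base.all_regions_mean - 50.0)

    def test_noisy_session_recovers_commanded_levels(self, face_features):
        """Session means over noisy frames land within 3 SE of the commanded levels."""
        noise_sd = 8.0
        frames, rois = [], None
        for seed in range(12):
            _, frame, truth = gen_face_scene(
                face_features, roi_levels=self.LEVELS, noise_sd=noise_sd, seed=seed
            )
            frames.append(frame)
            rois = truth["rois"]
        result = session_ft(frames, rois)
        for name, level in self.LEVELS.items():
            rows, cols = rois[name].to_slices()
            n_px = (rows.stop - rows.start) * (cols.stop - cols.start) * len(frames)
            se = noise_sd / np.sqrt(n_px)
            assert abs(result.per_roi_mean[name] - level) < 3 * se

    def test_no_frames_rejected(self, face_features):
        with pytest.raises(ValueError):
            session_ft([], define_rois(face_features))


def test_feature_file_round_trip(tmp_path, face_features):
    path = tmp_path / "features.csv"
    write_features(path, face_features)
    loaded = read_features(path)
    assert loaded.left_eye == face_features.left_eye
    assert loaded.nose_box == face_features.nose_box
    assert loaded.nostrils == face_features.nostrils


def test_thermal_frame_validates_count_range():
    with pytest.raises(ValueError):
        ThermalFrame(counts=np.full((4, 4), 20000.0))
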