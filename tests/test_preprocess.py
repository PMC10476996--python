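import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oarsort.preprocess import (
    ClassifierSample,
    DegenerateVolumeError,
    OversizeInputError,
    PreprocessConfig,
    assemble_sample,
    center_window,
    crop_to_body,
    extract_window,
    get_profile,
    load_config,
    make_addmap,
    mask_outside_body,
    pad_or_downscale,
    resample,
    slice_eligibility,
    zscore_normalize,
)
from oarsort.rtstruct_io import ImageVolume, NamedStructure, find_body


def vol(arr, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(arr, dtype=float), spacing)


class TestZScore:
    def test_hand_computed_example(self):
        # stats only from {0, 100}: mu=50, sigma=50 -> [-21, -1, 1]
        v = vol(np.array([-1000.0, 0.0, 100.0]).reshape(3, 1, 1))
        out = zscore_normalize(v, air_threshold=-1000.0)
        np.testing.assert_allclose(
            out.voxels.ravel(), [-21.0, -1.0, 1.0], atol=1e-12
        )

    def test_identity_when_already_normalized(self, rng):
        data = rng.normal(0.0, 1.0, size=(4, 5, 6))
        data -= data.mean()
        data /= data.std()
        out = zscore_normalize(vol(data), air_threshold=-1000.0)
        np.testing.assert_allclose(out.voxels, data, atol=1e-12)

    def test_all_air_is_degenerate(self):
        v = vol(np.full((3, 3, 3), -1000.0))
        with pytest.raises(DegenerateVolumeError):
            zscore_normalize(v, air_threshold=-1000.0)

    def test_constant_above_threshold_degenerate(self):
        v = vol(np.full((3, 3, 3), 40.0))
        with pytest.raises(DegenerateVolumeError):
            zscore_normalize(v, air_threshold=-1000.0)

    def test_population_std_used(self):
        v = vol(np.array([0.0, 2.0]).reshape(2, 1, 1))
        out = zscore_normalize(v, air_threshold=-1000.0)
        # population sigma = 1 exactly (sample sigma would be sqrt(2))
        np.testing.assert_allclose(out.voxels.ravel(), [-1.0, 1.0])


class TestResample:
    def test_mask_stays_binary(self, rng):
        mask = (rng.random((10, 12, 14)) > 0.6).astype(np.uint8)
        out = resample(
            ImageVolume(mask, (2.5, 1.0, 1.0)), (3.0, 2.0, 2.0), mode="mask"
        )
        assert set(np.unique(out.voxels)) <= {0, 1}

    def test_identity_spacing(self, rng):
        data = rng.normal(size=(6, 6, 6))
        out = resample(vol(data, (2, 2, 2)), (2, 2, 2), mode="intensity")
        np.testing.assert_array_equal(out.voxels, data)

    def test_constant_volume_stays_constant(self):
        out = resample(
            vol(np.full((8, 8, 8), 7.0), (1, 1, 1)), (2.0, 2.0, 2.0),
            mode="intensity",
        )
        np.testing.assert_allclose(out.voxels, 7.0, atol=1e-5)

    def test_extent_preserved_within_one_voxel(self):
        out = resample(
            vol(np.zeros((30, 40, 50)), (2.0, 1.0, 1.0)), (3.0, 2.0, 2.0),
            mode="intensity",
        )
        for n_out, n_in, s_in, s_out in zip(
            out.shape, (30, 40, 50), (2.0, 1.0, 1.0), (3.0, 2.0, 2.0)
        ):
            assert abs(n_out * s_out - n_in * s_in) <= s_out

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            resample(vol(np.zeros((2, 2, 2))), (1, 1, 1), mode="cubic")


class TestBodyMaskingAndCrop:
    def test_couch_removed(self):
        data = np.zeros((4, 6, 6))
        data[:, 5, :] = 200.0  # couch-like slab
        body = np.zeros((4, 6, 6), dtype=np.uint8)
        body[:, 1:4, 1:4] = 1
        data[body > 0] = 1.5
        out = mask_outside_body(vol(data), NamedStructure("BODY", body))
        assert np.all(out.voxels[:, 5, :] == 0.0)
        assert np.all(out.voxels[body > 0] == 1.5)

    def test_full_body_is_identity(self, rng):
        data = rng.normal(size=(3, 4, 5))
        body = NamedStructure("BODY", np.ones((3, 4, 5), dtype=np.uint8))
        np.testing.assert_array_equal(
            mask_outside_body(vol(data), body).voxels, data
        )

    def test_empty_body_fatal(self):
        body = NamedStructure("BODY", np.zeros((2, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            mask_outside_body(vol(np.zeros((2, 2, 2))), body)

    def test_crop_matches_bounding_box(self):
        body = np.zeros((10, 10, 10), dtype=np.uint8)
        body[2:7, 3:9, 1:5] = 1
        out = crop_to_body(vol(np.ones((10, 10, 10))), NamedStructure("b", body))
        assert out.shape == (5, 6, 4)

    def test_crop_idempotent(self, rng):
        body = np.zeros((8, 8, 8), dtype=np.uint8)
        body[1:5, 2:6, 3:7] = 1
        v = vol(rng.normal(size=(8, 8, 8)))
        once = crop_to_body(v, NamedStructure("b", body))
        body2 = NamedStructure("b", body[1:5, 2:6, 3:7])
        twice = crop_to_body(once, body2)
        np.testing.assert_array_equal(once.voxels, twice.voxels)


class TestAddMap:
    def test_three_levels(self):
        body = np.zeros((4, 4, 4), dtype=np.uint8)
        body[1:3, 1:3, 1:3] = 1
        struct = np.zeros((4, 4, 4), dtype=np.uint8)
        struct[1, 1, 1] = 1
        am = make_addmap(body, struct)
        assert am[1, 1, 1] == 1.0       # overlap
        assert am[2, 2, 2] == 0.5       # body only
        assert am[0, 0, 0] == 0.0       # background
        assert set(np.unique(am)) == {0.0, 0.5, 1.0}

    def test_non_binary_fatal(self):
        with pytest.raises(ValueError):
            make_addmap(np.full((2, 2, 2), 2), np.zeros((2, 2, 2)))

    def test_structure_outside_body_warns(self, caplog):
        body = np.zeros((3, 3, 3), dtype=np.uint8)
        body[1, 1, 1] = 1
        struct = np.zeros((3, 3, 3), dtype=np.uint8)
        struct[0, 0, 0] = 1
        with caplog.at_level("WARNING", logger="oarsort.preprocess"):
            am = make_addmap(body, struct)
        assert am[0, 0, 0] == 0.5
        assert any("outside the body" in r.message for r in caplog.records)


def mask_with_slices(nonzero, total=200):
    m = np.zeros((total, 4, 4), dtype=np.uint8)
    for k in nonzero:
        m[k, 2, 2] = 1
    return m


class TestEligibilityAndWindow:
    def test_eligibility_boundary(self):
        assert slice_eligibility(mask_with_slices(range(96)), 96) is True
        assert slice_eligibility(mask_with_slices(range(97)), 96) is False

    def test_scattered_slices_counted_not_extent(self):
        # 3 nonzero slices spread over 150 -> count is what matters
        assert slice_eligibility(mask_with_slices([0, 70, 140]), 96) is True

    def test_window_hand_example(self):
        # nonzero slices 40..60, cap 96 -> center 50 -> [2, 98)
        m = mask_with_slices(range(40, 61))
        assert center_window(m, 96, 200) == (2, 98)

    def test_symmetric_structure_centered(self):
        m = mask_with_slices(range(90, 111))
        start, end = center_window(m, 20, 200)
        assert (start + end) / 2 == 100

    def test_edge_window_zero_filled_and_contains_structure(self):
        m = mask_with_slices(range(0, 5), total=30)
        window = center_window(m, 20, 30)
        assert window[0] < 0  # extends beyond the inferior edge
        out = extract_window(m, window)
        assert out.shape[0] == 20
        assert out.sum() == m.sum()  # every nonzero slice retained

    @given(
        first=st.integers(0, 50),
        extent=st.integers(1, 24),
        cap=st.integers(24, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_window_containment_property(self, first, extent, cap):
        m = mask_with_slices(range(first, first + extent), total=80)
        start, end = center_window(m, cap, 80)
        assert end - start == cap
        assert start <= first and first + extent <= end
        out = extract_window(m, (start, end))
        assert out.sum() == m.sum()


class TestPadOrDownscale:
    def test_symmetric_pad_example(self):
        out = pad_or_downscale(np.ones((96, 150, 250)), (96, 184, 280))
        assert out.shape == (96, 184, 280)
        # rows: 34 extra -> 17/17; cols: 30 extra -> 15/15
        assert np.all(out[:, :17] == 0) and np.all(out[:, -17:] == 0)
        assert np.all(out[:, :, :15] == 0) and np.all(out[:, :, -15:] == 0)
        assert np.all(out[:, 17:-17, 15:-15] == 1)

    def test_odd_remainder_high_side(self):
        out = pad_or_downscale(np.ones((2, 3, 3)), (2, 4, 3))
        assert np.all(out[:, 0] == 1) or np.all(out[:, -1] == 0)
        # 1 extra row -> 0 low, 1 high
        assert np.all(out[:, 3] == 0)
        assert np.all(out[:, :3] == 1)

    def test_identity_when_target_size(self, rng):
        x = rng.normal(size=(4, 5, 6))
        np.testing.assert_array_equal(pad_or_downscale(x, (4, 5, 6)), x)

    def test_oversize_without_downscale_fatal(self):
        with pytest.raises(OversizeInputError):
            pad_or_downscale(np.ones((96, 220, 340)), (96, 200, 328))

    def test_oversize_with_downscale(self):
        out = pad_or_downscale(
            np.ones((96, 220, 340)), (96, 200, 328), allow_downscale=True
        )
        assert out.shape == (96, 200, 328)

    def test_downscale_preserves_addmap_codomain(self, rng):
        x = rng.choice([0.0, 0.5, 1.0], size=(10, 60, 70))
        out = pad_or_downscale(x, (10, 50, 64), allow_downscale=True)
        assert set(np.unique(out)) <= {0.0, 0.5, 1.0}


class TestProfilesAndConfig:
    def test_grid_slices_must_match_cap(self):
        with pytest.raises(ValueError):
            PreprocessConfig("x", grid=(10, 10, 50), slice_cap=96)

    def test_bowel_profile_values(self):
        cfg = get_profile("bowel")
        assert cfg.grid == (184, 280, 96)
        assert cfg.spacing == (3.0, 2.0, 2.0)
        assert cfg.supported_extent_mm == 288.0

    def test_pelvis_profile_values(self):
        assert get_profile("pelvis").grid == (200, 328, 96)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "profiles.yaml"
        path.write_text(
            "custom:\n  grid: [100, 120, 48]\n  slice_cap: 48\n"
            "  spacing: [3.0, 2.0, 2.0]\n  allow_downscale: true\n"
        )
        cfg = load_config(path, "custom")
        assert cfg.grid == (100, 120, 48)
        assert cfg.allow_downscale is True


class TestAssembleSample:
    def test_full_chain_on_phantom(self, phantom):
        ct, sset, labels = phantom
        body = find_body(sset)
        cfg = get_profile("phantom")
        struct = next(s for s in sset if s.name == "Bladder")
        sample = assemble_sample(ct, body, struct, cfg, label="Bladder")
        assert sample.ct.shape == cfg.grid_src
        assert set(np.unique(sample.addmap)) <= {0.0, 0.5, 1.0}
        assert sample.label == "Bladder"

    def test_different_structures_get_different_windows(self, phantom):
        ct, sset, labels = phantom
        body = find_body(sset)
        cfg = get_profile("phantom")
        by_name = {s.name: s for s in sset}
        s1 = assemble_sample(ct, body, by_name["Bladder"], cfg)
        s2 = assemble_sample(ct, body, by_name["Dose_ctrl"], cfg)
        assert not np.array_equal(s1.ct, s2.ct)

    def test_oversize_structure_skipped(self, phantom):
        ct, sset, labels = phantom
        body = find_body(sset)
        cfg = get_profile("phantom")
        tall = NamedStructure("tall", body.mask.copy())
        assert assemble_sample(ct, body, tall, cfg) is None

    def test_determinism(self, phantom):
        ct, sset, labels = phantom
        body = find_body(sset)
        cfg = get_profile("phantom")
        struct = next(s for s in sset if s.name == "Rectum")
        a = assemble_sample(ct, body, struct, cfg)
        b = assemble_sample(ct, body, struct, cfg)
        np.testing.assert_array_equal(a.ct, b.ct)
        np.testing.assert_array_equal(a.addmap, b.addmap)

    def test_sample_persistence_round_trip(self, phantom, tmp_path):
        from oarsort.preprocess import load_sample, save_sample

        ct, sset, labels = phantom
        body = find_body(sset)
        cfg = get_profile("phantom")
        struct = next(s for s in sset if s.name == "Bladder")
        sample = assemble_sample(ct, body, struct, cfg, label="Bladder",
                                 patient_id="fix01")
        save_sample(sample, tmp_path / "s1")
        loaded = load_sample(tmp_path / "s1")
        np.testing.assert_array_equal(loaded.ct, sample.ct.astype(np.float32))
        np.testing.assert_array_equal(loaded.addmap, sample.addmap)
        assert loaded.label == "Bladder" and loaded.patient_id == "fix01"

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSample(
                ct=np.zeros((2, 2, 2)), addmap=np.zeros((3, 2, 2)),
                structure_name="x",
            )
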