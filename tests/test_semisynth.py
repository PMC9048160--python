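"""Semi-synthetic combination rules and dataset assembly."""

import json

import numpy as np
import pytest

from panev.core import ConfigError, RFFrame, read_image
from panev.semisynth import (SemisynthConfig, build_dataset, check_no_leakage,
                             combine_rf, normalize_needle_rf,
                             shaft_reaches_light, split_sizes)


@pytest.fixture()
def frames(probe, rng):
    needle = RFFrame(samples=0.2 * rng.standard_normal((1024, 128)),
                     fs_mhz=40.0, probe=probe)
    ref = RFFrame(samples=rng.standard_normal((1024, 128)), fs_mhz=40.0,
                  probe=probe)
    return needle, ref


class TestNormalize:
    def test_max_amplitude_matches_reference(self, frames):
        needle, ref = frames
        out = normalize_needle_rf(needle, ref, kappa=1.0)
        assert np.abs(out.samples).max() == pytest.approx(
            np.abs(ref.samples).max())

    def test_kappa_scales_linearly(self, frames):
        needle, ref = frames
        out = normalize_needle_rf(needle, ref, kappa=0.5)
        assert np.abs(out.samples).max() == pytest.approx(
            0.5 * np.abs(ref.samples).max())

    def test_waveform_shape_preserved(self, frames):
        needle, ref = frames
        out = normalize_needle_rf(needle, ref)
        nz = needle.samples != 0
        ratio = out.samples[nz] / needle.samples[nz]
        assert np.allclose(ratio, ratio.flat[0])

    def test_zero_inputs_rejected(self, frames, probe):
        needle, ref = frames
        zero = RFFrame(samples=np.zeros((1024, 128)), fs_mhz=40.0, probe=probe)
        with pytest.raises(ConfigError):
            normalize_needle_rf(zero, ref)
        with pytest.raises(ConfigError):
            normalize_needle_rf(needle, zero)


class TestCombine:
    def test_sum_with_leading_rows_zeroed(self, frames):
        needle, ref = frames
        out = combine_rf(needle, ref, zero_n=150)
        assert not out.samples[:150].any()
        assert np.allclose(out.samples[150],
                           needle.samples[150] + ref.samples[150])

    def test_zero_n_zero_is_plain_sum(self, frames, probe):
        needle, _ = frames
        zero = RFFrame(samples=np.zeros((1024, 128)), fs_mhz=40.0, probe=probe)
        out = combine_rf(needle, zero, zero_n=0)
        assert np.array_equal(out.samples, needle.samples)

    def test_commutative(self, frames):
        needle, ref = frames
        ab = combine_rf(needle, ref, 150).samples
        ba = combine_rf(ref, needle, 150).samples
        assert np.array_equal(ab, ba)

    def test_shape_mismatch_rejected(self, frames, probe):
        needle, _ = frames
        wide = RFFrame(samples=np.zeros((3072, 128)), fs_mhz=120.0, probe=probe)
        with pytest.raises(ConfigError):
            combine_rf(needle, wide, 150)


class TestSplits:
    @pytest.mark.parametrize("n,expected", [
        (10, (8, 1, 1)), (2000, (1600, 200, 200)), (7, (5, 1, 1)),
    ])
    def test_split_sizes(self, n, expected):
        assert split_sizes(n, (0.8, 0.1, 0.1)) == expected

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SemisynthConfig(split=(0.8, 0.1, 0.2))


class TestPoseFeasibility:
    def test_shallow_angle_deep_tip_is_dark(self, grid):
        assert not shaft_reaches_light(25.0, 20.0, 5.0, grid)

    def test_steep_or_shallow_poses_are_lit(self, grid):
        assert shaft_reaches_light(5.0, 20.0, 5.0, grid)
        assert shaft_reaches_light(25.0, 45.0, 5.0, grid)


class TestBuildDataset:
    @pytest.fixture(scope="class")
    def built(self, probe, grid, tmp_path_factory):
        out = tmp_path_factory.mktemp("dataset")
        cfg = SemisynthConfig(size=10, n_backgrounds=2)
        manifest = build_dataset(cfg, probe, grid, out, seed=3,
                                 n_photons=3_000,
                                 depths_mm=(5.0, 10.0), angles_deg=(30.0, 45.0))
        return out, manifest

    def test_manifest_counts_and_splits(self, built):
        _, manifest = built
        assert len(manifest.entries) == 10
        assert manifest.split_counts() == {"train": 8, "val": 1, "test": 1}

    def test_pairs_materialised_and_normalised(self, built):
        out, manifest = built
        for entry in manifest.entries[:4]:
            img = read_image(out / entry.input_path)
            target = read_image(out / entry.target_path)
            assert img.shape == (128, 128) and target.shape == (128, 128)
            assert img.pixels.max() == pytest.approx(1.0)
            assert target.kind == "ground-truth"
            assert 0 <= target.pixels.min() and target.pixels.max() <= 1.0
            # needle targets are sparse line fragments, not dense scenes
            assert (target.pixels > 0.05).mean() < 0.1

    def test_no_pose_background_leakage(self, built):
        _, manifest = built
        assert check_no_leakage(manifest)

    def test_manifest_determinism(self, probe, grid, tmp_path):
        kw = dict(probe=probe, grid=grid, seed=9, materialise=False)
        cfg = SemisynthConfig(size=40, n_backgrounds=3)
        m1 = build_dataset(cfg, out_dir=tmp_path / "a", **kw)
        m2 = build_dataset(cfg, out_dir=tmp_path / "b", **kw)
        j1 = json.loads((tmp_path / "a" / "manifest.json").read_text())
        j2 = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert j1 == j2
        m3 = build_dataset(cfg, out_dir=tmp_path / "c", probe=probe, grid=grid,
                           seed=10, materialise=False)
        assert ([e.split for e in m1.entries] != [e.split for e in m3.entries]
                or [e.background_id for e in m1.entries]
                != [e.background_id for e in m3.entries])

    def test_poses_all_reach_light(self, probe, grid, tmp_path):
        cfg = SemisynthConfig(size=60, n_backgrounds=2)
        manifest = build_dataset(cfg, probe, grid, tmp_path, seed=1,
                                 materialise=False)
        for e in manifest.entries:
            pose = e.needle_pose
            assert shaft_reaches_light(pose["tip_depth_mm"], pose["angle_deg"],
                                       pose["tip_x_mm"], grid)
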