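"""Synthetic scene generator: kinematics, rasterization, rendering, video."""

import numpy as np
import pytest

from holopol.errors import GeometryError, SamplingError
from holopol.polarimetry import dolp_map, split_mosaic, stokes_maps
from holopol.scene import (
    DEFAULT_MATERIALS,
    FlowSpec,
    MaterialSpec,
    NoiseSpec,
    OpticalConfig,
    ParticleSpec,
    SceneSpec,
    make_particle_fields,
    mean_flow_speed,
    mosaic_sample,
    render_polarized_hologram,
    render_video,
)

from conftest import oracle_channels

PITCH = OpticalConfig().object_pixel_pitch


def bead(r_px, center_px=(32, 32), material=None, theta=0.3, kind="bead"):
    material = material or DEFAULT_MATERIALS["PET"]
    return ParticleSpec(
        kind, 2 * r_px * PITCH, (center_px[1] * PITCH, center_px[0] * PITCH), theta, material
    )


class TestFlow:
    @pytest.mark.parametrize(
        "rate,expect", [(8.0, 8000 / 60 / 50), (0.0, 0.0), (15.0, 5.0)]
    )
    def test_mean_speed_from_volume_rate(self, rate, expect):
        assert mean_flow_speed(FlowSpec(volume_flow_rate=rate)) == pytest.approx(expect)
        if rate == 8.0:
            assert mean_flow_speed(FlowSpec()) == pytest.approx(2.6667, abs=1e-4)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            mean_flow_speed(FlowSpec(channel_inner_thickness=0.0))

    def test_pump_range_validation(self):
        FlowSpec(volume_flow_rate=8).validate_pump_range()
        with pytest.raises(ValueError):
            FlowSpec(volume_flow_rate=20).validate_pump_range()


class TestOpticalConfig:
    def test_channel_pitch_is_twice_physical(self):
        c = OpticalConfig()
        assert c.channel_pitch == 2 * c.physical_pixel_pitch
        assert c.channel_shape == (1028, 1232)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            OpticalConfig(wavelength=-1)
        with pytest.raises(ValueError):
            OpticalConfig(mosaic_shape=(5, 8))


class TestMaterials:
    def test_glass_is_the_zero_retardance_control(self):
        assert DEFAULT_MATERIALS["glass"].retardance_mean == 0
        with pytest.raises(ValueError):
            MaterialSpec("glass", 0.3)

    def test_validation(self):
        with pytest.raises(ValueError):
            MaterialSpec("PC", 0.5, retardance_sd=-0.1)
        with pytest.raises(ValueError):
            MaterialSpec("unobtainium", 0.5)


class TestParticleFields:
    def test_bead_mask_is_a_disk(self):
        r = 10
        mask, *_ = make_particle_fields(bead(r), (64, 64), PITCH, seed=1)
        assert abs(mask.sum() - np.pi * r**2) <= 4 * r

    def test_glass_particle_has_zero_retardance_map(self):
        p = bead(8, material=DEFAULT_MATERIALS["glass"])
        mask, dmap, _, tmap = make_particle_fields(p, (64, 64), PITCH, seed=2)
        assert np.all(dmap == 0)
        assert np.all(tmap[~mask] == 1.0)

    def test_outside_support_is_neutral(self):
        mask, dmap, thmap, tmap = make_particle_fields(bead(6), (64, 64), PITCH, seed=3)
        assert np.all(dmap[~mask] == 0) and np.all(tmap[~mask] == 1)

    def test_same_seed_reproduces_identical_maps(self):
        for kind in ("bead", "fragment", "foam", "fiber", "film", "pellet"):
            p = bead(9, kind=kind)
            a = make_particle_fields(p, (64, 64), PITCH, seed=7)
            b = make_particle_fields(p, (64, 64), PITCH, seed=7)
            for x, y in zip(a, b):
                assert np.array_equal(x, y)

    def test_oversized_particle_rejected(self):
        with pytest.raises(GeometryError):
            make_particle_fields(bead(40), (64, 64), PITCH, seed=1)
        with pytest.raises(GeometryError):
            make_particle_fields(bead(10, center_px=(2, 2)), (64, 64), PITCH, seed=1)


class TestRender:
    def test_empty_scene_channels_at_half_intensity(self, cfg):
        stack, truth = render_polarized_hologram(SceneSpec((), (32, 32), NoiseSpec(), 0), cfg)
        for ch in (stack.I0, stack.I45, stack.I90, stack.I135):
            assert np.allclose(ch, 0.5, atol=1e-9)
        assert truth.count == 0

    def test_single_bead_scene_has_fringes_and_truth(self, cfg):
        stack, truth = render_polarized_hologram(
            SceneSpec((bead(8),), (64, 64), NoiseSpec(), 1), cfg, z=2e-3
        )
        assert truth.count == 1
        assert truth.records[0].area_px > 0
        total = stack.I0 + stack.I90
        assert total.std() > 1e-3  # interference structure present

    @pytest.mark.parametrize("delta,theta", [(0.6, 0.0), (np.pi / 2, np.pi / 8), (1.9, 1.2)])
    def test_filled_retarder_matches_mueller_oracle(self, delta, theta):
        from holopol.scene import render_uniform_retarder

        st = render_uniform_retarder(delta, theta, (8, 8))
        ch = oracle_channels(delta, theta)
        assert np.allclose(st.I0, ch[0], atol=1e-9)
        assert np.allclose(st.I135, ch[135], atol=1e-9)
        # analytic signed form under the package's convention
        for adeg, img in ((45, st.I45), (90, st.I90)):
            a = np.deg2rad(adeg)
            assert np.allclose(img, 0.5 * (1 - np.sin(delta) * np.sin(2 * a - 2 * theta)), atol=1e-9)

    def test_determinism_bit_identical(self, cfg):
        sc = SceneSpec((bead(7),), (64, 64), NoiseSpec(0.05, 1e4, 0.01), seed=9)
        a, _ = render_polarized_hologram(sc, cfg, z=1e-3)
        b, _ = render_polarized_hologram(sc, cfg, z=1e-3)
        assert np.array_equal(a.I45, b.I45)

    def test_noiseless_energy_bounds(self, cfg):
        stack, _ = render_polarized_hologram(
            SceneSpec((bead(8),), (64, 64), NoiseSpec(), 4), cfg, z=1e-3
        )
        for ch in (stack.I0, stack.I45, stack.I90, stack.I135):
            assert ch.min() >= 0
            assert ch.max() <= 1.0 + 0.35  # diffraction overshoot stays bounded

    def test_complementarity_after_propagation(self, cfg):
        stack, _ = render_polarized_hologram(
            SceneSpec((bead(8),), (64, 64), NoiseSpec(), 4), cfg, z=2e-3
        )
        assert np.max(np.abs(stack.I0 + stack.I90 - stack.I45 - stack.I135)) < 1e-9

    def test_glass_scene_dolp_vanishes_everywhere(self, cfg):
        p = bead(10, material=DEFAULT_MATERIALS["glass"])
        stack, _ = render_polarized_hologram(SceneSpec((p,), (64, 64), NoiseSpec(), 5), cfg, z=2e-3)
        fm = dolp_map(stokes_maps(stack))
        assert np.max(fm.values) <= 1e-6

    def test_aliasing_guard(self):
        cfg = OpticalConfig()
        with pytest.raises(SamplingError):
            render_polarized_hologram(SceneSpec((bead(5),), (64, 64), NoiseSpec(), 0), cfg, z=0.5)


class TestMosaicSample:
    def test_round_trip_is_identity_noiseless(self, cfg):
        stack, _ = render_polarized_hologram(
            SceneSpec((bead(6),), (64, 64), NoiseSpec(), 2), cfg, z=1e-3
        )
        back = split_mosaic(mosaic_sample(stack), pitch=stack.pitch)
        for a, b in zip(back.channels(), stack.channels()):
            assert np.array_equal(a, b)

    def test_constant_channels_give_constant_mosaic(self):
        from holopol.polarimetry import PolarizationStack

        st = PolarizationStack(*[np.full((4, 4), 0.37)] * 4)
        assert np.all(mosaic_sample(st) == 0.37)

    def test_mosaic_doubles_resolution(self):
        from holopol.polarimetry import PolarizationStack

        st = PolarizationStack(*[np.zeros((1028, 1232))] * 4)
        assert mosaic_sample(st).shape == (2056, 2464)

    def test_noise_is_seeded(self):
        from holopol.polarimetry import PolarizationStack

        st = PolarizationStack(*[np.full((8, 8), 0.5)] * 4)
        n = NoiseSpec(0, 1e4, 0.01)
        a = mosaic_sample(st, noise=n, seed=3)
        b = mosaic_sample(st, noise=n, seed=3)
        c = mosaic_sample(st, noise=n, seed=4)
        assert np.array_equal(a, b) and not np.array_equal(a, c)


class TestVideo:
    def test_zero_flow_frames_identical(self, cfg):
        sc = SceneSpec((bead(6),), (48, 48), NoiseSpec(), 3)
        frames, _ = render_video(sc, FlowSpec(volume_flow_rate=0), 4, cfg, z=1e-3)
        for f in frames[1:]:
            assert np.array_equal(f, frames[0])

    def test_trajectory_is_collinear_with_expected_step(self, cfg):
        flow = FlowSpec(frames_per_second=30)
        sc = SceneSpec((bead(6, center_px=(12, 24)),), (48, 96), NoiseSpec(), 3)
        frames, truth = render_video(sc, flow, 5, cfg, z=1e-3)
        traj = truth.trajectories[1]
        assert len(traj) == 5
        rows = [t[1] for t in traj]
        cols = [t[2] for t in traj]
        assert np.allclose(rows, rows[0], atol=0.5)
        expected = mean_flow_speed(flow) * 1e-3 / flow.frames_per_second / cfg.object_pixel_pitch
        steps = np.diff(cols)
        assert np.all(np.abs(steps - expected) <= 0.5)

    def test_exiting_particle_is_retired_but_counted(self, cfg):
        sc = SceneSpec((bead(5, center_px=(40, 24)),), (48, 48), NoiseSpec(), 3)
        frames, truth = render_video(sc, FlowSpec(frames_per_second=10), 12, cfg, z=1e-3)
        assert truth.count == 1
        assert truth.trajectories[1][-1][0] < 11  # gone before the last frame
        assert not truth.label_masks[-1].any()

    def test_masks_are_disjoint_labels(self, cfg):
        sc = SceneSpec(
            (bead(5, center_px=(12, 12)), bead(5, center_px=(36, 30))), (48, 48), NoiseSpec(), 6
        )
        _, truth = render_video(sc, FlowSpec(), 2, cfg, z=1e-3)
        labels = truth.label_masks[0]
        assert set(np.unique(labels)) <= {0, 1, 2}

    def test_video_determinism(self, cfg):
        sc = SceneSpec((bead(5, center_px=(12, 12)),), (48, 48), NoiseSpec.mild(), 8)
        a, _ = render_video(sc, FlowSpec(), 3, cfg, z=1e-3)
        b, _ = render_video(sc, FlowSpec(), 3, cfg, z=1e-3)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
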