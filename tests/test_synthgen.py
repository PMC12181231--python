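"""Synthetic-generator contracts: schedules, scenes, time-lapses."""

import numpy as np
import pytest
from scipy import ndimage

import dropcascade as dc
from dropcascade.synthgen import NEVER, PlacementError

from conftest import make_scene_spec


class TestTransformationSchedule:
    def test_zero_rate_never_transforms(self):
        kin = dc.KineticsSpec(k_true=0.0, labile_fraction=1.0)
        times, _ = dc.sample_transformation_schedule(kin, 50, seed=1)
        assert np.all(times == NEVER)

    def test_inert_population_never_transforms(self):
        kin = dc.KineticsSpec(k_true=0.05, labile_fraction=0.0)
        times, _ = dc.sample_transformation_schedule(kin, 100, seed=2)
        assert np.all(times == NEVER)

    def test_survival_matches_closed_form(self):
        """Empirical ACC fraction at t=360 min agrees with exp(-k t) within
        3 Monte-Carlo standard errors."""
        k, n, t = 0.027, 10_000, 360.0
        kin = dc.KineticsSpec(k_true=k, labile_fraction=1.0)
        times, _ = dc.sample_transformation_schedule(kin, n, seed=3)
        p = np.exp(-k * t)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(np.mean(times > t) - p) <= 3 * se

    def test_phase_draw_follows_p_vaterite(self):
        kin = dc.KineticsSpec(p_vaterite=1.0)
        _, phases = dc.sample_transformation_schedule(kin, 200, seed=4)
        assert set(phases) == {dc.VATERITE}

    def test_deterministic_for_fixed_seed(self):
        kin = dc.KineticsSpec()
        a = dc.sample_transformation_schedule(kin, 100, seed=9)
        b = dc.sample_transformation_schedule(kin, 100, seed=9)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    @pytest.mark.parametrize("bad", [
        dict(labile_fraction=1.5), dict(p_vaterite=-0.1),
        dict(initial_transformed_fraction=1.0), dict(k_true=-1.0),
        dict(timesteps=[]), dict(timesteps=[10.0, 5.0]),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            dc.KineticsSpec(**bad)


class TestGenerateScene:
    def test_zero_droplets_gives_background_only(self):
        spec = make_scene_spec(droplets_per_frame=0)
        rgb, dm, vm, cm, truth = dc.generate_scene(spec, [], seed=0)
        assert dm.sum() == vm.sum() == cm.sum() == 0
        assert rgb.shape == (spec.image_height_px, spec.image_width_px, 3)
        assert truth.n_droplets == 0

    def test_component_counts_match_phases(self):
        spec = make_scene_spec(droplets_per_frame=3)
        rgb, dm, vm, cm, _ = dc.generate_scene(
            spec, [dc.ACC, dc.VATERITE, dc.CALCITE], seed=1)
        s8 = ndimage.generate_binary_structure(2, 2)
        assert ndimage.label(dm > 0, structure=s8)[1] == 3
        assert ndimage.label(vm > 0, structure=s8)[1] == 1
        assert ndimage.label(cm > 0, structure=s8)[1] == 1

    def test_bit_identical_for_fixed_seed(self):
        spec = make_scene_spec()
        phases = [dc.ACC] * 5 + [dc.VATERITE]
        a = dc.generate_scene(spec, phases, seed=7)
        b = dc.generate_scene(spec, phases, seed=7)
        for xa, xb in zip(a[:4], b[:4]):
            assert np.array_equal(xa, xb)

    def test_phase_list_length_enforced(self):
        with pytest.raises(ValueError, match="phase list length"):
            dc.generate_scene(make_scene_spec(), [dc.ACC], seed=0)

    def test_geometry_invariants(self):
        """Droplets fully inside the frame, pairwise non-overlapping, and
        every crystal lies strictly inside its parent droplet."""
        for seed in range(5):
            spec = make_scene_spec(droplets_per_frame=8)
            phases = [dc.VATERITE if i % 2 else dc.CALCITE for i in range(8)]
            _, dm, vm, cm, truth = dc.generate_scene(spec, phases, seed=seed)
            h, w = dm.shape
            for (r, c), rad in zip(truth.centers, truth.radii):
                assert rad <= r <= h - rad and rad <= c <= w - rad
            d = np.hypot(
                truth.centers[:, None, 0] - truth.centers[None, :, 0],
                truth.centers[:, None, 1] - truth.centers[None, :, 1])
            sep = truth.radii[:, None] + truth.radii[None, :]
            off_diag = ~np.eye(len(truth.radii), dtype=bool)
            assert np.all(d[off_diag] >= sep[off_diag])
            crystal = (vm > 0) | (cm > 0)
            assert not np.any(crystal & (dm == 0))

    def test_placement_failure_is_explicit(self):
        spec = make_scene_spec(image_height_px=64, image_width_px=64,
                               droplets_per_frame=30, droplet_radius_px=12)
        with pytest.raises(PlacementError, match="fewer or smaller"):
            dc.generate_scene(spec, [dc.ACC] * 30, seed=0)


class TestTimelapse:
    def _tiny(self, **kin_overrides):
        spec = make_scene_spec(droplets_per_frame=10)
        base = dict(k_true=0.03, labile_fraction=0.5,
                    timesteps=[0.0, 60.0, 180.0, 360.0], n_locations=3)
        base.update(kin_overrides)
        return spec, dc.KineticsSpec(**base)

    def test_zero_rate_keeps_acc_constant(self):
        spec, kin = self._tiny(k_true=0.0)
        tl = dc.generate_timelapse(spec, kin, seed=0, render=False)
        per_loc = tl.true_counts.groupby("location_id")["n_acc"].nunique()
        assert (per_loc == 1).all()

    def test_conservation_every_frame(self):
        spec, kin = self._tiny()
        tl = dc.generate_timelapse(spec, kin, seed=1, render=False)
        t = tl.true_counts
        assert (t.n_acc + t.n_vaterite_droplets + t.n_calcite_droplets
                == t.n_droplets).all()

    def test_acc_count_monotone_per_location(self):
        spec, kin = self._tiny()
        tl = dc.generate_timelapse(spec, kin, seed=2, render=False)
        for _, grp in tl.true_counts.groupby("location_id"):
            acc = grp.sort_values("timestep_index")["n_acc"].to_numpy()
            assert np.all(np.diff(acc) <= 0)

    def test_manifest_size_is_locations_times_timesteps(self):
        spec = make_scene_spec(droplets_per_frame=2)
        kin = dc.KineticsSpec(timesteps=list(np.linspace(0, 360, 16)),
                              n_locations=12)
        tl = dc.generate_timelapse(spec, kin, seed=3, render=False)
        assert len(tl.manifest) == 12 * 16 == 192

    def test_transformed_droplet_stays_transformed(self):
        spec, kin = self._tiny()
        tl = dc.generate_timelapse(spec, kin, seed=4, render=False)
        for loc in range(kin.n_locations):
            rows = [t for t, m in zip(tl.truths, tl.manifest.itertuples())
                    if m.location_id == loc]
            for earlier, later in zip(rows, rows[1:]):
                for pe, pl in zip(earlier.phases, later.phases):
                    if pe != dc.ACC:
                        assert pl == pe

    def test_empirical_acc_fraction_matches_closed_form(self):
        """Over 30 seeds the pooled ACC fraction tracks
        (1 - labile) + labile*exp(-k t) within Monte-Carlo error."""
        spec = make_scene_spec(droplets_per_frame=12)
        kin = dc.KineticsSpec(k_true=0.02, labile_fraction=0.4,
                              timesteps=[0.0, 120.0, 300.0], n_locations=2,
                              per_location_time_offset_min=0.0)
        fracs = []
        for seed in range(30):
            tl = dc.generate_timelapse(spec, kin, seed=seed, render=False)
            pooled = tl.true_counts.groupby("timestep_index")[
                ["n_acc", "n_droplets"]].sum()
            fracs.append(pooled.n_acc / pooled.n_droplets)
        mean_frac = np.mean(fracs, axis=0)
        t = np.array(kin.timesteps)
        expected = (1 - kin.labile_fraction
                    + kin.labile_fraction * np.exp(-kin.k_true * t))
        n = 30 * 2 * 12
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(mean_frac - expected) <= 4 * se + 1e-9)
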