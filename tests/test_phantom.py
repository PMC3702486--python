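"""Phantom geometry, inversion-recovery signal simulation, cohort simulation."""

import math

import numpy as np
import pytest

from mclegz.phantom import (
    CohortGroupParams,
    PapillaryMuscle,
    PhantomSpec,
    default_tis,
    healthy_null_ti,
    make_phantom,
    remote_roi_mask,
    simulate_cohort,
    simulate_ir_fgre,
    simulate_mcle,
    table_group_params,
)
from mclegz.volumes import Tissue


def brute_force_core_count(spec: PhantomSpec) -> int:
    """Independent per-voxel geometric scan for the core predicate."""
    nx, ny, nz = spec.shape
    cx, cy = spec.center
    count = 0
    core_limit = spec.endo_radius_mm + spec.transmural_fraction * (
        spec.epi_radius_mm - spec.endo_radius_mm
    )
    for i in range(nx):
        for j in range(ny):
            x = (i - cx) * spec.resolution
            y = (j - cy) * spec.resolution
            r = math.hypot(x, y)
            if not (spec.endo_radius_mm <= r < spec.epi_radius_mm):
                continue
            theta = math.degrees(math.atan2(y, x))
            d = abs((theta - spec.infarct_center_deg + 180.0) % 360.0 - 180.0)
            if spec.infarct_extent_deg > 0 and d <= spec.infarct_extent_deg / 2.0:
                if r < core_limit:
                    count += nz
    return count


class TestMakePhantom:
    def test_zero_extent_has_no_infarct(self):
        vol, _ = make_phantom(PhantomSpec(infarct_extent_deg=0.0))
        counts = vol.counts()
        assert counts[Tissue.CORE] == 0
        assert counts[Tissue.GRAY_ZONE] == 0

    @pytest.mark.parametrize("transmural", [1.0, 0.5])
    def test_core_count_matches_geometric_scan(self, transmural):
        spec = PhantomSpec(transmural_fraction=transmural)
        vol, _ = make_phantom(spec)
        assert vol.counts()[Tissue.CORE] == brute_force_core_count(spec)

    def test_deterministic(self, default_spec):
        a, am = make_phantom(default_spec)
        b, bm = make_phantom(default_spec)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(am.t1star, bm.t1star, equal_nan=True)

    def test_labels_partition_grid(self, phantom):
        vol, _ = phantom
        assert sum(vol.counts().values()) == int(np.prod(vol.shape))

    def test_myocardium_disjoint_from_blood(self, phantom):
        vol, _ = phantom
        assert not (vol.myocardium_mask & vol.blood_mask).any()

    def test_gray_zone_rims_the_core(self, phantom):
        vol, _ = phantom
        from scipy import ndimage

        gz = vol.mask(Tissue.GRAY_ZONE)
        near_core = ndimage.binary_dilation(
            vol.mask(Tissue.CORE), iterations=3
        )  # 3 voxels = 4.5 mm > 3 mm rim
        assert gz.any() and (gz <= near_core).all()

    def test_ground_truth_maps_follow_tissue_table(self, default_spec, phantom):
        vol, maps = phantom
        sig = default_spec.tissue_signals
        assert np.all(maps.t1star[vol.mask(Tissue.HEALTHY)] == sig[Tissue.HEALTHY].t1star)
        assert np.all(maps.a[vol.mask(Tissue.CORE)] == sig[Tissue.CORE].a)
        # gray zone defaults to the 50/50 core/healthy mix
        gz = vol.mask(Tissue.GRAY_ZONE)
        assert np.all(
            maps.t1star[gz]
            == 0.5 * (sig[Tissue.CORE].t1star + sig[Tissue.HEALTHY].t1star)
        )
        assert np.all(maps.b == 2.0 * maps.a)

    def test_pm_outside_blood_rejected(self):
        with pytest.raises(ValueError, match="blood pool"):
            PhantomSpec(pms=(
                PapillaryMuscle(center=(32.0, 45.0), radius_mm=4.0),
                PapillaryMuscle(center=(32.0, 20.0), radius_mm=4.0),
            ))

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(endo_radius_mm=30.0, epi_radius_mm=20.0)

    def test_oversized_rim_clips_with_warning(self):
        with pytest.warns(UserWarning, match="rim"):
            vol, _ = make_phantom(PhantomSpec(gray_zone_rim_mm=60.0))
        assert vol.counts()[Tissue.HEALTHY] == 0


class TestSimulateMCLE:
    def test_null_point_gives_zero_signal(self):
        spec = PhantomSpec()
        _, maps = make_phantom(spec)
        ti = spec.tissue_signals[Tissue.HEALTHY].t1star * math.log(2.0)
        series = simulate_mcle(maps, [ti], noise_sd=0.0)
        healthy = make_phantom(spec)[0].mask(Tissue.HEALTHY)
        assert np.allclose(series.data[..., 0][healthy], 0.0, atol=1e-9)

    def test_model_value_at_ti_600(self, phantom):
        # A=100, T1*=300 at TI=600: 100 - 200 exp(-2) = 72.9329...
        vol, maps = phantom
        spec = PhantomSpec(tissue_signals={
            Tissue.BLOOD: maps_sig(120, 250),
            Tissue.CORE: maps_sig(100, 300),
            Tissue.HEALTHY: maps_sig(80, 600),
        })
        v, m = make_phantom(spec)
        series = simulate_mcle(m, [600.0], noise_sd=0.0)
        core_vals = series.data[..., 0][v.mask(Tissue.CORE)]
        assert np.allclose(core_vals, 100.0 - 200.0 * math.exp(-2.0))
        assert np.allclose(core_vals, 72.932943, atol=1e-6)

    def test_steady_state_limit(self, phantom):
        vol, maps = phantom
        series = simulate_mcle(maps, [10 * 600.0], noise_sd=0.0)
        healthy = vol.mask(Tissue.HEALTHY)
        a = maps.a[healthy]
        assert np.all(np.abs(series.data[..., 0][healthy] - a) <= 1e-4 * a)

    def test_signal_increasing_in_ti(self, phantom):
        _, maps = phantom
        series = simulate_mcle(maps, default_tis(), noise_sd=0.0)
        diffs = np.diff(series.data[maps.valid], axis=-1)
        assert np.all(diffs > 0)

    def test_seed_reproducibility(self, phantom):
        _, maps = phantom
        s1 = simulate_mcle(maps, default_tis(), noise_sd=1.0, seed=7)
        s2 = simulate_mcle(maps, default_tis(), noise_sd=1.0, seed=7)
        assert np.array_equal(s1.data, s2.data)

    def test_empty_ti_list_rejected(self, phantom):
        _, maps = phantom
        with pytest.raises(ValueError):
            simulate_mcle(maps, [], noise_sd=0.0)


def maps_sig(a, t1):
    from mclegz.phantom import TissueSignal

    return TissueSignal(a=a, t1star=t1)


class TestSimulateIRFGRE:
    def test_healthy_nulled_at_default_ti(self, default_spec, phantom):
        vol, maps = phantom
        img = simulate_ir_fgre(maps, ti=healthy_null_ti(default_spec), noise_sd=0.0)
        assert np.allclose(img.data[vol.mask(Tissue.HEALTHY)], 0.0, atol=1e-9)

    def test_core_hyperenhanced_at_healthy_null(self, default_spec, phantom):
        vol, maps = phantom
        img = simulate_ir_fgre(maps, ti=healthy_null_ti(default_spec), noise_sd=0.0)
        assert np.all(img.data[vol.mask(Tissue.CORE)] > 0)
        assert img.data[vol.mask(Tissue.CORE)].mean() > img.data[vol.mask(Tissue.HEALTHY)].mean()

    def test_remote_roi_is_healthy_and_nonempty(self, default_spec, phantom):
        vol, _ = phantom
        roi = remote_roi_mask(vol, default_spec)
        assert roi.any()
        assert np.all(vol.labels[roi] == int(Tissue.HEALTHY))


class TestSimulateCohort:
    def test_zero_sd_yields_group_means(self):
        g1, g2 = table_group_params()
        g1 = CohortGroupParams(
            n=g1.n, measures={k: (m, 0.0) for k, (m, _) in g1.measures.items()}, pm_probs=(0, 0, 1)
        )
        g2 = CohortGroupParams(
            n=g2.n, measures={k: (m, 0.0) for k, (m, _) in g2.measures.items()}, pm_probs=(1, 0, 0)
        )
        df = simulate_cohort(g1, g2, seed=3)
        grp1 = df[df.therapy == 1]
        assert np.allclose(grp1["gz_lvm_mcle_pct"], 14.8)
        assert (grp1["pm_score"] == 2).all()
        assert (df[df.therapy == 0]["pm_score"] == 0).all()

    def test_total_is_core_plus_gz(self):
        df = simulate_cohort(seed=11)
        for method in ("mcle", "irfgre"):
            assert np.allclose(
                df[f"total_lvm_{method}_pct"],
                df[f"core_lvm_{method}_pct"] + df[f"gz_lvm_{method}_pct"],
                atol=1e-9,
            )

    def test_group_sizes_and_scores(self):
        df = simulate_cohort(seed=2)
        assert (df.therapy == 1).sum() == 12
        assert (df.therapy == 0).sum() == 13
        assert df.pm_score.isin([0, 1, 2]).all()

    def test_replicate_means_converge_to_group_mean(self):
        # law of large numbers over replicate cohorts for the MCLE gray zone
        means = []
        for s in range(400):
            df = simulate_cohort(seed=s)
            means.append(df[df.therapy == 1]["gz_lvm_mcle_pct"].mean())
        # MC error of the mean of 400 sample means: 4.8/sqrt(12*400) ~ 0.07
        assert abs(float(np.mean(means)) - 14.8) < 0.3

    def test_same_seed_identical(self):
        assert simulate_cohort(seed=5).equals(simulate_cohort(seed=5))

    def test_bad_probabilities_rejected(self):
        g1, _ = table_group_params()
        with pytest.raises(ValueError):
            CohortGroupParams(n=5, measures=g1.measures, pm_probs=(0.5, 0.2, 0.2))
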