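import numpy as np
import pandas as pd
import pytest

from alffpipe import alff
from alffpipe.alff import (
    AlffMap,
    BoldImage,
    DegenerateInputError,
    FeatureMatrix,
    MotionParameters,
    ParcellationAtlas,
    build_feature_matrix,
    compute_voxel_alff,
    exclude_high_motion,
    framewise_displacement,
    linear_detrend,
    region_average,
    standardize_alff,
)

from _oracles import alff_literal


def _single_voxel_image(ts, tr=2.0):
    data = np.asarray(ts, dtype=float)[None, None, None, :]
    mask = np.ones((1, 1, 1), dtype=bool)
    return BoldImage(data, tr=tr, mask=mask)


class TestLinearDetrend:
    def test_pure_line_maps_to_zero(self):
        assert np.allclose(linear_detrend([1.0, 2.0, 3.0, 4.0]), 0.0)

    def test_constant_maps_to_zero(self):
        assert np.allclose(linear_detrend([5.0] * 10), 0.0)

    def test_matches_polyfit_oracle(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        x = np.arange(4)
        slope, intercept = np.polyfit(x, y, 1)
        expected = y - (slope * x + intercept)
        assert np.allclose(linear_detrend(y), expected)
        # frozen oracle values
        assert np.allclose(linear_detrend(y), [0.2, -0.6, 0.6, -0.2])

    def test_zero_slope_and_mean(self):
        rng = np.random.default_rng(0)
        out = linear_detrend(rng.normal(size=50))
        assert abs(out.mean()) < 1e-12
        assert abs(np.polyfit(np.arange(50), out, 1)[0]) < 1e-12

    def test_too_short_raises(self):
        with pytest.raises(DegenerateInputError):
            linear_detrend([1.0, 2.0])


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        mp = MotionParameters(np.zeros((20, 6)))
        assert np.allclose(framewise_displacement(mp), 0.0)

    def test_first_frame_zero_and_step(self):
        params = np.zeros((3, 6))
        params[1, :3] = 0.1            # 0.1 mm on each translation axis
        params[1, 3] = 0.001           # 1 mrad rotation
        fd = framewise_displacement(MotionParameters(params), head_radius=50.0)
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(0.3 + 50 * 0.001)   # 0.35 mm

    def test_wrong_columns_raise(self):
        with pytest.raises(ValueError, match="6 columns"):
            MotionParameters(np.zeros((10, 5)))

    def test_single_volume_raises(self):
        with pytest.raises(ValueError):
            framewise_displacement(MotionParameters(np.zeros((1, 6))))


class TestExcludeHighMotion:
    def _motion(self, step, n=30):
        params = np.zeros((n, 6))
        params[:, 0] = np.arange(n) * step
        return MotionParameters(params)

    def test_high_motion_subject_flagged(self):
        motion = {
            (1, "pre"): self._motion(0.01), (1, "post"): self._motion(0.01),
            (2, "pre"): self._motion(0.5), (2, "post"): self._motion(0.01),
        }
        retained, log = exclude_high_motion(motion, threshold=0.2)
        assert retained == [1]
        assert log[0]["subject_id"] == 2
        assert log[0]["offending_conditions"] == ["pre"]

    def test_infinite_threshold_excludes_nobody(self):
        motion = {(s, c): self._motion(0.5)
                  for s in (1, 2) for c in ("pre", "post")}
        retained, log = exclude_high_motion(motion, threshold=np.inf)
        assert retained == [1, 2] and log == []

    def test_all_excluded_gives_empty_cohort(self):
        motion = {(1, "pre"): self._motion(0.5), (1, "post"): self._motion(0.5)}
        retained, log = exclude_high_motion(motion, threshold=0.2)
        assert retained == [] and len(log) == 1


class TestComputeVoxelAlff:
    def test_pure_sinusoid_closed_form(self):
        # amplitude-2 sinusoid at 0.05 Hz, N=200, TR=2 s: one in-band bin of
        # amplitude 2.0 among 29 in-band bins
        t = np.arange(200) * 2.0
        img = _single_voxel_image(2.0 * np.sin(2 * np.pi * 0.05 * t))
        # the sinusoid is its own detrended series; detrending again would
        # inject leakage from the tiny least-squares slope it has
        m = compute_voxel_alff(img, band=(0.01, 0.08), detrend=False)
        assert m.values[0, 0, 0] == pytest.approx(2.0 / 29.0, abs=1e-10)

    def test_constant_voxel_is_zero(self):
        img = _single_voxel_image(np.full(64, 7.0))
        assert compute_voxel_alff(img).values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(3)
        ts = rng.normal(size=128)
        a1 = compute_voxel_alff(_single_voxel_image(ts)).values[0, 0, 0]
        a3 = compute_voxel_alff(_single_voxel_image(3.0 * ts)).values[0, 0, 0]
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_band_above_nyquist_raises(self):
        img = _single_voxel_image(np.random.default_rng(0).normal(size=64))
        with pytest.raises(ValueError, match="Nyquist"):
            compute_voxel_alff(img, band=(0.01, 0.3))

    def test_no_inband_bin_raises(self):
        img = _single_voxel_image(np.random.default_rng(0).normal(size=16), tr=0.5)
        with pytest.raises(DegenerateInputError):
            compute_voxel_alff(img, band=(0.001, 0.002))

    def test_out_of_mask_voxels_zero(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 1, 1, 64))
        mask = np.array([True, False]).reshape(2, 1, 1)
        m = compute_voxel_alff(BoldImage(data, tr=2.0, mask=mask))
        assert m.values[1, 0, 0] == 0.0
        assert m.values[0, 0, 0] > 0.0

    def test_oracle_equivalence_100_series(self):
        rng = np.random.default_rng(42)
        tr, band = 2.0, (0.01, 0.08)
        for _ in range(100):
            n = rng.integers(60, 220)
            ts = rng.normal(size=n) + rng.uniform(-0.05, 0.05) * np.arange(n)
            got = compute_voxel_alff(_single_voxel_image(ts, tr=tr),
                                     band=band).values[0, 0, 0]
            assert got == pytest.approx(alff_literal(ts, tr, band), abs=1e-10)

    def test_white_noise_scales_with_sd(self):
        rng = np.random.default_rng(5)
        r = []
        for _ in range(30):
            ts = rng.normal(size=160)
            a1 = compute_voxel_alff(_single_voxel_image(ts)).values[0, 0, 0]
            a2 = compute_voxel_alff(_single_voxel_image(2 * ts)).values[0, 0, 0]
            r.append(a2 / a1)
        assert np.mean(r) == pytest.approx(2.0, abs=1e-9)

    def test_band_bin_bookkeeping(self):
        n, tr = 200, 2.0
        narrow = alff._band_bins(n, tr, (0.02, 0.05))
        wide = alff._band_bins(n, tr, (0.01, 0.08))
        assert set(narrow) <= set(wide)
        assert len(wide) == 29 and wide[0] == 4 and wide[-1] == 32
        full = alff._band_bins(n, tr, (1 / (n * tr), 1 / (2 * tr)))
        assert len(full) == n // 2


class TestStandardize:
    def test_two_voxel_example(self):
        m = AlffMap(np.array([1.0, 3.0]).reshape(2, 1, 1), band=(0.01, 0.08))
        out = standardize_alff(m, np.ones((2, 1, 1), bool))
        assert np.allclose(out.values.ravel(), [0.5, 1.5])
        assert out.standardized

    def test_inmask_mean_is_one(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.1, 5.0, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.3
        out = standardize_alff(AlffMap(vals, band=(0.01, 0.08)), mask)
        assert out.values[mask].mean() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.1, 5.0, size=(3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        once = standardize_alff(AlffMap(vals, band=(0.01, 0.08)), mask)
        twice = standardize_alff(once, mask)
        assert np.allclose(once.values, twice.values)

    def test_zero_mean_raises(self):
        m = AlffMap(np.zeros((2, 2, 2)), band=(0.01, 0.08))
        with pytest.raises(ZeroDivisionError):
            standardize_alff(m, np.ones((2, 2, 2), bool))


class TestRegionAverage:
    def test_single_region_gives_global_mean(self):
        vals = np.array([0.5, 1.5, 1.0, 1.0]).reshape(4, 1, 1)
        atlas = ParcellationAtlas(np.ones((4, 1, 1), dtype=int))
        m = AlffMap(vals, band=(0.01, 0.08), standardized=True)
        out = region_average(m, atlas)
        assert list(out.index) == [1]
        assert out.iloc[0] == pytest.approx(1.0)

    def test_two_voxel_region(self):
        vals = np.array([0.5, 1.5, 2.0]).reshape(3, 1, 1)
        atlas = ParcellationAtlas(np.array([1, 1, 2]).reshape(3, 1, 1))
        m = AlffMap(vals, band=(0.01, 0.08), standardized=True)
        out = region_average(m, atlas)
        assert out.loc[1] == pytest.approx(1.0)
        assert out.loc[2] == pytest.approx(2.0)

    def test_246_regions_from_synthetic_atlas(self, strong_cohort):
        from alffpipe.synthetic import SyntheticConfig, generate_atlas
        cfg = SyntheticConfig(n_regions=246, volume_dims=(18, 18, 12), seed=3)
        atlas = generate_atlas(cfg)
        vals = np.ones(atlas.labels.shape)
        m = AlffMap(vals, band=(0.01, 0.08), standardized=True)
        assert len(region_average(m, atlas)) == 246

    def test_requires_standardized(self):
        m = AlffMap(np.ones((2, 1, 1)), band=(0.01, 0.08), standardized=False)
        with pytest.raises(ValueError, match="standardized"):
            region_average(m, ParcellationAtlas(np.ones((2, 1, 1), dtype=int)))

    def test_shape_mismatch_raises(self):
        m = AlffMap(np.ones((2, 1, 1)), band=(0.01, 0.08), standardized=True)
        with pytest.raises(ValueError, match="mismatch"):
            region_average(m, ParcellationAtlas(np.ones((3, 1, 1), dtype=int)))


class TestFeatureMatrix:
    def _vectors(self, n_subjects=3, n_regions=5, seed=0):
        rng = np.random.default_rng(seed)
        return {
            (sid, cond): pd.Series(rng.uniform(0.5, 1.5, n_regions),
                                   index=range(1, n_regions + 1))
            for sid in range(1, n_subjects + 1) for cond in ("pre", "post")
        }

    def test_shape_and_label_balance(self):
        fm = build_feature_matrix(self._vectors(n_subjects=30))
        assert fm.values.shape == (60, 5)
        assert (fm.labels == 1).sum() == 30 and (fm.labels == -1).sum() == 30

    def test_single_subject(self):
        fm = build_feature_matrix(self._vectors(n_subjects=1))
        assert fm.values.shape == (2, 5)

    def test_insertion_order_irrelevant(self):
        v = self._vectors()
        fm1 = build_feature_matrix(dict(sorted(v.items())))
        fm2 = build_feature_matrix(dict(sorted(v.items(), reverse=True)))
        assert fm1.values.equals(fm2.values)
        assert (fm1.labels == fm2.labels).all()

    def test_unpaired_subject_raises(self):
        v = self._vectors()
        del v[(2, "post")]
        with pytest.raises(ValueError):
            build_feature_matrix(v)

    def test_nan_region_dropped_with_warning(self):
        v = self._vectors()
        v[(1, "pre")].loc[3] = np.nan
        with pytest.warns(UserWarning, match="dropping"):
            fm = build_feature_matrix(v)
        assert 3 not in fm.values.columns

    def test_tsv_roundtrip(self, tmp_path):
        fm = build_feature_matrix(self._vectors())
        path = tmp_path / "fm.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert np.allclose(back.values.to_numpy(), fm.values.to_numpy())
        assert (back.labels == fm.labels).all()

    def test_paired_arrays_alignment(self):
        fm = build_feature_matrix(self._vectors())
        sids, pre, post = fm.paired_arrays()
        for i, sid in enumerate(sids):
            row_pre = fm.values[(fm.subject_ids == sid) & (fm.labels == -1)]
            assert np.allclose(pre[i], row_pre.to_numpy().ravel())
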