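"""NNLS unmixing of line scans and area maps."""

import numpy as np
import pytest

import ramanmcr as rm
from ramanmcr.unmix import (
    field_from_map,
    grid_shape,
    metastable_area_plot,
    nnls_solve,
    unmix_area_map,
    unmix_scan,
)

from .oracles import nnls_bruteforce


class TestNNLSSolve:
    def test_identity_passthrough(self):
        x = nnls_solve(np.eye(2), np.array([0.2, 0.8]))
        np.testing.assert_allclose(x, [0.2, 0.8])

    def test_negative_target_clamped(self):
        x = nnls_solve(np.eye(2), np.array([-1.0, 2.0]))
        np.testing.assert_allclose(x, [0.0, 2.0])

    def test_matches_active_set_enumeration(self):
        """Random 6x3 instances agree with the exhaustive active-set oracle."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            A = rng.normal(size=(6, 3))
            b = rng.normal(size=6)
            np.testing.assert_allclose(
                nnls_solve(A, b), nnls_bruteforce(A, b), atol=1e-8
            )

    def test_residual_beats_clipped_least_squares(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            A = rng.normal(size=(8, 4))
            b = rng.normal(size=8)
            x = nnls_solve(A, b)
            ls, *_ = np.linalg.lstsq(A, b, rcond=None)
            clipped = np.clip(ls, 0, None)
            assert np.linalg.norm(A @ x - b) <= np.linalg.norm(A @ clipped - b) + 1e-12

    def test_zero_column_rejected_by_name(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="ghost"):
            nnls_solve(A, np.array([1.0, 1.0]), labels=["real", "ghost"])


class TestUnmixScan:
    def test_single_component_closure(self, axis):
        lib = rm.make_component_spectra(
            {"a": rm.BandTable((rm.Band(700, 20, 1.0),)),
             "b": rm.BandTable((rm.Band(1500, 20, 1.0),))},
            axis,
        )
        field = rm.ConcentrationField(
            np.dstack([np.ones((2, 4)), np.zeros((2, 4))]),
            ["a", "b"],
            np.array([0.0, 1.0]),
            np.linspace(0, 1.8, 4),
        )
        scan = rm.synthesize_linescan(field, lib, rm.NoiseSpec.noiseless(), seed=0)
        cmap, profiles = unmix_scan(scan, lib)
        np.testing.assert_allclose(cmap.values[0], 1.0, atol=1e-9)
        np.testing.assert_allclose(cmap.values[1], 0.0, atol=1e-9)
        np.testing.assert_allclose(profiles["a"], 1.0)

    def test_noiseless_scenario_recovers_truth_field(self, tp4_noiseless):
        cmap, _ = unmix_scan(tp4_noiseless.scan, tp4_noiseless.truth_library)
        truth = tp4_noiseless.truth_field.fractions.transpose(2, 0, 1)
        assert np.abs(cmap.values - truth).max() <= 1e-6

    def test_masking_nondiscriminating_channels_is_benign(self, tp4_noiseless):
        """Hiding channel ranges that carry no distinguishing bands degrades
        recovery by less than 10x the full-range error."""
        lib = tp4_noiseless.truth_library
        truth = tp4_noiseless.truth_field.fractions.transpose(2, 0, 1)
        sub = rm.HyperLineScan(
            tp4_noiseless.scan.intensities[:, ::20],
            tp4_noiseless.scan.times,
            tp4_noiseless.scan.positions[::20],
            lib.axis,
        )
        full_err = max(
            np.abs(unmix_scan(sub, lib)[0].values - truth[:, :, ::20]).max(), 1e-12
        )
        for lo, hi in [(1900.0, 2300.0), (760.0, 900.0)]:
            mask = ~lib.axis.window_mask(lo, hi)
            err = np.abs(
                unmix_scan(sub, lib, channel_mask=mask)[0].values - truth[:, :, ::20]
            ).max()
            assert err <= 10 * full_err

    def test_pixel_permutation_equivariance(self, tp4_seed42):
        lib = tp4_seed42.truth_library
        sub = rm.HyperLineScan(
            tp4_seed42.scan.intensities[:6, :30],
            tp4_seed42.scan.times[:6],
            tp4_seed42.scan.positions[:30],
            lib.axis,
        )
        cmap, _ = unmix_scan(sub, lib, closure=False)
        perm = np.random.default_rng(0).permutation(30)
        permuted = rm.HyperLineScan(
            sub.intensities[:, perm], sub.times, sub.positions[perm], lib.axis
        )
        cmap_p, _ = unmix_scan(permuted, lib, closure=False)
        np.testing.assert_allclose(cmap_p.values, cmap.values[:, :, perm], atol=1e-10)

    def test_gain_linearity_without_closure(self, tp4_noiseless):
        lib = tp4_noiseless.truth_library
        sub = rm.HyperLineScan(
            tp4_noiseless.scan.intensities[:4, :10],
            tp4_noiseless.scan.times[:4],
            tp4_noiseless.scan.positions[:10],
            lib.axis,
        )
        base, _ = unmix_scan(sub, lib, closure=False)
        scaled = rm.HyperLineScan(
            sub.intensities * 3.5, sub.times, sub.positions, lib.axis
        )
        res, _ = unmix_scan(scaled, lib, closure=False)
        np.testing.assert_allclose(
            res.values, 3.5 * base.values, rtol=1e-8, atol=1e-6 * base.values.max()
        )

    def test_axis_mismatch_rejected(self, tp4_noiseless):
        other_axis = rm.WavenumberAxis(400, 1800, 4)
        lib = rm.make_component_spectra(
            {"x": rm.BandTable((rm.Band(700, 20),))}, other_axis
        )
        with pytest.raises(ValueError, match="ax[ie]s"):
            unmix_scan(tp4_noiseless.scan, lib)


class TestMetastableAreaPlot:
    def test_absent_metastables_give_zero_series(self):
        frac = np.dstack([np.full((3, 2), 0.6), np.full((3, 2), 0.4),
                          np.zeros((3, 2))])
        field = rm.ConcentrationField(
            frac, ["s1", "s2", "m"], np.arange(3.0), np.arange(2.0)
        )
        series = metastable_area_plot(field, ["m"])
        np.testing.assert_array_equal(series["m"], 0.0)

    def test_default_scenario_series_unimodal_and_closed(self, tp4_noiseless):
        cmap, _ = unmix_scan(tp4_noiseless.scan, tp4_noiseless.truth_library)
        field = field_from_map(cmap)
        all_series = metastable_area_plot(field, list(field.labels))
        np.testing.assert_allclose(all_series.sum(axis=1), 1.0, atol=1e-6)
        meta = metastable_area_plot(field, ["TP MS1", "TP MS2"])
        for col in meta:
            y = meta[col].to_numpy()
            d = np.diff(y)
            tol = 1e-9
            assert ((d[:-1] < -tol) & (d[1:] > tol)).sum() == 0

    def test_unknown_label_rejected(self, tp4_noiseless):
        field = tp4_noiseless.truth_field
        with pytest.raises(ValueError, match="nope"):
            metastable_area_plot(field, ["nope"])


class TestAreaMap:
    def test_grid_shape_contract(self):
        assert grid_shape((1170.0, 2109.0), 8.0) == (147, 264)

    def test_missing_step_rejected(self, tp4_noiseless):
        with pytest.raises(ValueError, match="step"):
            unmix_area_map(
                np.zeros((4, 4, 976)), tp4_noiseless.truth_library, None
            )

    def _scene(self, lib, extra=None, seed=0, noise=None):
        patches = [
            ((slice(2, 8), slice(2, 10)), {"TP MH": 1.0}),
            ((slice(12, 18), slice(5, 14)), {"TP AH II": 1.0}),
        ]
        if extra:
            patches.append(extra)
        return rm.synthesize_area_scene(
            (20, 16), 8.0, patches, lib,
            noise=noise or rm.NoiseSpec.noiseless(), seed=seed,
        )

    def test_pure_patches_map_to_their_regions(self, tp4_noiseless):
        lib = tp4_noiseless.truth_library
        cube, truth = self._scene(lib)
        cmap = unmix_area_map(cube, lib, step_um=8.0)
        mh = cmap.component("TP MH")
        assert mh[2:8, 2:10].min() > 0.9
        outside = mh.copy()
        outside[2:8, 2:10] = 0
        assert outside.max() <= 1e-8

    def test_residual_metastable_detected(self, tp4_noiseless):
        """A particle of anhydrate carrying 10% residual metastable shows a
        mean metastable fraction within +/-0.02 of truth on its patch."""
        lib = tp4_noiseless.truth_library
        extra = ((slice(12, 18), slice(5, 14)),
                 {"TP AH II": 0.9, "TP MS1": 0.1})
        cube, truth = rm.synthesize_area_scene(
            (20, 16), 8.0,
            [((slice(2, 8), slice(2, 10)), {"TP MH": 1.0}), extra],
            lib, noise=rm.NoiseSpec(), seed=11,
        )
        cmap = unmix_area_map(cube, lib, step_um=8.0, closure=True)
        ms1 = cmap.component("TP MS1")[12:18, 5:14]
        assert abs(np.nanmean(ms1) - 0.1) <= 0.02

    def test_roi_crop(self, tp4_noiseless):
        lib = tp4_noiseless.truth_library
        cube, _ = self._scene(lib)
        cmap = unmix_area_map(
            cube, lib, step_um=8.0, roi_um=((0.0, 64.0), (0.0, 80.0))
        )
        assert cmap.values.shape[1:] == (9, 11)
        assert cmap.coords["y_um"][-1] <= 64.0
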