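"""Constrained MCR-ALS: rank selection, initialization, projection, resolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramanmcr as rm
from ramanmcr.mcr import (
    MCRConstraints,
    estimate_rank,
    initialize_unknowns,
    lack_of_fit,
    mcr_als,
    unimodality_project,
)

from .conftest import best_match_stats
from .oracles import unimodal_bruteforce


class TestLackOfFit:
    def test_exact_model_is_zero(self):
        C = np.array([[1.0, 2.0], [0.5, 1.5]])
        S = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]])
        assert lack_of_fit(C @ S, C, S) == 0.0

    def test_zero_model_is_100(self):
        D = np.array([[3.0, 4.0]])
        assert lack_of_fit(D, np.zeros((1, 1)), np.zeros((1, 2))) == 100.0

    def test_half_energy_misfit(self):
        """Missing one of two equal orthogonal entries leaves
        100*sqrt(1/2) ~ 70.71% lack of fit."""
        D = np.eye(2)
        C = np.array([[1.0], [0.0]])
        S = np.array([[1.0, 0.0]])
        assert lack_of_fit(D, C, S) == pytest.approx(100 * np.sqrt(0.5))

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            lack_of_fit(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 2)))


class TestEstimateRank:
    def test_noiseless_rank1(self):
        rng = np.random.default_rng(0)
        D = np.outer(rng.random(30), rng.random(50))
        sel = estimate_rank(D, 5)
        assert sel.k == 1
        assert sel.table.lof_percent.iloc[0] <= 1e-8

    def test_noiseless_rank3_lof_floor(self):
        rng = np.random.default_rng(1)
        D = rng.random((40, 3)) @ rng.random((3, 60))
        sel = estimate_rank(D, 6)
        assert sel.k == 3
        assert sel.table.lof_percent.iloc[2] <= 1e-8

    def test_default_scenario_selects_generator_count(self, tp4_seed42):
        from ramanmcr.preprocess import select_best_position, snr_per_position

        best = select_best_position(snr_per_position(tp4_seed42.scan, 0))
        sel = estimate_rank(tp4_seed42.scan.trace(best), 6)
        assert sel.k == tp4_seed42.truth_library.n_components

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_rank(np.zeros((5, 5)), 3)

    def test_k_max_validated(self):
        with pytest.raises(ValueError):
            estimate_rank(np.eye(3), 7)


class TestInitializeUnknowns:
    def test_no_unknowns_returns_library(self, tp4_noiseless):
        lib = tp4_noiseless.truth_library
        S0 = initialize_unknowns(tp4_noiseless.scan.trace(0), lib)
        np.testing.assert_array_equal(S0, lib.spectra)

    def test_pure_observation_recovered(self, axis):
        """If one observation contains the single unknown component alone,
        the initial unknown spectrum matches it up to scale."""
        known = rm.BandTable((rm.Band(700, 20, 1.0),)).evaluate(axis)
        hidden = rm.BandTable((rm.Band(1500, 25, 1.0),)).evaluate(axis)
        D = np.vstack(
            [2.0 * known, 1.5 * known + 0.2 * hidden, 0.9 * hidden, 0.5 * known]
        )
        lib = rm.SpectralLibrary(
            ["k", "u"],
            np.vstack([known, np.full_like(known, np.nan)]),
            np.array([True, False]),
            axis,
        )
        S0 = initialize_unknowns(D, lib)
        cos = S0[1] @ hidden / np.linalg.norm(S0[1]) / np.linalg.norm(hidden)
        assert cos >= 0.999

    def test_selection_is_order_free(self, axis):
        """Permuting the observations changes nothing about which spectra are
        selected (compared as a set)."""
        rng = np.random.default_rng(5)
        bands = [rm.BandTable((rm.Band(500 + 150 * i, 20, 1.0),)) for i in range(3)]
        comps = np.vstack([b.evaluate(axis) for b in bands])
        W = rng.random((10, 3)) * np.array([1.0, 0.6, 0.3])
        D = W @ comps + 1e-3 * rng.random((10, axis.n_channels))
        lib = rm.SpectralLibrary(
            ["k", "u1", "u2"],
            np.vstack([comps[0], np.full((2, axis.n_channels), np.nan)]),
            np.array([True, False, False]),
            axis,
        )
        S0 = initialize_unknowns(D, lib)
        perm = rng.permutation(10)
        S0p = initialize_unknowns(D[perm], lib)
        got = {tuple(np.round(r, 10)) for r in S0[1:]}
        gotp = {tuple(np.round(r, 10)) for r in S0p[1:]}
        assert got == gotp

    def test_fewer_observations_than_unknowns_rejected(self, axis):
        lib = rm.SpectralLibrary(
            ["u1", "u2"],
            np.full((2, axis.n_channels), np.nan),
            np.array([False, False]),
            axis,
        )
        with pytest.raises(ValueError, match="observation"):
            initialize_unknowns(np.ones((1, axis.n_channels)), lib)


class TestUnimodalityProjection:
    @pytest.mark.parametrize(
        "vec",
        [
            [0.0, 1.0, 3.0, 2.0, 1.0],
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 1.0],
            [2.0, 2.0, 2.0],
        ],
        ids=["unimodal", "increasing", "decreasing", "flat"],
    )
    def test_already_unimodal_unchanged(self, vec):
        np.testing.assert_array_equal(
            unimodality_project(np.array(vec)), np.array(vec)
        )

    def test_known_case_matches_bruteforce(self):
        y = np.array([1.0, 3.0, 2.0, 4.0, 1.0])
        np.testing.assert_allclose(
            unimodality_project(y), unimodal_bruteforce(y), atol=1e-12
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=0, max_size=12)
    )
    def test_matches_exhaustive_oracle(self, vec):
        """On every vector up to length 12 the projection achieves the same
        squared error as exhaustive mode search with two-sided PAVA."""
        y = np.array(vec)
        got = unimodality_project(y)
        want = unimodal_bruteforce(y)
        if y.size:
            assert ((got - y) ** 2).sum() == pytest.approx(
                ((want - y) ** 2).sum(), abs=1e-9
            )
        else:
            assert got.size == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=12))
    def test_output_is_unimodal_and_nonnegative(self, vec):
        out = unimodality_project(np.array(vec))
        assert out.min() >= 0
        d = np.diff(out)
        fell = False
        for step in d:
            if step < -1e-12:
                fell = True
            assert not (step > 1e-12 and fell)


class TestMCRALS:
    def test_all_known_noiseless_single_solve(self, tp4_noiseless):
        """With every spectrum known the first constrained NNLS solve already
        recovers the generator concentrations to 1e-6."""
        D = tp4_noiseless.scan.trace(0)
        res = mcr_als(D, tp4_noiseless.truth_library)
        truth = tp4_noiseless.truth_field.fractions[:, 0, :]
        assert np.abs(res.C - truth).max() <= 1e-6
        assert res.lof_trace[-1] <= 1e-6
        assert res.converged

    def test_noiseless_two_unknowns_recovered(self, tp4_noiseless):
        D = tp4_noiseless.scan.trace(0)
        res = mcr_als(D, tp4_noiseless.stable_library)
        cosines, rmse = best_match_stats(
            res, tp4_noiseless.truth_library,
            tp4_noiseless.truth_field.fractions[:, 0, :],
        )
        assert cosines.min() >= 0.99
        assert rmse <= 0.02
        assert res.avg_rel_residual < 0.1

    def test_known_rows_bit_identical_and_closure(self, tp4_noiseless):
        lib = tp4_noiseless.stable_library
        res = mcr_als(tp4_noiseless.scan.trace(0), lib)
        for j in np.flatnonzero(lib.known_mask):
            assert np.array_equal(res.S[j], lib.spectra[j])
        assert np.abs(res.C.sum(axis=1) - 1.0).max() <= 1e-9
        assert res.C.min() >= 0 and res.S.min() >= 0
        assert res.lof_trace[-1] <= res.lof_trace[0]

    def test_permutation_equivariance_without_unimodality(self, tp4_noiseless):
        """Row-permuting D permutes C identically (time-order constraints
        disabled, since unimodality is defined on the time ordering)."""
        D = tp4_noiseless.scan.trace(0)
        cons = MCRConstraints(unimodality="none")
        rng = np.random.default_rng(0)
        perm = rng.permutation(D.shape[0])
        res = mcr_als(D, tp4_noiseless.stable_library, cons, refine=False)
        res_p = mcr_als(D[perm], tp4_noiseless.stable_library, cons, refine=False)
        np.testing.assert_allclose(res_p.C, res.C[perm], atol=1e-8)

    def test_nonconvergence_warns(self, tp4_noiseless):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = mcr_als(
                tp4_noiseless.scan.trace(0),
                tp4_noiseless.stable_library,
                max_iter=3,
                refine=False,
            )
        assert not res.converged

    def test_nonfinite_data_rejected(self, tp4_noiseless):
        D = tp4_noiseless.scan.trace(0).copy()
        D[0, 0] = np.nan
        with pytest.raises(ValueError):
            mcr_als(D, tp4_noiseless.stable_library)
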