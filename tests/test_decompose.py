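import numpy as np
import pandas as pd
import pytest
from conftest import reference_frame, two_component_config

from tricalib import (
    FitOptions,
    align_factors,
    init_loadings,
    parafac_als,
    reconstruct,
    simulate_cube,
    swatld,
)
from tricalib.decompose import normalize_loadings


def best_cosines(B_fit, B_true):
    """For each true column, the best |cosine| over fitted columns."""
    Bf = B_fit / np.linalg.norm(B_fit, axis=0)
    Bt = B_true / np.linalg.norm(B_true, axis=0)
    return np.abs(Bf.T @ Bt).max(axis=0)


class TestInit:
    def test_svd_init_deterministic(self, noiseless_two_component):
        cube, _, _ = noiseless_two_component
        opts = FitOptions(n_components=2, init="svd")
        l1, l2 = init_loadings(cube, opts), init_loadings(cube, opts)
        assert np.array_equal(l1.A, l2.A) and np.array_equal(l1.B, l2.B)

    def test_random_init_seed_determined(self, noiseless_two_component):
        cube, _, _ = noiseless_two_component
        opts = FitOptions(n_components=2, init="random", seed=5)
        l1, l2 = init_loadings(cube, opts), init_loadings(cube, opts)
        assert np.array_equal(l1.A, l2.A)
        l3 = init_loadings(cube, FitOptions(n_components=2, init="random", seed=6))
        assert not np.array_equal(l1.A, l3.A)

    def test_svd_init_recovers_rank_one_profiles(self):
        cfg = two_component_config(
            components=two_component_config().components[:1],
            concentration_ranges={"x": (1.0, 10.0)},
        )
        cube, _, truth = simulate_cube(cfg)
        l = init_loadings(cube, FitOptions(n_components=1, init="svd"))
        assert best_cosines(l.A, truth.A[:, :1])[0] >= 0.999
        assert best_cosines(l.B, truth.B[:, :1])[0] >= 0.999

    def test_too_many_components_rejected(self, noiseless_two_component):
        cube, _, _ = noiseless_two_component
        with pytest.raises(ValueError, match="exceeds"):
            init_loadings(cube, FitOptions(n_components=999))


@pytest.mark.parametrize("engine", [parafac_als, swatld])
class TestExactFit:
    def test_noiseless_two_component_exact(self, engine, noiseless_two_component):
        cube, _, truth = noiseless_two_component
        res = engine(cube, FitOptions(n_components=2))
        assert res.fit_percent >= 99.999
        assert best_cosines(res.B, truth.B).min() >= 0.999
        assert best_cosines(res.A, truth.A).min() >= 0.999

    def test_unit_norm_convention_and_nonnegativity(self, engine, noiseless_two_component):
        cube, _, _ = noiseless_two_component
        res = engine(cube, FitOptions(n_components=2))
        np.testing.assert_allclose(np.linalg.norm(res.A, axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(res.B, axis=0), 1.0, atol=1e-9)
        assert res.A.min() >= 0 and res.B.min() >= 0

    def test_noisy_fit_above_99(self, engine, noisy_two_component):
        cube, _, _ = noisy_two_component
        res = engine(cube, FitOptions(n_components=2))
        assert res.fit_percent >= 99.0


class TestParafacAls:
    def test_fit_trace_monotone(self, noisy_two_component):
        cube, _, _ = noisy_two_component
        for nonneg in ((), ("A", "B", "C")):
            res = parafac_als(cube, FitOptions(n_components=2, nonnegative=nonneg))
            assert np.all(np.diff(res.fit_trace) >= -1e-8)

    def test_multistart_keeps_best(self, noisy_two_component):
        cube, _, _ = noisy_two_component
        single = parafac_als(cube, FitOptions(n_components=2, init="random", seed=1))
        multi = parafac_als(
            cube, FitOptions(n_components=2, init="random", seed=1, n_starts=3)
        )
        assert multi.fit_percent >= single.fit_percent - 1e-9


class TestSwatld:
    def test_excess_factor_still_recovers_true_spectra(self, noiseless_two_component):
        cube, _, truth = noiseless_two_component
        res = swatld(cube, FitOptions(n_components=3))
        assert best_cosines(res.B, truth.B).min() >= 0.99

    def test_concentration_agreement_with_parafac(self, noisy_two_component):
        cube, design, truth = noisy_two_component
        refs = reference_frame(cube, design, truth)
        out = {}
        for engine in (parafac_als, swatld):
            res = engine(cube, FitOptions(n_components=2))
            al = align_factors(res, refs)
            out[engine.__name__] = al.scores()[list(design.analyte_names)]
        a, b = out["parafac_als"].to_numpy(), out["swatld"].to_numpy()
        mask = np.abs(a) > 1e-3 * np.abs(a).max()
        assert np.abs((b[mask] - a[mask]) / a[mask]).max() <= 0.02


class TestAlignFactors:
    def test_reversed_reference_order_recovered(self, noiseless_two_component):
        cube, design, truth = noiseless_two_component
        res = parafac_als(cube, FitOptions(n_components=2))
        refs_rev = reference_frame(cube, design, truth)[["y", "x"]]
        al = align_factors(res, refs_rev)
        assert al.component_names == ("y", "x")
        for r in al.analyte_correlations.values():
            assert r >= 0.9999

    def test_sign_flip_corrected_and_reconstruction_preserved(
        self, noiseless_two_component
    ):
        from dataclasses import replace

        cube, design, truth = noiseless_two_component
        res = parafac_als(cube, FitOptions(n_components=2, nonnegative=()))
        flipped = replace(
            res, B=res.B * np.array([-1.0, 1.0]), C=res.C * np.array([-1.0, 1.0])
        )
        al = align_factors(flipped, reference_frame(cube, design, truth))
        assert min(al.analyte_correlations.values()) >= 0.9999
        np.testing.assert_allclose(reconstruct(al), reconstruct(res), atol=1e-9)

    def test_leftover_factors_ordered_by_score_norm(self, paperlike):
        cube, design, truth = paperlike
        res = swatld(cube, FitOptions(n_components=3))
        al = align_factors(res, reference_frame(cube, design, truth))
        assert al.component_names[:2] == ("vancomycin", "cephalexin")
        assert al.component_names[2] == "interferent_1"

    def test_grid_mismatch_rejected(self, noiseless_two_component):
        cube, design, truth = noiseless_two_component
        res = parafac_als(cube, FitOptions(n_components=2))
        bad = reference_frame(cube, design, truth).iloc[:-3]
        with pytest.raises(ValueError, match="wavelength"):
            align_factors(res, bad)


class TestReconstruct:
    def test_exact_fit_reconstruction_matches_cube(self, noiseless_two_component):
        cube, _, _ = noiseless_two_component
        res = parafac_als(cube, FitOptions(n_components=2))
        rel = np.linalg.norm(reconstruct(res) - cube.values) / np.linalg.norm(cube.values)
        assert rel <= 1e-6

    def test_zero_scores_give_zero_array(self, noiseless_two_component):
        from dataclasses import replace

        cube, _, _ = noiseless_two_component
        res = parafac_als(cube, FitOptions(n_components=2))
        zero = replace(res, C=np.zeros_like(res.C))
        assert np.abs(reconstruct(zero)).max() == 0.0

    def test_stored_fit_consistent_with_reconstruction(self, noisy_two_component):
        cube, _, _ = noisy_two_component
        res = swatld(cube, FitOptions(n_components=2))
        ssr = np.sum((cube.values - reconstruct(res)) ** 2)
        fit = 100 * (1 - ssr / np.sum(cube.values**2))
        assert fit == pytest.approx(res.fit_percent, abs=1e-6)

    def test_normalization_leaves_reconstruction_invariant(self, noisy_two_component):
        cube, _, _ = noisy_two_component
        res = parafac_als(cube, FitOptions(n_components=2))
        A, B, C = normalize_loadings(res.A * 3.0, res.B * 0.5, res.C / 1.5)
        np.testing.assert_allclose(
            np.einsum("in,jn,kn->ijk", A, B, C),
            np.einsum("in,jn,kn->ijk", res.A * 3.0, res.B * 0.5, res.C / 1.5),
            atol=1e-10,
        )

    def test_shape_mismatch_rejected(self, noiseless_two_component):
        cube, _, _ = noiseless_two_component
        res = parafac_als(cube, FitOptions(n_components=2))
        with pytest.raises(ValueError, match="shape"):
            reconstruct(res, cube_shape=(1, 2, 3))


class TestSecondOrderAdvantage:
    def test_prediction_scores_proportional_despite_interferent(self, paperlike):
        cube, design, truth = paperlike
        pred = design.sample_ids_with_role("prediction")
        for engine in (parafac_als, swatld):
            res = engine(cube, FitOptions(n_components=3))
            al = align_factors(res, reference_frame(cube, design, truth))
            scores = al.scores()
            for a in design.analyte_names:
                ratio = scores.loc[pred, a].to_numpy() / truth.C.loc[pred, a].to_numpy()
                assert np.abs(ratio / ratio.mean() - 1).max() <= 0.03
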