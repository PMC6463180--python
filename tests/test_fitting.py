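"""Closed-form and Levenberg–Marquardt refitting, offset estimation."""

import numpy as np
import pytest
import statsmodels.api as sm

import neoref as nr
from neoref import (CHB_SURFACE, HCT_SURFACE, FitMethod, GridDataset,
                    SurfaceParameters, design_matrix, design_row,
                    estimate_offset, fit_closed_form, fit_lm,
                    generate_grid)
from neoref.exceptions import (IdentifiabilityError, InvalidInputError,
                               MissingDataError)


@pytest.mark.parametrize("ga,pna,expected", [
    (40, 0, [1, 40, 1600, 0, 0]),
    (0, 0, [1, 0, 0, 0, 0]),
    (30, 7, [8, 30, 900, 210, 49]),
])
def test_design_row_basis(ga, pna, expected):
    np.testing.assert_array_equal(design_row(ga, pna), expected)


def test_design_matrix_rejects_non_finite():
    with pytest.raises(InvalidInputError):
        design_matrix([np.nan], [0.0])


def _noise_free_grid(model, ga_vals, pna_vals):
    return generate_grid(model, ga_vals, pna_vals)


@pytest.mark.parametrize("preset", ["chb", "hct"])
def test_closed_form_recovers_published_coefficients(preset,
                                                     full_grid_points):
    """Noise-free data generated from a preset identifies it exactly."""
    model = nr.get_model(preset)
    data = _noise_free_grid(model, *full_grid_points)
    result = fit_closed_form(data)
    np.testing.assert_allclose(result.surface.as_array(),
                               model.surface.as_array(), atol=1e-6)
    assert result.converged
    assert result.method is FitMethod.CLOSED_FORM
    assert result.sse == pytest.approx(0.0, abs=1e-12)


def test_closed_form_matches_statsmodels_ols(chb_model):
    """Independent OLS cross-check on a noisy grid."""
    data = generate_grid(chb_model, noise=nr.NoiseSpec(sd_mean=0.5, seed=3))
    ours = fit_closed_form(data).surface.as_array()
    X = design_matrix(data.ga, data.pna)
    theirs = sm.OLS(data.mean, X).fit().params
    np.testing.assert_allclose(ours, theirs, atol=1e-10)


def test_exact_plane_interpolation():
    """Five points on mean = 2·(1+pna) give p1=2 and zero elsewhere."""
    ga = np.array([22.0, 25.0, 30.0, 35.0, 42.0])
    pna = np.array([0.0, 3.0, 7.0, 14.0, 28.0])
    data = GridDataset(ga=ga, pna=pna, mean=2.0 * (1.0 + pna))
    result = fit_closed_form(data)
    np.testing.assert_allclose(result.surface.as_array(),
                               [2, 0, 0, 0, 0], atol=1e-8)


def test_rank_deficient_design_names_directions():
    """A single-GA, PNA=0 slice cannot separate several basis terms."""
    ga = np.full(10, 30.0)
    pna = np.zeros(10)
    data = GridDataset(ga=ga, pna=pna, mean=np.full(10, 14.0))
    with pytest.raises(IdentifiabilityError) as err:
        fit_closed_form(data)
    assert err.value.directions


def test_too_few_points_is_identifiability_error():
    data = GridDataset(ga=[30.0, 31.0], pna=[0.0, 1.0], mean=[14.0, 14.1])
    with pytest.raises(IdentifiabilityError):
        fit_closed_form(data)


def test_lm_from_zero_init_matches_closed_form(chb_model, full_grid_points):
    data = _noise_free_grid(chb_model, *full_grid_points)
    lm = fit_lm(data)
    cf = fit_closed_form(data)
    np.testing.assert_allclose(lm.surface.as_array(),
                               cf.surface.as_array(), atol=1e-6)
    assert lm.method is FitMethod.LEVENBERG_MARQUARDT


def test_lm_at_fixed_point_converges_immediately(chb_model):
    data = generate_grid(chb_model)
    result = fit_lm(data, init=chb_model.surface)
    assert result.converged
    assert result.sse == pytest.approx(0.0, abs=1e-12)
    assert result.n_iterations <= 2


def test_lm_nonconvergence_carries_iterate(chb_model):
    data = generate_grid(chb_model, noise=nr.NoiseSpec(sd_mean=1.0, seed=1))
    from neoref.exceptions import ConvergenceError
    with pytest.raises(ConvergenceError) as err:
        fit_lm(data, max_iter=2)
    assert isinstance(err.value.iterate, SurfaceParameters)


def test_noisy_recovery_within_three_standard_errors(chb_model):
    """With Gaussian noise (sd 0.5) the estimate lands within the usual
    sampling band of the truth."""
    data = generate_grid(chb_model, noise=nr.NoiseSpec(sd_mean=0.5,
                                                       seed=11))
    est = fit_closed_form(data).surface.as_array()
    X = design_matrix(data.ga, data.pna)
    se = sm.OLS(data.mean, X).fit().bse
    assert np.all(np.abs(est - chb_model.surface.as_array()) < 3.0 * se)


def test_rmse_shrinks_with_replication(chb_model):
    """Coefficient RMSE scales ~1/sqrt(n) as the grid is replicated."""
    rng = np.random.default_rng(42)
    ga0, pna0 = nr.default_layout()
    truth = chb_model.surface.as_array()

    def rmse(n_rep, reps=40):
        ga = np.tile(ga0, n_rep)
        pna = np.tile(pna0, n_rep)
        clean = nr.evaluate_mean(chb_model.surface, ga, pna)
        errs = []
        for _ in range(reps):
            data = GridDataset(ga=ga, pna=pna,
                               mean=clean + rng.normal(0, 0.5, len(ga)))
            errs.append(fit_closed_form(data).surface.as_array() - truth)
        return np.sqrt(np.mean(np.square(errs)))

    ratio = rmse(1) / rmse(16)
    assert 2.0 < ratio < 8.0   # ideal ratio 4


def test_offset_recovery_exact(chb_model, hct_model):
    for model, want in ((chb_model, 3.76), (hct_model, 10.69)):
        data = generate_grid(model)
        assert estimate_offset(data, model.surface) \
            == pytest.approx(want, abs=1e-9)


def test_offset_zero_when_band_collapsed():
    ga = np.arange(22.0, 43.0)
    pna = np.zeros_like(ga)
    mean = np.linspace(10, 20, len(ga))
    data = GridDataset(ga=ga, pna=pna, mean=mean, p5=mean, p95=mean)
    assert estimate_offset(data, CHB_SURFACE) == 0.0


def test_offset_pools_alternating_half_spreads(chb_model):
    """Half-spreads alternating 3 and 5 over equal counts average to 4."""
    ga = np.arange(22.0, 30.0)
    pna = np.zeros_like(ga)
    mean = nr.evaluate_mean(chb_model.surface, ga, pna)
    half = np.where(np.arange(len(ga)) % 2 == 0, 3.0, 5.0)
    data = GridDataset(ga=ga, pna=pna, mean=mean,
                       p5=mean - half, p95=mean + half)
    assert estimate_offset(data, chb_model.surface) == pytest.approx(4.0)


def test_offset_symmetric_in_p5_p95_roles(chb_model):
    """Swapping which side of the band is reported leaves the estimate
    unchanged (pooled estimator symmetry)."""
    data = generate_grid(chb_model)
    lower_only = GridDataset(ga=data.ga, pna=data.pna, mean=data.mean,
                             p5=data.p5)
    upper_only = GridDataset(ga=data.ga, pna=data.pna, mean=data.mean,
                             p95=data.p95)
    a = estimate_offset(lower_only, chb_model.surface)
    b = estimate_offset(upper_only, chb_model.surface)
    assert a == pytest.approx(b, abs=1e-12)


def test_offset_uses_fitted_means_where_missing(chb_model):
    data = generate_grid(chb_model)
    holes = data.mean.copy()
    holes[::3] = np.nan
    holey = GridDataset(ga=data.ga, pna=data.pna, mean=holes,
                        p5=data.p5, p95=data.p95)
    assert estimate_offset(holey, chb_model.surface) \
        == pytest.approx(3.76, abs=1e-9)


def test_offset_requires_percentile_data(chb_grid, chb_model):
    bare = GridDataset(ga=chb_grid.ga, pna=chb_grid.pna, mean=chb_grid.mean)
    with pytest.raises(MissingDataError):
        estimate_offset(bare, chb_model.surface)


def test_grid_dataset_rejects_inverted_bands():
    with pytest.raises(InvalidInputError):
        GridDataset(ga=[30.0], pna=[0.0], mean=[14.0], p5=[15.0],
                    p95=[16.0])
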