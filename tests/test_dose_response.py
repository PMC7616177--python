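"""4PL fitting: exact recovery, an independent grid-search oracle, equivariances."""

import numpy as np
import pytest

from pharmfit import (
    ConcentrationResponseCurve,
    FlatDataError,
    fit_4pl,
    fit_thermal_melt,
    gen_dose_response,
    normalize_to_reference,
    potency_summary,
)

GRID8 = np.logspace(-10, -4, 8)


def make_curve(conc, resp, **kw):
    kw.setdefault("ligand_id", "L")
    kw.setdefault("pathway_id", "P")
    return ConcentrationResponseCurve(concentrations=conc, responses=resp, **kw)


@pytest.mark.parametrize(
    "truth",
    [
        {"bottom": 0.0, "top": 100.0, "pEC50": 7.0, "hill": 1.0},
        {"bottom": 10.0, "top": 80.0, "pEC50": 6.2, "hill": 1.7},
        {"bottom": 0.0, "top": 55.0, "pEC50": 8.1, "hill": 0.7},
    ],
)
def test_noiseless_exact_recovery(truth):
    curve = gen_dose_response(truth, GRID8, replicates=1, noise_sd=0.0, seed=0)
    fit = fit_4pl(curve)
    assert fit.converged
    for name, key in [("bottom", "bottom"), ("top", "top"), ("pEC50", "pEC50"), ("hill", "hill")]:
        got, want = getattr(fit, name), truth[key]
        assert got == pytest.approx(want, rel=1e-6, abs=1e-6), name


def test_grid_search_oracle_agrees_with_fitter():
    """Brute-force profile over (pEC50, hill) with analytic plateaus lands on the
    same minimizer as the nonlinear fitter, within grid resolution."""
    conc = np.logspace(-9, -5, 12)
    curve = gen_dose_response(
        {"bottom": 5.0, "top": 95.0, "pEC50": 7.0, "hill": 1.2}, conc, 1, 0.05, seed=1
    )
    y = curve.responses
    log_a = np.log10(curve.concentrations)
    pec50s = np.arange(5.0, 9.0001, 0.01)
    hills = np.arange(0.5, 2.0001, 0.01)
    best = (np.inf, None, None)
    ones = np.ones_like(y)
    for h in hills:
        # shape function for every pEC50 at once: (npec, npts)
        s = 1.0 / (1.0 + 10.0 ** ((-pec50s[:, None] - log_a[None, :]) * h))
        # analytic least-squares plateaus: y ~ bottom + (top-bottom)*s
        n = y.size
        sy = s @ y
        s1 = s.sum(axis=1)
        ss = (s * s).sum(axis=1)
        det = n * ss - s1 ** 2
        beta = (n * sy - s1 * y.sum()) / det  # top - bottom
        alpha = (y.sum() - beta * s1) / n  # bottom
        resid = y[None, :] - (alpha[:, None] + beta[:, None] * s)
        rss = (resid ** 2).sum(axis=1)
        i = int(np.argmin(rss))
        if rss[i] < best[0]:
            best = (rss[i], pec50s[i], h)
    _, pec50_star, hill_star = best
    fit = fit_4pl(curve)
    assert fit.pEC50 == pytest.approx(pec50_star, abs=0.011)
    assert fit.hill == pytest.approx(hill_star, abs=0.011)


def test_scale_equivariance():
    curve = gen_dose_response({"bottom": 2.0, "top": 90.0, "pEC50": 7.3, "hill": 1.1}, GRID8, 2, 0.05, seed=4)
    f1 = fit_4pl(curve)
    c = 3.7
    scaled = make_curve(curve.concentrations, curve.responses * c)
    f2 = fit_4pl(scaled)
    assert f2.pEC50 == pytest.approx(f1.pEC50, abs=1e-6)
    assert f2.hill == pytest.approx(f1.hill, abs=1e-6)
    assert f2.top == pytest.approx(f1.top * c, rel=1e-6)
    assert f2.bottom == pytest.approx(f1.bottom * c, abs=1e-4)
    assert f2.residual_sd == pytest.approx(f1.residual_sd * c, rel=1e-6)


def test_concentration_unit_shift():
    """Treating the same numbers as nM (i.e. x 1e-9 in molar) shifts pEC50 by exactly 9."""
    curve = gen_dose_response({"bottom": 0.0, "top": 100.0, "pEC50": 7.0, "hill": 1.0}, GRID8, 1, 0.03, seed=5)
    f_m = fit_4pl(curve)
    f_nm = fit_4pl(make_curve(curve.concentrations * 1e-9, curve.responses))
    assert f_nm.pEC50 - f_m.pEC50 == pytest.approx(9.0, abs=1e-6)


def test_requires_four_distinct_concentrations():
    with pytest.raises(ValueError, match="4 distinct"):
        fit_4pl(make_curve(np.array([1e-9, 1e-8, 1e-9, 1e-7]), np.array([1.0, 2.0, 1.0, 3.0])))


def test_flat_data_is_distinct_error():
    with pytest.raises(FlatDataError):
        fit_4pl(make_curve(GRID8, np.full(8, 42.0)))
    # flat within replicate noise also refuses to fit
    rng = np.random.default_rng(0)
    conc = np.tile(GRID8, 3)
    with pytest.raises(FlatDataError):
        fit_4pl(make_curve(conc, 50.0 + rng.normal(0, 5.0, conc.size)))


def test_top_extrapolated_flag():
    # EC50 sits above the top of the tested range: plateau never approached
    curve = gen_dose_response({"bottom": 0, "top": 100, "pEC50": 4.0, "hill": 1.0}, np.logspace(-9, -6, 8), 1, 0.0, 0)
    fit = fit_4pl(curve)
    assert "top-extrapolated" in fit.flags


def test_normalize_to_reference_endpoints_and_partial_agonist():
    ref = fit_4pl(gen_dose_response({"bottom": 0.0, "top": 800.0, "pEC50": 7.0, "hill": 1.0}, GRID8, 1, 0.0, 0))
    curve = make_curve(GRID8[:4], np.array([800.0, 0.0, 400.0, 800.0]))
    norm = normalize_to_reference(curve, ref)
    assert norm.response_units == "percent_reference"
    assert norm.responses[0] == pytest.approx(100.0, abs=1e-9)
    assert norm.responses[1] == pytest.approx(0.0, abs=1e-9)
    # operational partial agonist tau=1 plateaus at Em/2 -> 50% of reference
    partial = gen_dose_response(
        {"em": 800.0, "basal": 0.0, "n": 1.0, "log_R": 6.0, "log_KA": -6.0},  # tau = 1
        GRID8, 1, 0.0, 0, model="operational",
    )
    top = fit_4pl(normalize_to_reference(partial, ref)).top
    assert top == pytest.approx(50.0, abs=0.2)


def test_normalize_degenerate_reference_errors():
    ref = fit_4pl(gen_dose_response({"bottom": 0.0, "top": 100.0, "pEC50": 7.0, "hill": 1.0}, GRID8, 1, 0.0, 0))
    bad = ref.__class__(**{**ref.__dict__, "top": ref.bottom})
    with pytest.raises(ValueError, match="degenerate"):
        normalize_to_reference(gen_dose_response({"bottom": 0, "top": 1, "pEC50": 7, "hill": 1}, GRID8, 1, 0, 0), bad)


def test_potency_summary_arithmetic():
    fits = [
        fit_4pl(gen_dose_response({"bottom": 0, "top": 100, "pEC50": p, "hill": 1}, GRID8, 1, 0.0, 0))
        for p in (7.4, 7.5, 7.6)
    ]
    s = potency_summary(fits)
    assert s.mean_pEC50 == pytest.approx(7.5, abs=1e-6)
    assert s.sem_pEC50 == pytest.approx(0.1 / np.sqrt(3), abs=1e-4)
    assert s.n_experiments == 3
    single = potency_summary(fits[:1])
    assert single.sem_pEC50 == 0.0 and "n=1" in single.flags
    with pytest.raises(ValueError):
        potency_summary([])


def test_thermal_melt_noiseless_and_interpolated_midpoint():
    t = np.arange(30.0, 61.0, 2.5)
    frac = 1.0 / (1.0 + np.exp((t - 45.0) * 0.6))
    res = fit_thermal_melt(t, frac)
    assert res["tm"] == pytest.approx(45.0, abs=1e-6)
    # midpoint between measured points: recovered by the fit, not the grid
    t2 = np.array([30.0, 38.0, 44.0, 47.0, 52.0, 60.0])
    frac2 = 1.0 / (1.0 + np.exp((t2 - 45.5) * 0.8))
    assert fit_thermal_melt(t2, frac2)["tm"] == pytest.approx(45.5, abs=1e-6)


def test_thermal_melt_noisy_recovery():
    t = np.arange(35.0, 70.1, 2.5)
    clean = 1.0 / (1.0 + np.exp((t - 52.0) * 0.5))
    tms = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        tms.append(fit_thermal_melt(t, clean + rng.normal(0, 0.03, t.size))["tm"])
    assert np.mean(tms) == pytest.approx(52.0, abs=0.5)


def test_thermal_melt_no_transition_errors():
    t = np.arange(30.0, 45.0, 2.0)
    with pytest.raises(ValueError, match="transition"):
        fit_thermal_melt(t, np.full(t.size, 0.98))


def test_curve_validation():
    with pytest.raises(ValueError):
        make_curve(np.array([1e-9, -1e-8]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        make_curve(np.array([1e-9, 0.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        make_curve(np.array([1e-9]), np.array([1.0, 2.0]))
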