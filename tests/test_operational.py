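"""Operational-model fitting and bias arithmetic."""

import numpy as np
import pytest

from pharmfit import (
    assess_bias,
    bias_table_from_fits,
    delta_delta_log_r,
    delta_log_r,
    fit_4pl,
    fit_operational_global,
    gen_dose_response,
    operational_response,
)
from pharmfit.operational import BiasEntry, BiasTable, LigandTransduction

GRID8 = np.logspace(-10, -4, 8)


def entry(pathway, log_r, se):
    return LigandTransduction(
        ligand_id="x", pathway_id=pathway, log_R=log_r, log_KA=-6.0,
        se_log_R=se, se_log_KA=0.1,
    )


def test_closed_form_identities_noiseless():
    """tau=4, K_A=1uM, Em=100, n=1: half-max at A = K_A/(1+tau) = 200 nM and
    plateau Em*tau/(1+tau) = 80 - reproduced by the fitted model within 1e-6."""
    truth = {"em": 100.0, "basal": 0.0, "n": 1.0, "log_R": np.log10(4.0 / 1e-6) - 6.0 - (-6.0) , "log_KA": -6.0}
    # log_R = log10(tau) - log10(K_A) = log10(4) + 6
    truth["log_R"] = np.log10(4.0) + 6.0
    curves = [
        gen_dose_response(truth, GRID8, 1, 0.0, 0, model="operational", ligand_id="partial"),
        gen_dose_response({"em": 100.0, "basal": 0.0, "n": 1.0, "log_R": 8.5, "log_KA": -5.0},
                          GRID8, 1, 0.0, 1, model="operational", ligand_id="ref"),
    ]
    of = fit_operational_global(curves, "ref")
    e = of["partial"]
    # A -> infinity limit of the fitted curve: Em*tau/(1+tau)
    plateau = of.basal + (of.em - of.basal) * e.tau ** of.n / (1.0 + e.tau ** of.n)
    assert plateau == pytest.approx(80.0, abs=1e-6)
    half_resp = operational_response(200e-9, of.em, of.basal, of.n, e.log_R, e.log_KA)
    assert half_resp == pytest.approx(40.0, abs=1e-6)


def test_log_r_difference_recovery_under_noise():
    """Two ligands with true log_R 8.0 (reference) and 6.5: over 200 seeded
    5%-noise simulations the mean recovered difference is -1.5 within 0.1."""
    diffs = []
    for seed in range(200):
        curves = [
            gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 8.0, "log_KA": -6.0},
                              GRID8, 2, 0.05, 2 * seed, model="operational", ligand_id="ref"),
            gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 6.5, "log_KA": -5.5},
                              GRID8, 2, 0.05, 2 * seed + 1, model="operational", ligand_id="test"),
        ]
        of = fit_operational_global(curves, "ref")
        diffs.append(of["test"].log_R - of["ref"].log_R)
    assert np.mean(diffs) == pytest.approx(-1.5, abs=0.1)


def test_receptor_depletion_signature():
    """High-reserve agonist (tau=30) vs the same ligand at tau=0.3: both the
    half-max location and the plateau fall - potency and maximum drop together."""
    ka = 1e-6
    hi = {"em": 100, "basal": 0, "n": 1, "log_R": np.log10(30) - np.log10(ka), "log_KA": np.log10(ka)}
    lo = {"em": 100, "basal": 0, "n": 1, "log_R": np.log10(0.3) - np.log10(ka), "log_KA": np.log10(ka)}
    c_hi = gen_dose_response(hi, GRID8, 1, 0.0, 0, model="operational")
    c_lo = gen_dose_response(lo, GRID8, 1, 0.0, 0, model="operational")
    f_hi, f_lo = fit_4pl(c_hi), fit_4pl(c_lo)
    assert f_lo.top < f_hi.top  # maximum falls
    assert f_lo.pEC50 < f_hi.pEC50  # potency falls


def test_nested_4pl_consistency_large_tau():
    """With n = 1 and large tau the operational curve is a 4PL with
    EC50 -> K_A/(1+tau); the two fits agree within 1e-4 relative."""
    tau, ka = 300.0, 1e-6
    truth = {"em": 100, "basal": 0, "n": 1, "log_R": np.log10(tau / ka), "log_KA": np.log10(ka)}
    curve = gen_dose_response(truth, np.logspace(-11, -5, 10), 1, 0.0, 0, model="operational")
    f = fit_4pl(curve)
    assert f.ec50 == pytest.approx(ka / (1 + tau), rel=1e-4)


def test_reference_invariance_under_permutation():
    curves = [
        gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 8.0, "log_KA": -6.0},
                          GRID8, 2, 0.05, 11, model="operational", ligand_id="A"),
        gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 7.0, "log_KA": -5.5},
                          GRID8, 2, 0.05, 12, model="operational", ligand_id="B"),
        gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 6.0, "log_KA": -5.0},
                          GRID8, 2, 0.05, 13, model="operational", ligand_id="C"),
    ]
    f1 = fit_operational_global(curves, "A")
    f2 = fit_operational_global(curves[::-1], "A")
    for lig in "ABC":
        assert f1[lig].log_R == pytest.approx(f2[lig].log_R, abs=1e-6)
    assert f1.em == pytest.approx(f2.em, abs=1e-6)


def test_single_ligand_errors():
    c = gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 8.0, "log_KA": -6.0},
                          GRID8, 1, 0.0, 0, model="operational")
    with pytest.raises(ValueError, match="2 ligands"):
        fit_operational_global([c], "test")


def test_delta_log_r_arithmetic_and_sign():
    ref = entry("Gq", 8.0, 0.20)
    test = entry("Gq", 6.5, 0.10)
    d = delta_log_r(test, ref)
    assert d.value == pytest.approx(-1.5)
    assert d.sem == pytest.approx(np.sqrt(0.1 ** 2 + 0.2 ** 2), abs=1e-4)  # 0.2236
    # reference vs itself: 0 with sqrt(2)-inflated SEM
    d0 = delta_log_r(ref, ref)
    assert d0.value == 0.0
    assert d0.sem == pytest.approx(0.20 * np.sqrt(2), abs=1e-12)
    # more efficient test ligand -> positive delta
    assert delta_log_r(entry("Gq", 9.0, 0.1), ref).value > 0
    with pytest.raises(ValueError, match="cross-pathway"):
        delta_log_r(entry("arrestin", 6.5, 0.1), ref)


def test_delta_delta_arithmetic_antisymmetry_and_bias_factor():
    deltas = {"Gq": BiasEntry(0.3, 0.1), "arrestin": BiasEntry(-0.2, 0.1)}
    dd = delta_delta_log_r(deltas)
    assert dd[("Gq", "arrestin")].value == pytest.approx(0.5)
    assert dd[("Gq", "arrestin")].sem == pytest.approx(np.sqrt(0.02), abs=1e-4)  # 0.1414
    assert dd[("arrestin", "Gq")].value == -dd[("Gq", "arrestin")].value  # exact antisymmetry
    table = BiasTable("x", "ref", deltas, dd)
    assert table.bias_factor("Gq", "arrestin") == pytest.approx(10 ** 0.5, rel=1e-12)  # 3.16
    with pytest.raises(ValueError):
        delta_delta_log_r({"Gq": BiasEntry(0.3, 0.1)})


def test_assess_bias_threshold():
    deltas = {"a": BiasEntry(0.0, 0.1), "b": BiasEntry(-0.4, 0.1), "c": BiasEntry(0.9, 0.1)}
    dd = delta_delta_log_r(deltas)
    table = BiasTable("x", "ref", deltas, dd)
    flags = assess_bias(table)
    assert flags[("a", "b")] is True  # 0.4: within the +/-1 window
    assert flags[("b", "c")] is False  # 1.3: biased
    assert flags[("a", "c")] is True  # 0.9 boundary case stays unbiased
    # zero is trivially unbiased
    assert abs(dd[("a", "b")].value) != 0 or flags[("a", "b")]


def test_bias_table_from_fits_reference_delta_zero():
    fits = {}
    for i, pw in enumerate(["Gq", "pERK"]):
        curves = [
            gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 8.0, "log_KA": -6.0},
                              GRID8, 1, 0.0, 2 * i, model="operational", ligand_id="ref", pathway_id=pw),
            gen_dose_response({"em": 100, "basal": 0, "n": 1, "log_R": 6.5, "log_KA": -5.5},
                              GRID8, 1, 0.0, 2 * i + 1, model="operational", ligand_id="test", pathway_id=pw),
        ]
        fits[pw] = fit_operational_global(curves, "ref")
    table = bias_table_from_fits(fits, "ref", "ref")
    for pw in ("Gq", "pERK"):
        assert table.delta[pw].value == 0.0
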