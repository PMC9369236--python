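"""Hall–Ross QENS model, convolution, EISF extraction and global fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit
from scipy.special import voigt_profile
from scipy.stats import chi2 as chi2_dist

from piezodyn import (
    CONSTANTS,
    Condition,
    QensDataset,
    convolve_resolution,
    extract_eisf,
    fit_qens_global,
    hall_ross_hwhm,
    lorentzian,
    model_free_fit,
    qens_model,
)
from piezodyn import synthetic_data as sd
from piezodyn.eisf_geometry import EisfParams, eisf_model
from piezodyn.qens_fit import EisfCurve, HallRossParams
from piezodyn.studies import poisson_spectrum as poisson_qens

OMEGA = np.round(np.arange(-1.5, 1.5 + 1e-9, 0.02), 6)
D_OMEGA = 0.02


def gaussian_profile(omega, sigma=0.03):
    prof = np.exp(-(omega**2) / (2 * sigma**2))
    return prof / (prof.sum() * (omega[1] - omega[0]))


def test_hall_ross_zero_at_q_zero():
    assert hall_ross_hwhm(0.0, 1.0, 1.0) == 0.0


def test_hall_ross_saturates_at_hbar_over_tau():
    assert hall_ross_hwhm(100.0, 1.0, 1.0) == pytest.approx(CONSTANTS.hbar, rel=1e-10)


def test_hall_ross_scalar_oracle():
    # τ = 1 ps, ⟨l⟩ = 1 Å, q = 1 Å⁻¹ → ħ·(1 − e^(−1/2)), frozen via sympy
    assert hall_ross_hwhm(1.0, 1.0, 1.0) == pytest.approx(
        0.25898620206229410, rel=1e-12
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(tau=st.floats(0.1, 50.0), ell=st.floats(0.1, 5.0))
def test_hall_ross_monotone_and_bounded(tau, ell):
    q = np.linspace(0.0, 10.0, 200)
    g = hall_ross_hwhm(q, tau, ell)
    assert np.all(np.diff(g) >= -1e-15)
    assert np.all(g <= CONSTANTS.hbar / tau + 1e-12)


def _params(**kw):
    base = dict(tau=2.0, jump_len=1.2, gamma_loc=0.3, scale_amp=1.0, dw_msd=0.0)
    base.update(kw)
    return HallRossParams(**base)


def test_model_merges_to_single_lorentzian_when_gamma_loc_zero():
    q = np.array([1.0])
    gj = hall_ross_hwhm(1.0, 2.0, 1.2)
    model = qens_model(q, OMEGA, [0.4], _params(gamma_loc=0.0))
    assert np.allclose(model[0], lorentzian(OMEGA, gj), rtol=1e-12)


def test_model_single_lorentzian_when_a0_is_one():
    q = np.array([1.0])
    gj = hall_ross_hwhm(1.0, 2.0, 1.2)
    model = qens_model(q, OMEGA, [1.0], _params())
    assert np.allclose(model[0], lorentzian(OMEGA, gj), rtol=1e-12)


def test_unscaled_model_has_unit_area():
    from scipy.integrate import quad

    area, _ = quad(
        lambda w: qens_model([1.0], [w], [0.6], _params())[0, 0],
        -np.inf, np.inf, limit=400,
    )
    assert area == pytest.approx(1.0, abs=1e-6)


def test_delta_resolution_is_identity():
    res = np.zeros_like(OMEGA)
    res[(OMEGA.size - 1) // 2] = 1.0 / D_OMEGA
    model = lorentzian(OMEGA, 0.2)
    conv = convolve_resolution(model, res, D_OMEGA)
    assert np.allclose(conv, model, rtol=1e-10)


def test_lorentzian_convolution_sums_hwhms():
    res = lorentzian(OMEGA, 0.07)
    res = res / (res.sum() * D_OMEGA)
    conv = convolve_resolution(lorentzian(OMEGA, 0.1), res, D_OMEGA)

    def lor(w, a, g):
        return a * g / np.pi / (g**2 + w**2)

    popt, _ = curve_fit(lor, OMEGA, conv, p0=[1.0, 0.15])
    assert popt[1] == pytest.approx(0.17, rel=5e-3)


def test_gaussian_convolution_matches_voigt_at_peak():
    sigma = 0.03  # 30 µeV Gaussian resolution
    conv = convolve_resolution(lorentzian(OMEGA, 0.1), gaussian_profile(OMEGA, sigma),
                               D_OMEGA)
    i0 = (OMEGA.size - 1) // 2
    expected = voigt_profile(0.0, sigma, 0.1)
    assert conv[i0] == pytest.approx(expected, rel=1e-4)


def test_convolution_linear_and_area_preserving():
    res = gaussian_profile(OMEGA)
    a = lorentzian(OMEGA, 0.1)
    b = lorentzian(OMEGA, 0.4)
    ca = convolve_resolution(a, res, D_OMEGA)
    cb = convolve_resolution(b, res, D_OMEGA)
    cab = convolve_resolution(2.0 * a + 3.0 * b, res, D_OMEGA)
    assert np.allclose(cab, 2.0 * ca + 3.0 * cb, rtol=1e-10)
    # area preservation to 1e-6 is well-posed for models vanishing at the
    # window edge (Lorentzian wings exchange ~1e-4 mass across it)
    compact = np.exp(-(OMEGA**2) / (2 * 0.2**2))
    conv = convolve_resolution(compact, res, D_OMEGA)
    assert conv.sum() * D_OMEGA == pytest.approx(compact.sum() * D_OMEGA, abs=1e-6)


def _resolution_only_spectrum():
    res = gaussian_profile(OMEGA, 0.0297)  # ≈70 µeV HWHM
    return QensDataset(
        q=np.array([1.0]), omega=OMEGA, s_qw=res[None, None, :],
        sigma=np.full((1, 1, OMEGA.size), 1e-4),
        resolution=res[None, :], conditions=[Condition(300.0, 1.0)],
    )


def test_eisf_of_pure_elastic_spectrum():
    spec = _resolution_only_spectrum()
    curve = extract_eisf(spec, correct_bias=False)
    # raw ratio equals the resolution's own enclosed fraction in 1 FWHM
    fwhm = 2 * 0.0297 * np.sqrt(2 * np.log(2))
    inner = np.abs(OMEGA) <= fwhm
    enclosed = spec.s_qw[0, 0, inner].sum() / spec.s_qw[0, 0].sum()
    assert curve.a0_raw[0] == pytest.approx(enclosed, rel=1e-6)
    full = extract_eisf(spec, elastic_window=2.0, correct_bias=False)
    assert full.a0[0] == pytest.approx(1.0, abs=1e-12)


def test_eisf_of_broad_lorentzian_matches_analytic_fraction():
    gamma, w = 1.2, 0.1  # HWHM ≫ window
    s = lorentzian(OMEGA, gamma)
    spec = QensDataset(
        q=np.array([1.0]), omega=OMEGA, s_qw=s[None, None, :],
        sigma=np.full((1, 1, OMEGA.size), 1e-4),
        resolution=gaussian_profile(OMEGA)[None, :],
        conditions=[Condition(300.0, 1.0)],
    )
    curve = extract_eisf(spec, elastic_window=w, correct_bias=False)
    grid_total = np.arctan(1.51 / gamma)  # spectrum is truncated at the window edge
    expected = np.arctan((w + 0.01) / gamma) / grid_total
    assert curve.a0_raw[0] == pytest.approx(expected, rel=0.02)


def test_eisf_extraction_recovers_known_a0_after_bias_correction(qens_truth, rng):
    spec = sd.qens_reference(qens_truth)
    a0_true = eisf_model(spec.q, qens_truth.eisf)
    j = int(np.argmin(np.abs(a0_true - 0.6)))  # channel generated at A0 ≈ 0.6
    noisy = poisson_qens(spec, 1e4, rng)
    curve = extract_eisf(noisy)
    assert abs(curve.a0[j] - a0_true[j]) < 0.05


def test_model_free_selects_single_lorentzian(rng):
    s = convolve_resolution(lorentzian(OMEGA, 0.25), gaussian_profile(OMEGA), D_OMEGA)
    sig = np.full_like(s, s.max() / 100)
    spec = QensDataset(
        q=np.array([0.8, 1.2, 1.6]), omega=OMEGA,
        s_qw=np.tile(s + rng.normal(0, sig), (1, 3, 1)),
        sigma=np.tile(sig, (1, 3, 1)),
        resolution=np.tile(gaussian_profile(OMEGA), (3, 1)),
        conditions=[Condition(300.0, 1.0)],
    )
    fit = model_free_fit(spec, max_components=2)
    assert fit.n_components == 1


def test_model_free_identifies_two_components(qens_reference_set, rng):
    chosen = []
    q_sub = slice(0, 7, 2)  # 4 q channels keep the survey fast
    ref = qens_reference_set
    for _ in range(20):
        s = ref.s_qw[0, q_sub]
        sig = (s.max(axis=1, keepdims=True) / 50) * np.ones_like(s)  # SNR 50
        spec = QensDataset(
            q=ref.q[q_sub], omega=ref.omega,
            s_qw=(s + rng.normal(0, sig))[None], sigma=sig[None],
            resolution=ref.resolution[q_sub], conditions=list(ref.conditions),
        )
        fit = model_free_fit(spec, max_components=3)
        chosen.append(fit.n_components)
    assert sum(n == 2 for n in chosen) >= 18  # ≥90%


def test_model_free_broad_component_is_flat(qens_reference_set, rng):
    ref = qens_reference_set
    s = ref.s_qw[0]
    sig = (s.max(axis=1, keepdims=True) / 100) * np.ones_like(s)
    spec = QensDataset(
        q=ref.q, omega=ref.omega, s_qw=(s + rng.normal(0, sig))[None],
        sigma=sig[None], resolution=ref.resolution, conditions=list(ref.conditions),
    )
    fit = model_free_fit(spec, max_components=2)
    broad = fit.component_trends[-1]
    assert broad["trend"] == "flat"
    assert abs(broad["slope"]) < 2.0 * broad["slope_err"]


def test_noiseless_global_fit_recovers_truth(qens_truth, qens_reference_set):
    a0 = eisf_model(qens_reference_set.q, qens_truth.eisf)
    eisf = EisfCurve(q=qens_reference_set.q, a0=a0,
                     sigma=np.full(a0.size, 1e-3))
    fit = fit_qens_global(qens_reference_set, eisf)
    assert fit.tau == pytest.approx(qens_truth.tau, rel=1e-4)
    assert fit.jump_len == pytest.approx(qens_truth.jump_len, rel=1e-4)
    assert fit.gamma_loc == pytest.approx(qens_truth.gamma_loc, rel=1e-4)


def test_generate_convolve_fit_identity_for_random_draws(rng):
    """Noiseless pipeline identity over random parameter draws."""
    for _ in range(20):
        truth = sd.QensTruth(
            tau=float(rng.uniform(0.5, 10.0)),
            jump_len=float(rng.uniform(0.5, 2.5)),
            gamma_loc=float(rng.uniform(0.1, 1.0)),
            dw_msd=float(rng.uniform(0.0, 0.2)),
        )
        spec = sd.qens_reference(truth)
        a0 = eisf_model(spec.q, truth.eisf)
        eisf = EisfCurve(q=spec.q, a0=a0, sigma=np.full(a0.size, 1e-3))
        fit = fit_qens_global(spec, eisf)
        assert fit.tau == pytest.approx(truth.tau, rel=1e-3)
        assert fit.jump_len == pytest.approx(truth.jump_len, rel=1e-3)
        assert fit.gamma_loc == pytest.approx(truth.gamma_loc, rel=1e-3)


def test_joint_tau_jump_confidence_region_covers_truth(qens_truth, qens_reference_set, rng):
    """The reported τ–⟨l⟩ covariance gives honest joint 2σ coverage."""
    level = chi2_dist.ppf(0.9545, 2)
    covered = 0
    for _ in range(20):
        noisy = poisson_qens(qens_reference_set, 1e4, rng)
        eisf = extract_eisf(noisy)
        fit = fit_qens_global(noisy, eisf)
        delta = np.array([
            np.log(qens_truth.tau) - np.log(fit.tau),
            np.log(qens_truth.jump_len) - np.log(fit.jump_len),
        ])
        cov2 = fit.cov_log[:2, :2]
        m = float(delta @ np.linalg.solve(cov2, delta))
        covered += m <= level
        assert np.isfinite(fit.corr_tau_jump)
    assert covered >= 18
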