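"""Quasi-elastic spectral analysis: Hall–Ross jump-diffusion global fitting.

The scattering law combines an "elastic" fraction A0(q) (the elastic
incoherent structure factor) carried by the jump-diffusion Lorentzian, and a
quasi-elastic fraction broadened additionally by fast localized motions:

    S(q, ω) = A0(q)·L(ω; Γj(q)) + (1 − A0(q))·L(ω; Γj(q) + Γloc)

with unit-area Lorentzians L(ω; Γ) = (1/π)·Γ/(Γ² + ω²) and the Hall–Ross
half-width at half-maximum for jump diffusion with Gaussian-distributed jump
lengths:

    Γj(q) = (ħ/τ)·[1 − exp(−q²·⟨l⟩²/2)]

τ is the residence time between jumps (ps) and ⟨l⟩ the mean jump length (Å);
Γj saturates at ħ/τ for large q, while Γloc is q-independent (methyl-group
rotation and similar localized motions).  The model is convolved with the
measured resolution function and scaled by a q-dependent Debye–Waller-like
amplitude scale·exp(−q²·⟨u²⟩) before comparison with data.  A0(q) is fixed
from a direct integration of the spectra, leaving three physical free
parameters (Γloc, τ, ⟨l⟩) plus the amplitude pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .constants import CONSTANTS
from .data_model import Condition, QensDataset, ValidationError
from .eins_twostate import fit_covariance


@dataclass
class HallRossParams:
    """Fitted QENS parameters at one (T, P) condition."""

    tau: float  # ps
    jump_len: float  # Å
    gamma_loc: float  # meV
    scale_amp: float = 1.0
    dw_msd: float = 0.0  # Å²
    condition: Condition = None  # type: ignore[assignment]
    uncertainties: dict = field(default_factory=dict)
    chi2_red: float = np.nan
    corr_tau_jump: float = np.nan
    cov_log: np.ndarray = None  # type: ignore[assignment]
    param_names: tuple = ()

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.jump_len <= 0:
            raise ValidationError("tau and jump_len must be positive")
        if self.gamma_loc < 0:
            raise ValidationError("gamma_loc must be non-negative")


@dataclass
class EisfCurve:
    """Extracted elastic incoherent structure factor A0(q)."""

    q: np.ndarray
    a0: np.ndarray
    sigma: np.ndarray
    condition: Condition = None  # type: ignore[assignment]
    a0_raw: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.a0 = np.asarray(self.a0, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.a0_raw is None:
            self.a0_raw = self.a0.copy()
        if np.any(self.a0 < -2 * self.sigma) or np.any(self.a0 > 1 + 2 * self.sigma):
            raise ValidationError("a0 must lie in [0, 1] within error")


@dataclass
class ModelFreeFit:
    """Survey fit of an elastic line plus free Lorentzians, per q."""

    n_components: int
    criterion: dict  # n -> summed AICc
    hwhm: np.ndarray  # (n_q, n_components), sorted narrow→broad
    amplitude: np.ndarray  # (n_q, n_components)
    elastic_amplitude: np.ndarray  # (n_q,)
    q: np.ndarray
    component_trends: list = field(default_factory=list)
    failed_q: list = field(default_factory=list)


def hall_ross_hwhm(q, tau: float, jump_len: float):
    """Hall–Ross HWHM Γj(q) = (ħ/τ)·[1 − exp(−q²⟨l⟩²/2)] in meV."""
    if tau <= 0:
        raise ValidationError("tau must be positive")
    q = np.asarray(q, dtype=float)
    return (CONSTANTS.hbar / tau) * (1.0 - np.exp(-(q**2) * jump_len**2 / 2.0))


def lorentzian(omega, hwhm: float):
    """Unit-area Lorentzian with half-width at half-maximum ``hwhm``."""
    if hwhm < 0:
        raise ValidationError("Lorentzian width must be non-negative")
    omega = np.asarray(omega, dtype=float)
    return (hwhm / np.pi) / (hwhm**2 + omega**2)


def qens_model(q, omega, a0, params: HallRossParams):
    """Model S(q, ω) on a grid, including the Debye–Waller amplitude.

    Returns an (n_q, n_ω) array.  The unscaled spectral shape integrates to 1
    over ω for every q; the applied scale is scale_amp·exp(−q²·dw_msd).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    a0 = np.atleast_1d(np.asarray(a0, dtype=float))
    if np.any((a0 < 0) | (a0 > 1)):
        raise ValidationError("a0 must lie in [0, 1]")
    shape = _qens_shape(q, np.asarray(omega, dtype=float), a0,
                        params.tau, params.jump_len, params.gamma_loc)
    amp = params.scale_amp * np.exp(-(q**2) * params.dw_msd)
    return amp[:, None] * shape


def _qens_shape(q, omega, a0, tau, jump_len, gamma_loc):
    gj = hall_ross_hwhm(q, tau, jump_len)[:, None]
    gb = gj + gamma_loc
    om2 = omega[None, :] ** 2
    narrow = (gj / np.pi) / (gj**2 + om2)
    broad = (gb / np.pi) / (gb**2 + om2)
    return a0[:, None] * narrow + (1.0 - a0[:, None]) * broad


def convolve_resolution(model, resolution, d_omega: float):
    """Discrete convolution of a model with area-normalized resolution profiles.

    Both arrays live on the same even ω grid (last axis); profiles are assumed
    centred on ω = 0 of a symmetric grid.  The full linear convolution is
    computed with zero padding and cropped back to the analysis window, which
    preserves the model area up to the resolution mass lost past the window
    edges (≲1e-6 for instrument-like profiles).
    """
    model = np.asarray(model, dtype=float)
    resolution = np.asarray(resolution, dtype=float)
    if model.shape[-1] != resolution.shape[-1]:
        raise ValidationError("model and resolution must share the omega grid")
    n = model.shape[-1]
    i0 = (n - 1) // 2  # index of ω = 0 on a symmetric odd grid
    full = fftconvolve(model, resolution, mode="full", axes=-1)
    return full[..., i0 : i0 + n] * d_omega


def _resolution_fwhm(omega, profile):
    """Numerical FWHM of a single resolution profile via half-max crossings."""
    peak = profile.max()
    half = peak / 2.0
    above = profile >= half
    idx = np.where(above)[0]
    lo, hi = idx[0], idx[-1]

    def _cross(i_out, i_in):
        x0, x1 = omega[i_out], omega[i_in]
        y0, y1 = profile[i_out], profile[i_in]
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    left = omega[lo] if lo == 0 else _cross(lo - 1, lo)
    right = omega[hi] if hi == len(omega) - 1 else _cross(hi + 1, hi)
    return right - left


def extract_eisf(
    spectrum: QensDataset,
    elastic_window: float | None = None,
    correct_bias: bool = True,
) -> EisfCurve:
    """A0(q) from integration of the elastic region over the total integral.

    Per q channel, A0 = ∫_{|ω|≤w} S dω / ∫ S dω with the half-width ``w``
    defaulting to one resolution FWHM at that q.  The raw ratio is biased
    because both spectral components leak across the window; with
    ``correct_bias`` the enclosed fractions of a light two-Lorentzian pre-fit
    are used to invert  raw = A0·E_narrow + (1 − A0)·E_broad.
    """
    if spectrum.s_qw.shape[0] != 1:
        raise ValidationError("extract_eisf expects a single-condition dataset")
    omega, dw = spectrum.omega, spectrum.d_omega
    s, sig = spectrum.s_qw[0], spectrum.sigma[0]
    n_q = spectrum.q.size

    a0_raw = np.zeros(n_q)
    a0_err = np.zeros(n_q)
    a0_corr = np.zeros(n_q)
    for i in range(n_q):
        w = elastic_window
        if w is None:
            w = _resolution_fwhm(omega, spectrum.resolution[i])
        inner = np.abs(omega) <= w + 1e-12
        n_sum = s[i, inner].sum() * dw
        d_sum = s[i].sum() * dw
        if d_sum <= 0:
            a0_raw[i] = np.nan
            a0_err[i] = np.inf
            a0_corr[i] = np.nan
            continue
        m_sum = d_sum - n_sum
        var_n = (sig[i, inner] ** 2).sum() * dw**2
        var_m = (sig[i, ~inner] ** 2).sum() * dw**2
        raw = n_sum / d_sum
        err = np.sqrt(m_sum**2 * var_n + n_sum**2 * var_m) / d_sum**2
        a0_raw[i] = raw
        a0_err[i] = max(err, 1e-12)

        if correct_bias:
            g_n, g_b, cov_g = _two_lorentz_widths(omega, dw, s[i], sig[i],
                                                  spectrum.resolution[i])

            def corrected(gn, gb):
                u, big_u = _window_integrals(omega, dw, gn,
                                             spectrum.resolution[i], w)
                v, big_v = _window_integrals(omega, dw, gb,
                                             spectrum.resolution[i], w)
                # invert raw = (A0·u + (1−A0)·v) / (A0·U + (1−A0)·V)
                denom = u - v - raw * (big_u - big_v)
                if abs(denom) <= 1e-3:
                    return raw, 1.0
                damp = (big_v * denom
                        + (raw * big_v - v) * (big_u - big_v)) / denom**2
                return (raw * big_v - v) / denom, damp

            a0_corr[i], damp = corrected(g_n, g_b)
            # error budget: amplified raw-ratio noise plus the pre-fit
            # width uncertainties pushed through the inversion
            hn, hb = max(0.02 * g_n, 1e-4), max(0.02 * g_b, 1e-4)
            d_dgn = (corrected(g_n + hn, g_b)[0] - a0_corr[i]) / hn
            d_dgb = (corrected(g_n, g_b + hb)[0] - a0_corr[i]) / hb
            grad = np.array([d_dgn, d_dgb])
            var_widths = float(grad @ cov_g @ grad)
            a0_err[i] = np.sqrt((damp * a0_err[i]) ** 2
                                + max(var_widths, 0.0))
        else:
            a0_corr[i] = raw

    a0 = np.clip(a0_corr, 0.0, 1.0)
    return EisfCurve(
        q=spectrum.q, a0=a0, sigma=np.minimum(a0_err, 1.0),
        condition=spectrum.conditions[0], a0_raw=a0_raw,
    )


def _window_integrals(omega, dw, hwhm, resolution, window):
    """(inside-window, whole-grid) integrals of a unit convolved Lorentzian."""
    conv = convolve_resolution(lorentzian(omega, hwhm), resolution, dw)
    inner = np.abs(omega) <= window + 1e-12
    return conv[inner].sum() * dw, conv.sum() * dw


def _two_lorentz_widths(omega, dw, s, sig, resolution):
    """Light per-q pre-fit of two convolved Lorentzians.

    Returns the two HWHMs (narrow first) and their 2×2 covariance.
    """
    area = max(s.sum() * dw, 1e-12)

    def resid(p):
        frac = 1.0 / (1.0 + np.exp(-p[0]))  # logistic keeps frac in (0,1)
        g1, g2 = np.exp(p[1]), np.exp(p[2])
        model = np.exp(p[3]) * (frac * lorentzian(omega, g1)
                                + (1 - frac) * lorentzian(omega, g2))
        return (convolve_resolution(model, resolution, dw) - s) / sig

    p0 = np.array([0.5, np.log(0.05), np.log(0.5), np.log(area)])
    res = least_squares(resid, p0, max_nfev=200)
    g1, g2 = np.exp(res.x[1]), np.exp(res.x[2])
    dof = max(omega.size - 4, 1)
    chi2_red = 2.0 * res.cost / dof
    cov_log = fit_covariance(res.jac, max(chi2_red, 1.0))[1:3, 1:3]
    cov_g = cov_log * np.outer([g1, g2], [g1, g2])  # delta method
    if g1 <= g2:
        return g1, g2, cov_g
    return g2, g1, cov_g[::-1, ::-1]


def _aicc(chi2: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return chi2 + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def model_free_fit(spectrum: QensDataset, max_components: int = 3) -> ModelFreeFit:
    """Survey fit: resolution-shaped elastic line + n free Lorentzians per q.

    Fits n = 1…max_components, reports the summed small-sample-corrected AIC
    per n, and classifies each component's HWHM(q) trend as q-independent
    (flat) or saturating (Hall–Ross-shaped) by comparing both trend models.
    """
    if max_components not in (1, 2, 3):
        raise ValidationError("max_components must be 1, 2 or 3")
    if spectrum.s_qw.shape[0] != 1:
        raise ValidationError("model_free_fit expects a single-condition dataset")
    omega, dw = spectrum.omega, spectrum.d_omega
    n_q, n_w = spectrum.q.size, omega.size
    s_all, sig_all = spectrum.s_qw[0], spectrum.sigma[0]

    results = {}
    crit = {}
    failed: dict[int, list] = {}
    for n in range(1, max_components + 1):
        widths = np.full((n_q, n), np.nan)
        amps = np.full((n_q, n), np.nan)
        eamp = np.full(n_q, np.nan)
        chi2_total = 0.0
        failed[n] = []
        for i in range(n_q):
            s, sig, res_prof = s_all[i], sig_all[i], spectrum.resolution[i]
            area = max(s.sum() * dw, 1e-12)

            def resid(p):
                model = p[0] * res_prof
                for j in range(n):
                    model = model + p[1 + 2 * j] * convolve_resolution(
                        lorentzian(omega, p[2 + 2 * j]), res_prof, dw
                    )
                return (model - s) / sig

            # deterministic width ladder for the starts
            g0 = [0.05 * 4**j for j in range(n)]
            p0 = np.concatenate([[0.1 * area],
                                 np.array([[area / n, g] for g in g0]).ravel()])
            lb = np.zeros(1 + 2 * n)
            lb[2::2] = 1e-5
            ub = np.full(1 + 2 * n, np.inf)
            ub[2::2] = 50.0
            try:
                fit = least_squares(resid, p0, bounds=(lb, ub), max_nfev=300)
            except Exception:
                failed[n].append(i)
                continue
            order = np.argsort(fit.x[2::2])
            widths[i] = fit.x[2::2][order]
            amps[i] = fit.x[1::2][order]
            eamp[i] = fit.x[0]
            chi2_total += _aicc(2.0 * fit.cost, 1 + 2 * n, n_w)
        results[n] = (widths, amps, eamp)
        crit[n] = chi2_total

    n_best = min(crit, key=crit.get)
    widths, amps, eamp = results[n_best]

    trends = []
    for j in range(n_best):
        ok = np.isfinite(widths[:, j])
        trends.append(_classify_trend(spectrum.q[ok], widths[ok, j]))

    return ModelFreeFit(
        n_components=n_best, criterion=crit,
        hwhm=widths, amplitude=amps, elastic_amplitude=eamp,
        q=spectrum.q, component_trends=trends, failed_q=failed[n_best],
    )


def _classify_trend(q, g):
    """Flat vs saturating classification of a HWHM(q) series."""
    n = q.size
    resid_flat = g - g.mean()
    chi_flat = float(resid_flat @ resid_flat)

    def hr_resid(p):
        return (CONSTANTS.hbar / np.exp(p[0])) * (
            1.0 - np.exp(-(q**2) * np.exp(2 * p[1]) / 2.0)
        ) - g

    fit = least_squares(hr_resid, [np.log(CONSTANTS.hbar / max(g.max(), 1e-6)),
                                   np.log(1.0)], max_nfev=200)
    chi_sat = 2.0 * fit.cost
    # linear slope diagnostic with its standard error
    A = np.vstack([np.ones(n), q]).T
    coef, res_ss, *_ = np.linalg.lstsq(A, g, rcond=None)
    dof = max(n - 2, 1)
    s2 = (res_ss[0] if res_ss.size else 0.0) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    # widths carry no error bars here, so compare scale-invariant
    # Gaussian-likelihood AICc terms n·ln(RSS/n) instead of raw RSS
    tiny = 1e-30
    ll_flat = n * np.log(max(chi_flat, tiny) / n)
    ll_sat = n * np.log(max(chi_sat, tiny) / n)
    label = "flat" if _aicc(ll_flat, 1, n) <= _aicc(ll_sat, 2, n) else "saturating"
    return {
        "trend": label,
        "slope": float(coef[1]),
        "slope_err": float(np.sqrt(max(cov[1, 1], 0.0))),
    }


#: Deterministic multi-start decades for (τ/ps, ⟨l⟩/Å, Γloc/meV).
START_GRID_TAU = (0.2, 2.0, 20.0)
START_GRID_L = (0.3, 1.0, 3.0)
START_GRID_GLOC = (0.03, 0.3, 3.0)


def fit_qens_global(
    spectrum: QensDataset,
    eisf: EisfCurve,
    fix_dw: float | None = None,
    adequate_stop: bool = True,
) -> HallRossParams:
    """Global weighted fit of the whole S(q, ω) map at one condition.

    A0(q) is fixed from ``eisf``; free parameters are (Γloc, τ, ⟨l⟩) plus an
    overall amplitude and a Debye–Waller MSD (frozen when ``fix_dw`` is
    given).  Internally positive parameters are fitted in log space; starts
    come from a deterministic 3×3×3 grid over parameter decades, abandoned
    early once a start reaches a statistically adequate χ².
    """
    if spectrum.s_qw.shape[0] != 1:
        raise ValidationError("fit_qens_global expects a single-condition dataset")
    if spectrum.q.size < 5:
        raise ValidationError("need at least 5 q channels")
    if eisf.q.shape != spectrum.q.shape or not np.allclose(eisf.q, spectrum.q):
        raise ValidationError("EISF curve q grid must match the spectrum")

    q, omega, dw = spectrum.q, spectrum.omega, spectrum.d_omega
    s, sig = spectrum.s_qw[0], spectrum.sigma[0]
    a0 = np.clip(eisf.a0, 0.0, 1.0)
    res_prof = spectrum.resolution

    # seed amplitude and Debye-Waller slope from per-q areas
    areas = np.clip(s.sum(axis=1) * dw, 1e-12, None)
    slope, intercept = np.polyfit(q**2, np.log(areas), 1)
    dw0 = fix_dw if fix_dw is not None else float(np.clip(-slope, 0.0, 2.0))
    scale0 = float(np.exp(intercept))

    free_dw = fix_dw is None

    def unpack(p):
        tau, jl, gl = np.exp(p[0]), np.exp(p[1]), np.exp(p[2])
        scale = np.exp(p[3])
        dw_msd = p[4] if free_dw else fix_dw
        return tau, jl, gl, scale, dw_msd

    def residuals(p):
        tau, jl, gl, scale, dw_msd = unpack(p)
        shape = _qens_shape(q, omega, a0, tau, jl, gl)
        model = convolve_resolution(shape, res_prof, dw)
        amp = scale * np.exp(-(q**2) * dw_msd)
        return ((amp[:, None] * model - s) / sig).ravel()

    n_par = 5 if free_dw else 4
    dof = s.size - n_par
    adequate = dof + 3.0 * np.sqrt(2.0 * dof)
    lb = np.concatenate([np.log([1e-2, 5e-2, 1e-4, 1e-12]), [0.0] if free_dw else []])
    ub = np.concatenate([np.log([1e3, 20.0, 50.0, 1e12]), [5.0] if free_dw else []])

    best = None
    for t0, l0, g0 in itertools.product(START_GRID_TAU, START_GRID_L, START_GRID_GLOC):
        p0 = np.concatenate([np.log([t0, l0, g0, scale0]), [dw0] if free_dw else []])
        p0 = np.clip(p0, lb + 1e-9, ub - 1e-9)
        try:
            fit = least_squares(residuals, p0, bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
        except Exception:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
        if adequate_stop and 2.0 * best.cost <= adequate:
            break
    if best is None:
        raise RuntimeError("QENS global fit failed from every start")

    chi2 = 2.0 * best.cost
    chi2_red = chi2 / dof
    tau, jl, gl, scale, dw_msd = unpack(best.x)

    cov = fit_covariance(best.jac, chi2_red)
    # the fixed A0(q) carry extraction errors that dominate the parameter
    # uncertainty; propagate them through the fit's sensitivity
    # dp/da0 = −(JᵀJ)⁻¹ Jᵀ (∂r/∂a0)
    sigma_a0 = np.clip(np.asarray(eisf.sigma, dtype=float), 0.0, 1.0)
    if np.any(sigma_a0 > 0):
        r0 = residuals(best.x)
        dr_da0 = np.empty((r0.size, a0.size))
        for j in range(a0.size):
            step_j = 1e-4
            a0[j] += step_j
            dr_da0[:, j] = (residuals(best.x) - r0) / step_j
            a0[j] -= step_j
        jtj_inv = fit_covariance(best.jac, 1.0)
        sens = -jtj_inv @ (best.jac.T @ dr_da0)
        cov = cov + (sens * sigma_a0**2) @ sens.T
    perr_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    unc = {
        "tau": tau * perr_log[0],
        "jump_len": jl * perr_log[1],
        "gamma_loc": gl * perr_log[2],
        "scale_amp": scale * perr_log[3],
        "dw_msd": perr_log[4] if free_dw else 0.0,
    }
    denom = np.sqrt(cov[0, 0] * cov[1, 1])
    corr = float(cov[0, 1] / denom) if denom > 0 else np.nan
    names = ("log_tau", "log_jump_len", "log_gamma_loc", "log_scale") + (
        ("dw_msd",) if free_dw else ()
    )
    return HallRossParams(
        tau=tau, jump_len=jl, gamma_loc=gl, scale_amp=scale, dw_msd=dw_msd,
        condition=spectrum.conditions[0], uncertainties=unc,
        chi2_red=chi2_red, corr_tau_jump=corr, cov_log=cov, param_names=names,
    )
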