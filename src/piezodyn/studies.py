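"""End-to-end validation studies on synthetic ground truth.

Each function runs one complete study — generate data with known truth,
push it through the pipeline, measure the outcome — and returns plain
numbers.  They are used by the test suite and by ``scripts/acceptance.py``
to quantify what the pipeline recovers under controlled conditions:
reduction-chain exactness, parameter-recovery error under counting noise,
convolution accuracy against closed forms, thermal-law classification rates
and MSD-breakpoint detection rates.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import voigt_profile

from . import synthetic_data as sd
from .constants import CONSTANTS
from .eins_twostate import MsdCurve, fit_two_state_global
from .eisf_geometry import EisfParams, eisf_model, fit_eisf
from .qens_fit import EisfCurve, convolve_resolution, extract_eisf, fit_qens_global, lorentzian
from .reduction import reduce_elastic, reduce_qens
from .seq_compare import align_pair, enumerate_substitutions, synthetic_ortholog_pair
from .thermal_models import detect_breakpoint, select_thermal_law


def end_to_end_identity(seed: int = 0) -> dict:
    """Noiseless generate→reduce round trip for elastic and QENS chains.

    Raw data carry backgrounds, transmissions, detector efficiency and (for
    QENS) the detailed-balance asymmetry; the reduction chain must return
    the reference spectra exactly.  Errors are relative to the reference
    maximum.
    """
    truth = sd.preset_profiles("piezophile_like", seed=seed)
    truth.noise = sd.NoiseSpec(model="none")

    out = sd.generate_elastic_dataset(truth, seed=seed)
    red = reduce_elastic(out["sample"], out["empty_cell"], out["buffer"],
                         out["vanadium"],
                         displaced_fraction=truth.backgrounds.displaced_fraction)
    ref = out["reference"]
    el_err = float(np.max(np.abs(red.intensity - ref.intensity))
                   / np.max(ref.intensity))

    truth.qens = {k: truth.qens[k] for k in sorted(truth.qens)[:3]}
    out = sd.generate_qens_dataset(truth, seed=seed)
    red = reduce_qens(out["sample"], out["empty_cell"], out["buffer"],
                      out["vanadium"],
                      displaced_fraction=truth.backgrounds.displaced_fraction)
    ref = out["reference"]
    q_err = float(np.max(np.abs(red.s_qw - ref.s_qw)) / np.max(ref.s_qw))
    return {"elastic": el_err, "qens": q_err,
            "n": int(ref.s_qw.size + out["reference"].s_qw.size)}


def eins_recovery(n_replicates: int = 50, noise_frac: float = 0.02,
                  seed: int = 0) -> dict:
    """Two-state recovery: 9 temperatures × 25 q points, multiplicative noise.

    Returns median absolute recovery errors (percent) for d, ΔH and ΔS over
    seeded replicates.
    """
    truth = sd.ElasticTruth(d=1.4, dH=12.0, dS=25.0)
    ref = sd.elastic_reference(truth)  # 9 T × 25 q defaults
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_replicates):
        noisy = sd.add_multiplicative_noise(ref, noise_frac, rng)
        fit = fit_two_state_global(noisy)
        errs.append([abs(fit.d - truth.d) / truth.d,
                     abs(fit.dH - truth.dH) / truth.dH,
                     abs(fit.dS - truth.dS) / truth.dS])
    med = np.median(np.asarray(errs), axis=0) * 100.0
    return {"d_pct": float(med[0]), "dH_pct": float(med[1]),
            "dS_pct": float(med[2]), "n": n_replicates}


def poisson_spectrum(reference, counts, rng):
    """Poisson counting noise with ~``counts`` total counts per q channel."""
    from .data_model import QensDataset

    s = reference.s_qw[0]
    n0_q = counts / (s.sum(axis=1) * reference.d_omega)
    cts = rng.poisson(s * n0_q[:, None])
    return QensDataset(
        q=reference.q, omega=reference.omega,
        s_qw=(cts / n0_q[:, None])[None],
        sigma=(np.sqrt(np.maximum(cts, 1.0)) / n0_q[:, None])[None],
        resolution=reference.resolution, conditions=list(reference.conditions),
    )


def qens_recovery(n_replicates: int = 20, counts: float = 1e4,
                  seed: int = 0) -> dict:
    """Hall–Ross global-fit recovery under Poisson counting noise.

    ~``counts`` total counts per q channel; A0(q) is extracted from each
    noisy spectrum (not taken from truth).  Returns median absolute recovery
    errors (percent) for τ, ⟨l⟩ and Γloc.
    """
    truth = sd.QensTruth(tau=2.0, jump_len=1.2, gamma_loc=0.3)
    ref = sd.qens_reference(truth)
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_replicates):
        spec = poisson_spectrum(ref, counts, rng)
        eisf = extract_eisf(spec)
        fit = fit_qens_global(spec, eisf)
        errs.append([abs(fit.tau - truth.tau) / truth.tau,
                     abs(fit.jump_len - truth.jump_len) / truth.jump_len,
                     abs(fit.gamma_loc - truth.gamma_loc) / truth.gamma_loc])
    med = np.median(np.asarray(errs), axis=0) * 100.0
    return {"tau_pct": float(med[0]), "jump_len_pct": float(med[1]),
            "gamma_loc_pct": float(med[2]), "n": n_replicates}


def eisf_recovery(n_replicates: int = 50, noise_frac: float = 0.05,
                  seed: int = 0) -> dict:
    """Geometry-model recovery of the confinement radius at 5% noise."""
    truth = EisfParams(p_immobile=0.3, s_confined=0.5, radius=3.0)
    q = np.linspace(0.6, 1.8, 13)
    a0 = eisf_model(q, truth)
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_replicates):
        noisy = np.clip(a0 * (1 + noise_frac * rng.standard_normal(q.size)),
                        0.0, None)
        fit = fit_eisf(EisfCurve(q=q, a0=noisy, sigma=noise_frac * a0))
        errs.append(abs(fit.radius - truth.radius) / truth.radius)
    return {"radius_pct": float(np.median(errs) * 100.0), "n": n_replicates}


def convolution_oracles() -> dict:
    """Convolution accuracy against two closed forms.

    Lorentzian⊗Lorentzian must be a Lorentzian with summed HWHMs (fitted
    width error, percent); Gaussian⊗Lorentzian must match the Voigt profile
    at the peak (relative error).
    """
    omega = np.round(np.arange(-1.5, 1.5 + 1e-9, 0.02), 6)
    d_omega = 0.02
    res = lorentzian(omega, 0.07)
    res = res / (res.sum() * d_omega)
    conv = convolve_resolution(lorentzian(omega, 0.1), res, d_omega)

    def lor(w, a, g):
        return a * g / np.pi / (g**2 + w**2)

    popt, _ = curve_fit(lor, omega, conv, p0=[1.0, 0.15])
    width_err = abs(popt[1] - 0.17) / 0.17 * 100.0

    sigma = 0.03
    gauss = np.exp(-(omega**2) / (2 * sigma**2))
    gauss = gauss / (gauss.sum() * d_omega)
    conv2 = convolve_resolution(lorentzian(omega, 0.1), gauss, d_omega)
    i0 = (omega.size - 1) // 2
    voigt_err = abs(conv2[i0] - voigt_profile(0.0, sigma, 0.1)) / voigt_profile(
        0.0, sigma, 0.1
    )
    return {"lorentzian_width_err_pct": float(width_err),
            "voigt_peak_rel_err": float(voigt_err), "n": int(omega.size)}


def law_discrimination(n_replicates: int = 100, noise_frac: float = 0.03,
                       seed: int = 0) -> dict:
    """Classification rates for Arrhenius- and VFT-generated τ(T) series.

    Arrhenius truth counts as correct when classified Arrhenius or flagged
    indistinguishable (the simpler law must never lose to VFT); VFT truth
    (T0 = 200 K, D = 3 — strongly curved) must be identified as VFT.
    """
    T = sd.DEFAULT_TEMPERATURES
    rng = np.random.default_rng(seed)
    ok_arr = 0
    for _ in range(n_replicates):
        tau = 0.05 * np.exp(15.0 / (CONSTANTS.Rgas * T))
        noisy = tau * (1 + noise_frac * rng.standard_normal(T.size))
        ok_arr += select_thermal_law(T, noisy, noise_frac * tau).chosen != "vft"
    ok_vft = 0
    for _ in range(n_replicates):
        tau = 0.1 * np.exp(3.0 * 200.0 / (T - 200.0))
        noisy = tau * (1 + noise_frac * rng.standard_normal(T.size))
        ok_vft += select_thermal_law(T, noisy, noise_frac * tau).chosen == "vft"
    return {"arrhenius_pct": 100.0 * ok_arr / n_replicates,
            "vft_pct": 100.0 * ok_vft / n_replicates, "n": n_replicates}


def breakpoint_performance(n_replicates: int = 100, seed: int = 0) -> dict:
    """Specificity on linear MSD curves; sensitivity on slope-ratio-3 hinges.

    Sensitivity counts detections whose breakpoint lands within one 10 K bin
    of the true 320 K hinge.
    """
    T = sd.DEFAULT_TEMPERATURES
    rng = np.random.default_rng(seed)
    linear_ok = 0
    for _ in range(n_replicates):
        y = 0.2 + 0.004 * (T - 283.0)
        noisy = y * (1 + 0.03 * rng.standard_normal(T.size))
        bp = detect_breakpoint(MsdCurve(T, np.zeros_like(y), noisy, 1.0,
                                        sigma=0.03 * y))
        linear_ok += bp.is_linear
    hinge_ok = 0
    for _ in range(n_replicates):
        y = 0.2 + 0.002 * (T - 283.0) + 0.004 * np.clip(T - 320.0, 0, None)
        noisy = y * (1 + 0.02 * rng.standard_normal(T.size))
        bp = detect_breakpoint(MsdCurve(T, np.zeros_like(y), noisy, 1.0,
                                        sigma=0.02 * y))
        hinge_ok += (not bp.is_linear) and abs(bp.t_star - 320.0) <= 10.0
    return {"specificity_pct": 100.0 * linear_ok / n_replicates,
            "sensitivity_pct": 100.0 * hinge_ok / n_replicates,
            "n": n_replicates}


def ortholog_substitutions() -> dict:
    """Alignment of the synthetic ortholog pair with planted substitutions."""
    seq_a, seq_b = synthetic_ortholog_pair()
    records = enumerate_substitutions(align_pair(seq_a, seq_b))
    labels = {r.label for r in records}
    return {"count": len(records),
            "has_core_pair": ("I35V" in labels) and ("I100V" in labels),
            "n": len(seq_a)}
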