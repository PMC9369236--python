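"""Temperature-law analysis of fitted dynamical parameters.

Arrhenius behaviour, Γloc(T) = Γ0·exp(−EA/RT) or τ(T) = τ0·exp(+EA/RT)
(note the sign reversal, since τ = ħ/Γ), signals activated processes; the
Vogel–Fulcher–Tammann law τ(T) = τ0·exp(D·T0/(T − T0)) signals cooperative,
glass-like relaxation, with Vogel temperature T0 and fragility index 1/D.
Model selection uses the small-sample-corrected Akaike criterion on the
log-transformed weighted fits.

Also provided: the pseudo-diffusion coefficient D_pseudo = ⟨l⟩²/(2τ), the
resilience (pseudo force constant) from the slope of the total MSD versus
temperature, and an F-tested two-segment breakpoint search on MSD curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import f as f_dist

from .constants import CONSTANTS
from .data_model import ValidationError
from .eins_twostate import MsdCurve

_KB_JOULE = 1.380649e-23  # J/K


@dataclass
class ArrheniusFit:
    """Weighted linear fit of ln y versus 1/T."""

    ea: float  # kJ/mol
    prefactor: float  # Γ0 (meV) or τ0 (ps)
    sign_mode: str  # rate | time
    ea_err: float = np.nan
    prefactor_err: float = np.nan
    rsq: float = np.nan
    chi2: float = np.nan

    @property
    def ea_kcal(self) -> float:
        return self.ea * CONSTANTS.kcal_per_kJ


@dataclass
class VftFit:
    tau0: float  # ps
    d_strength: float  # dimensionless D
    t0: float  # Vogel temperature, K
    dt0_product: float = np.nan  # D·T0 = slope in 1/(T−T0), K
    uncertainties: dict = field(default_factory=dict)
    chi2: float = np.nan
    flags: list = field(default_factory=list)

    @property
    def fragility(self) -> float:
        return 1.0 / self.d_strength if self.d_strength > 0 else np.inf


@dataclass
class LawSelection:
    chosen: str  # arrhenius | vft | indistinguishable
    delta_criterion: float
    aicc_arrhenius: float
    aicc_vft: float
    arrhenius: ArrheniusFit = None  # type: ignore[assignment]
    vft: VftFit = None  # type: ignore[assignment]
    warning: str = ""


@dataclass
class ResilienceResult:
    slope: float  # Å²/K
    slope_err: float
    force_constant: float  # N/m
    flags: list = field(default_factory=list)


@dataclass
class BreakpointResult:
    t_star: float  # K, NaN when linear
    slope_low: float  # Å²/K
    slope_high: float
    significance: float  # p-value of the two-segment vs one-segment F-test
    is_linear: bool = False


def _wls(x, y, w):
    """Weighted straight-line fit; returns (a, b, var_a, var_b, chi2)."""
    sw = w.sum()
    sx, sy = (w * x).sum(), (w * y).sum()
    sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
    delta = sw * sxx - sx**2
    b = (sw * sxy - sx * sy) / delta
    a = (sy - b * sx) / sw
    var_b = sw / delta
    var_a = sxx / delta
    chi2 = float((w * (y - a - b * x) ** 2).sum())
    return a, b, var_a, var_b, chi2


def fit_arrhenius(T, y, y_err=None, sign_mode: str = "rate") -> ArrheniusFit:
    """Activation energy from the weighted fit of ln y against 1/T.

    ``sign_mode="rate"`` for widths (slope = −EA/R) and ``"time"`` for
    relaxation times (slope = +EA/R).
    """
    if sign_mode not in ("rate", "time"):
        raise ValidationError("sign_mode must be 'rate' or 'time'")
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    if T.size < 3:
        raise ValidationError("need at least 3 points")
    if np.any(y <= 0):
        raise ValidationError("observable must be strictly positive")
    w = np.ones_like(y) if y_err is None else (y / np.asarray(y_err)) ** 2
    a, b, var_a, var_b, chi2 = _wls(1.0 / T, np.log(y), w)
    sign = -1.0 if sign_mode == "rate" else 1.0
    ea = sign * b * CONSTANTS.Rgas
    # weighted R² against the weighted-mean model
    z = np.log(y)
    zbar = (w * z).sum() / w.sum()
    ss_tot = float((w * (z - zbar) ** 2).sum())
    rsq = 1.0 - chi2 / ss_tot if ss_tot > 0 else 1.0
    return ArrheniusFit(
        ea=float(ea), prefactor=float(np.exp(a)), sign_mode=sign_mode,
        ea_err=float(np.sqrt(var_b) * CONSTANTS.Rgas),
        prefactor_err=float(np.exp(a) * np.sqrt(var_a)),
        rsq=rsq, chi2=chi2,
    )


def fit_vft(T, tau, tau_err=None, t0_margin: float = 20.0) -> VftFit:
    """Weighted VFT fit τ = τ0·exp(D·T0/(T − T0)) with a profiled T0.

    The Vogel temperature is profiled over [0, min(T) − margin] using the
    exact weighted linear sub-fit of ln τ versus 1/(T − T0), then refined.
    When T0 hits its upper bound the fit is flagged as weakly identifiable;
    when the product D·T0 is consistent with zero the law reduces to an
    Arrhenius/constant form and is flagged accordingly.
    """
    T = np.asarray(T, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if T.size < 5:
        raise ValidationError("need at least 5 points for a VFT fit")
    if np.any(tau <= 0):
        raise ValidationError("tau must be strictly positive")
    w = np.ones_like(tau) if tau_err is None else (tau / np.asarray(tau_err)) ** 2
    z = np.log(tau)
    t0_max = T.min() - t0_margin

    def chi2_of(t0):
        return _wls(1.0 / (T - t0), z, w)[4]

    grid = np.linspace(0.0, t0_max, 81)
    chis = np.array([chi2_of(t0) for t0 in grid])
    i = int(np.argmin(chis))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    ref = minimize_scalar(chi2_of, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    t0 = float(ref.x)
    a, b, var_a, var_b, chi2 = _wls(1.0 / (T - t0), z, w)

    flags = []
    if t0 > t0_max - 1e-3:
        flags.append("t0_at_upper_bound_weak_identifiability")
    b_err = float(np.sqrt(var_b))
    if abs(b) < 2.0 * b_err:
        flags.append("reduces_to_arrhenius_or_constant")

    # curvature of the χ²(T0) profile gives the T0 uncertainty
    h = max(t0_max / 80.0, 1e-3)
    c0 = chi2_of(t0)
    cp = chi2_of(min(t0 + h, t0_max))
    cm = chi2_of(max(t0 - h, 0.0))
    curv = (cp - 2 * c0 + cm) / h**2
    t0_err = float(np.sqrt(2.0 / curv)) if curv > 0 else np.inf

    if t0 > 1e-6:
        d = b / t0
        d_err = abs(d) * np.sqrt((b_err / b) ** 2 + (t0_err / t0) ** 2) if b != 0 else np.inf
    else:
        d, d_err = np.inf, np.inf
        flags.append("t0_zero_d_undefined")
    return VftFit(
        tau0=float(np.exp(a)), d_strength=float(d), t0=t0, dt0_product=float(b),
        uncertainties={"tau0": float(np.exp(a) * np.sqrt(var_a)),
                       "d_strength": float(d_err), "t0": t0_err,
                       "dt0_product": b_err},
        chi2=chi2, flags=flags,
    )


def _aicc(chi2: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return chi2 + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_thermal_law(T, tau, tau_err=None) -> LawSelection:
    """Arrhenius vs VFT comparison by small-sample-corrected AIC.

    The Gaussian likelihood with unknown error scale, n·ln(χ²/n) plus the
    AICc penalty, is used so the comparison is invariant under a common
    mis-scaling of the supplied error bars (fixed-EISF fits are known to
    understate them).  |ΔAICc| < 2 — or too few points to fit both laws —
    yields "indistinguishable" rather than a confident choice.
    """
    T = np.asarray(T, dtype=float)
    tau = np.asarray(tau, dtype=float)
    arr = fit_arrhenius(T, tau, tau_err, sign_mode="time")
    n = T.size

    def gauss_aicc(chi2, k):
        return _aicc(n * np.log(max(chi2, 1e-30) / n), k, n)

    if n < 5:
        return LawSelection(
            chosen="indistinguishable", delta_criterion=0.0,
            aicc_arrhenius=gauss_aicc(arr.chi2, 2), aicc_vft=np.inf,
            arrhenius=arr, warning="too few points to compare thermal laws",
        )
    vft = fit_vft(T, tau, tau_err)
    aicc_arr = gauss_aicc(arr.chi2, 2)
    aicc_vft = gauss_aicc(vft.chi2, 3)
    delta = aicc_arr - aicc_vft
    if abs(delta) < 2.0:
        chosen = "indistinguishable"
    else:
        chosen = "vft" if delta > 0 else "arrhenius"
    return LawSelection(chosen=chosen, delta_criterion=float(delta),
                        aicc_arrhenius=aicc_arr, aicc_vft=aicc_vft,
                        arrhenius=arr, vft=vft)


def pseudo_diffusion(jump_len: float, tau: float, units: str = "A2_per_ps") -> float:
    """Pseudo-diffusion coefficient D = ⟨l⟩²/(2τ).

    ``units``: "A2_per_ps" (default) or "1e-5_cm2_per_s"
    (1 Å²/ps = 10 × 10⁻⁵ cm²/s).
    """
    if tau <= 0:
        raise ValidationError("tau must be positive")
    d = jump_len**2 / (2.0 * tau)
    if units == "A2_per_ps":
        return d
    if units == "1e-5_cm2_per_s":
        return d * 10.0
    raise ValueError(f"unknown units '{units}'")


def resilience(msd: MsdCurve, window: tuple[float, float] | None = None) -> ResilienceResult:
    """Pseudo force constant 2·kB / (dΔxtot²/dT) in N/m.

    The MSD slope (Å²/K) is obtained by weighted linear fit inside
    ``window``; a flat curve means infinite resilience and is flagged as an
    overflow rather than reported as a number.
    """
    T = msd.temperatures
    if np.any(np.diff(T) <= 0):
        raise ValidationError("temperatures must be strictly increasing")
    y = msd.msd_total
    sel = np.ones(T.size, dtype=bool)
    if window is not None:
        sel = (T >= window[0]) & (T <= window[1])
    if sel.sum() < 3:
        raise ValidationError("need at least 3 points in the window")
    sig = msd.sigma[sel]
    w = np.where(np.isfinite(sig) & (sig > 0), 1.0 / np.where(sig > 0, sig, 1) ** 2, 1.0)
    _, b, _, var_b, _ = _wls(T[sel], y[sel], w)
    flags = []
    if b <= 0 or not np.isfinite(b) or abs(b) < 1e-15:
        return ResilienceResult(slope=float(b), slope_err=float(np.sqrt(var_b)),
                                force_constant=np.inf, flags=["overflow_flat_msd"])
    k = 2.0 * _KB_JOULE / (b * 1e-20)  # slope Å²/K → m²/K
    return ResilienceResult(slope=float(b), slope_err=float(np.sqrt(var_b)),
                            force_constant=float(k), flags=flags)


def detect_breakpoint(msd: MsdCurve, alpha: float = 0.05) -> BreakpointResult:
    """Two-segment continuous piecewise-linear search on Δxtot²(T).

    Every interior data temperature is tried as the hinge of the model
    y = a + b·T + c·max(0, T − T*); the best candidate is compared with the
    single-line null by an F-test and a breakpoint is only reported when
    p < ``alpha``.
    """
    T = msd.temperatures
    y = msd.msd_total
    n = T.size
    if n < 6:
        raise ValidationError("need at least 6 points for breakpoint detection")
    sig = msd.sigma
    w = np.where(np.isfinite(sig) & (sig > 0), 1.0 / np.where(sig > 0, sig, 1) ** 2, 1.0)
    sw = np.sqrt(w)

    def rss(design):
        A = design * sw[:, None]
        coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        r = A @ coef - y * sw
        return float(r @ r), coef

    rss0, _ = rss(np.column_stack([np.ones(n), T]))

    best = (np.inf, np.nan, None)
    for t_star in T[2:-2]:
        hinge = np.clip(T - t_star, 0.0, None)
        r, coef = rss(np.column_stack([np.ones(n), T, hinge]))
        if r < best[0]:
            best = (r, t_star, coef)
    rss1, t_star, coef = best
    dof = n - 3
    if rss1 <= 0:
        p_val = 0.0
    else:
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / dof)
        p_val = float(f_dist.sf(f_stat, 2, dof))
    if p_val < alpha:
        return BreakpointResult(
            t_star=float(t_star), slope_low=float(coef[1]),
            slope_high=float(coef[1] + coef[2]), significance=p_val,
        )
    _, line = rss(np.column_stack([np.ones(n), T]))
    return BreakpointResult(
        t_star=np.nan, slope_low=float(line[1]), slope_high=float(line[1]),
        significance=p_val, is_linear=True,
    )
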