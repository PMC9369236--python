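"""Two-state double-well analysis of elastic incoherent scans.

Hydrogen motions are modelled as vibrations inside two harmonic wells
(Debye–Waller mean-square displacement Δx0²) separated by a distance d and a
free-energy difference ΔG = ΔH − T·ΔS, with Arrhenius-populated states:

    S(q, 0) = exp(−Δx0²·q²) · [1 − 2·p1·p2·(1 − sinc(q·d))]

    p1/p2 = exp(−ΔH/(R·T) + ΔS/R)

The elastic scans of a whole temperature series at one pressure are fitted
globally: d, ΔH, ΔS (and one overall scale factor) are shared across
temperatures, while Δx0² is free per temperature.  The total mean-square
displacement adds the inter-well term:  Δxtot² = Δx0² + (p1·p2/3)·d².
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import CONSTANTS
from .data_model import ElasticScanSet, ValidationError

#: Deterministic multi-start grid for the shared parameters.
START_GRID_D = (0.5, 1.0, 1.5, 2.0, 3.0)  # Å
START_GRID_DH = (5.0, 10.0, 20.0, 40.0)  # kJ/mol
START_GRID_DS = (0.0, 20.0, 50.0)  # J/(mol·K)


def fit_covariance(jac: np.ndarray, chi2_red: float) -> np.ndarray:
    """Parameter covariance from a least-squares Jacobian.

    Directions in which the Jacobian carries (numerically) no information are
    given effectively infinite variance instead of the spuriously small one a
    pseudo-inverse would report — unidentifiable parameters must surface as
    huge uncertainties, not confident ones.
    """
    u, s, vt = np.linalg.svd(jac, full_matrices=False)
    tol = s.max() * 1e-8 if s.size and s.max() > 0 else 1.0
    inv_s2 = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0) ** 2, 1.0 / tol**2)
    return (vt.T * inv_s2) @ vt * max(chi2_red, 1e-30)


@dataclass
class TwoStateParams:
    """Result of a per-pressure global two-state fit."""

    dx0_sq: np.ndarray  # Å², one per temperature
    d: float  # Å
    dH: float  # kJ/mol
    dS: float  # J/(mol·K)
    scale: float
    pressure: float  # bar
    temperatures: np.ndarray  # K
    uncertainties: dict = field(default_factory=dict)
    chi2_red: float = np.nan
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dx0_sq = np.asarray(self.dx0_sq, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(self.dx0_sq < 0) or self.d < 0:
            raise ValidationError("dx0_sq and d must be non-negative")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValidationError("temperatures must be strictly increasing")


@dataclass
class MsdCurve:
    """Single-well and total MSD versus temperature at one pressure."""

    temperatures: np.ndarray  # K
    msd_single: np.ndarray  # Δx0²(T), Å²
    msd_total: np.ndarray  # Δxtot²(T), Å²
    pressure: float  # bar
    sigma: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.msd_single = np.asarray(self.msd_single, dtype=float)
        self.msd_total = np.asarray(self.msd_total, dtype=float)
        if self.sigma is None:
            self.sigma = np.full_like(self.msd_total, np.nan)
        if np.any(self.msd_total < self.msd_single - 1e-12):
            raise ValidationError("msd_total must dominate msd_single pointwise")


def population_fraction(dH: float, dS: float, T):
    """Populations (p1, p2) of the two wells; well 2 is the ground state.

    ``dH`` in kJ/mol, ``dS`` in J/(mol·K); p1/p2 = exp(−ΔH/RT + ΔS/R).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("temperature must be positive")
    R = CONSTANTS.Rgas
    ratio = np.exp(-dH / (R * T) + (dS / 1000.0) / R)
    p1 = ratio / (1.0 + ratio)
    return p1, 1.0 - p1


def _sinc(x):
    return np.sinc(np.asarray(x) / np.pi)  # sin(x)/x with sinc(0)=1


def two_state_elastic(q, dx0_sq: float, d: float, dH: float, dS: float, T: float):
    """Elastic intensity of the two-state model, normalized to 1 at q = 0."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q must be non-negative")
    if dx0_sq < 0 or d < 0:
        raise ValidationError("dx0_sq and d must be non-negative")
    p1, p2 = population_fraction(dH, dS, T)
    return np.exp(-dx0_sq * q**2) * (1.0 - 2.0 * p1 * p2 * (1.0 - _sinc(q * d)))


def _model_matrix(q, dx0_sq, d, dH, dS, temps):
    """Vectorized model over (T, q): shape (n_T, n_q), unscaled."""
    p1, p2 = population_fraction(dH, dS, temps)
    bracket = 1.0 - 2.0 * (p1 * p2)[:, None] * (1.0 - _sinc(q[None, :] * d))
    return np.exp(-np.outer(dx0_sq, q**2)) * bracket


def fit_two_state_global(
    scans: ElasticScanSet,
    fix_scale: bool = False,
    starts: str = "grid",
    adequate_stop: bool = True,
) -> TwoStateParams:
    """Global weighted least-squares fit of a one-pressure temperature series.

    Shared parameters (d, ΔH, ΔS) plus one overall scale; Δx0² free per
    temperature.  The fit is repeated from a deterministic grid of starting
    points (the model is multimodal in d and ΔH); with ``adequate_stop`` the
    grid is abandoned as soon as a start reaches a statistically adequate χ².

    Parameters with uncertainties exceeding their value are flagged as
    unidentifiable (degenerate data, e.g. d ≈ 0, cannot constrain ΔH, ΔS).
    """
    pressures = {c.pressure for c in scans.conditions}
    if len(pressures) != 1:
        raise ValidationError("fit_two_state_global expects a single pressure")
    pressure = pressures.pop()
    order = np.argsort([c.temperature for c in scans.conditions])
    temps = np.array([scans.conditions[i].temperature for i in order])
    n_t = temps.size
    if n_t < 3:
        raise ValidationError("need at least 3 temperatures for a global fit")
    qm = scans.q[scans.mask]
    if qm.size < 5:
        raise ValidationError("need at least 5 unmasked q points")
    inten = scans.intensity[order][:, scans.mask]
    sigma = scans.sigma[order][:, scans.mask]
    w = 1.0 / sigma

    scale0 = float(np.median(inten[:, 0])) if not fix_scale else 1.0
    scale0 = scale0 if scale0 > 0 else 1.0
    # per-T Debye-Waller seed from the low-q slope of ln I vs q²
    with np.errstate(divide="ignore", invalid="ignore"):
        lnI = np.log(np.clip(inten / scale0, 1e-12, None))
    q2 = qm**2
    slopes = -np.polyfit(q2, lnI.T, 1)[0]
    dx0_init = np.clip(slopes, 1e-4, 3.0)

    n_shared = 3 + (0 if fix_scale else 1)

    def unpack(p):
        d, dH, dS = p[0], p[1], p[2]
        scale = 1.0 if fix_scale else p[3]
        dx0 = p[n_shared:]
        return d, dH, dS, scale, dx0

    def residuals(p):
        d, dH, dS, scale, dx0 = unpack(p)
        model = scale * _model_matrix(qm, dx0, d, dH, dS, temps)
        return ((model - inten) * w).ravel()

    lb = np.concatenate([[0.0, -100.0, -500.0], [] if fix_scale else [1e-8], np.zeros(n_t)])
    ub = np.concatenate([[8.0, 300.0, 1000.0], [] if fix_scale else [np.inf],
                         np.full(n_t, 10.0)])

    if starts == "grid":
        grid = list(itertools.product(START_GRID_D, START_GRID_DH, START_GRID_DS))
    elif starts == "coarse":
        grid = [(1.0, 10.0, 20.0), (2.0, 20.0, 0.0), (0.5, 40.0, 50.0)]
    else:
        raise ValueError("starts must be 'grid' or 'coarse'")

    dof = inten.size - (n_shared + n_t)
    if dof <= 0:
        raise ValidationError("fewer data points than parameters")
    adequate = dof + 3.0 * np.sqrt(2.0 * dof)

    best = None
    for d0, dh0, ds0 in grid:
        p0 = np.concatenate([[d0, dh0, ds0], [] if fix_scale else [scale0], dx0_init])
        try:
            res = least_squares(residuals, p0, bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if adequate_stop and 2.0 * best.cost <= adequate:
            break
    if best is None or not best.success and best.cost > 1e10:
        raise RuntimeError("two-state global fit failed to converge from any start")

    chi2 = 2.0 * best.cost
    chi2_red = chi2 / dof
    d, dH, dS, scale, dx0 = unpack(best.x)

    # the model depends on ΔH, ΔS only through p1·p2, which is invariant
    # under (ΔH, ΔS) → (−ΔH, −ΔS); canonicalize so that well 2 is the
    # ground state (ΔG ≥ 0 at the mean temperature)
    if dH - temps.mean() * dS / 1000.0 < 0:
        dH, dS = -dH, -dS

    # covariance from the Jacobian at the solution, scaled by reduced χ²
    cov = fit_covariance(best.jac, chi2_red)
    perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    unc = {
        "d": perr[0],
        "dH": perr[1],
        "dS": perr[2],
        "scale": np.nan if fix_scale else perr[3],
        "dx0_sq": perr[n_shared:],
    }
    flags = []
    for name, value in (("d", d), ("dH", dH), ("dS", dS)):
        if not np.isfinite(unc[name]) or unc[name] > abs(value):
            flags.append(f"{name}_unidentifiable")
    return TwoStateParams(
        dx0_sq=dx0, d=d, dH=dH, dS=dS, scale=scale,
        pressure=pressure, temperatures=temps,
        uncertainties=unc, chi2_red=chi2_red, flags=flags,
    )


def total_msd(params: TwoStateParams) -> MsdCurve:
    """Total MSD curve Δxtot²(T) = Δx0²(T) + (p1·p2/3)·d²."""
    p1, p2 = population_fraction(params.dH, params.dS, params.temperatures)
    total = params.dx0_sq + (p1 * p2 / 3.0) * params.d**2
    sigma = params.uncertainties.get("dx0_sq")
    return MsdCurve(
        temperatures=params.temperatures,
        msd_single=params.dx0_sq.copy(),
        msd_total=total,
        pressure=params.pressure,
        sigma=None if sigma is None else np.asarray(sigma, dtype=float),
    )
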