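"""Geometric model of the elastic incoherent structure factor.

The extracted A0(q) is decomposed into an immobile fraction p, a fraction s
of mobile hydrogens undergoing confined jump-diffusion inside a sphere of
radius R, and the rest performing methyl three-site jumps of fixed distance
aM = √3·R_M = 1.715 Å:

    A0(q) = p + (1 − p)·[ s·Aj(q) + (1 − s)·A3(q) ]
    Aj(q) = j0²(q·R/2)          (confined jump-diffusion)
    A3(q) = (1/3)·(1 + 2·j0(q·aM))   (methyl rotation)

with j0(x) = sin(x)/x.  ``aj_form="full"`` switches Aj to j0²(q·R) for
sensitivity analysis of the functional form.  The confinement radius can be
compared with the equivalent radius of protein cavities,
R_eq = (3V/4π)^(1/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .data_model import Condition, ValidationError
from .eins_twostate import fit_covariance
from .qens_fit import EisfCurve

A_METHYL = 1.715  # Å, √3 times the proton–axis distance of a methyl group


@dataclass
class EisfParams:
    """Geometry parameters of the EISF model."""

    p_immobile: float
    s_confined: float
    radius: float  # Å
    a_methyl: float = A_METHYL
    condition: Condition = None  # type: ignore[assignment]
    uncertainties: dict = field(default_factory=dict)
    chi2_red: float = np.nan
    flags: list = field(default_factory=list)
    aj_form: str = "half"

    def __post_init__(self) -> None:
        if not (0 <= self.p_immobile <= 1 and 0 <= self.s_confined <= 1):
            raise ValidationError("p and s must lie in [0, 1]")
        if self.radius <= 0:
            raise ValidationError("radius must be positive")


def _j0(x):
    return np.sinc(np.asarray(x) / np.pi)


def eisf_model(q, params: EisfParams):
    """Evaluate the geometric EISF model; equals 1 at q = 0."""
    q = np.asarray(q, dtype=float)
    arg = q * params.radius / (2.0 if params.aj_form == "half" else 1.0)
    aj = _j0(arg) ** 2
    a3 = (1.0 + 2.0 * _j0(q * params.a_methyl)) / 3.0
    p, s = params.p_immobile, params.s_confined
    return p + (1.0 - p) * (s * aj + (1.0 - s) * a3)


#: Deterministic multi-start radii (Å).
START_GRID_R = (1.0, 2.0, 4.0, 8.0)


def fit_eisf(
    curve: EisfCurve,
    a_methyl: float = A_METHYL,
    aj_form: str = "half",
) -> EisfParams:
    """Bounded weighted least-squares fit of the EISF geometry model.

    p, s ∈ [0, 1] and R ∈ (0.5, 20) Å with aM fixed; multi-start over R.
    Points with A0 exceeding 1 beyond 2σ are rejected with a warning flag.
    When the data cannot constrain R (e.g. s ≈ 0) the radius is flagged
    unidentifiable instead of being reported with false confidence.
    """
    ok = np.isfinite(curve.a0) & np.isfinite(curve.sigma)
    rejected = ok & (curve.a0 > 1.0 + 2.0 * curve.sigma)
    ok &= ~rejected
    q, a0, sig = curve.q[ok], curve.a0[ok], np.clip(curve.sigma[ok], 1e-12, None)
    if q.size < 6:
        raise ValidationError("need at least 6 usable q points to fit the EISF")

    def resid(p):
        m = EisfParams(p_immobile=p[0], s_confined=p[1], radius=p[2],
                       a_methyl=a_methyl, aj_form=aj_form)
        return (eisf_model(q, m) - a0) / sig

    lb, ub = [0.0, 0.0, 0.5], [1.0, 1.0, 20.0]
    best = None
    for r0 in START_GRID_R:
        try:
            fit = least_squares(resid, [0.2, 0.5, r0], bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, max_nfev=400)
        except Exception:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise RuntimeError(
            f"EISF fit failed to converge from starts R0 in {START_GRID_R}"
        )

    dof = max(q.size - 3, 1)
    chi2_red = 2.0 * best.cost / dof
    cov = fit_covariance(best.jac, chi2_red)
    perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    flags = []
    if np.any(rejected):
        flags.append(f"rejected_{int(rejected.sum())}_points_above_unity")
    if not np.isfinite(perr[2]) or perr[2] > best.x[2] or best.x[1] * (1 - best.x[0]) < 1e-3:
        flags.append("radius_unidentifiable")
    return EisfParams(
        p_immobile=float(best.x[0]), s_confined=float(best.x[1]),
        radius=float(best.x[2]), a_methyl=a_methyl,
        condition=curve.condition,
        uncertainties={"p_immobile": perr[0], "s_confined": perr[1], "radius": perr[2]},
        chi2_red=chi2_red, flags=flags, aj_form=aj_form,
    )


def equivalent_radius(volume: float) -> float:
    """Radius of the sphere with the same volume, (3V/4π)^(1/3), in Å."""
    if volume < 0:
        raise ValidationError("volume must be non-negative")
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))
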