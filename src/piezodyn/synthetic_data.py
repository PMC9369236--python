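"""Forward generator for raw-like and reduced EINS/QENS datasets.

Emulates a backscattering-style elastic scan (q ≈ 0.2–4.5 Å⁻¹, 283–363 K in
10 K bins, pressures 1/150/300/600 bar, two-state ground truth) and a
time-of-flight QENS map (q 0.6–1.8 Å⁻¹, ω −1.5…+1.5 meV in 0.02 meV steps,
~70 µeV HWHM Gaussian resolution, Hall–Ross + localized-Lorentzian ground
truth) with instrument effects layered on top of the noiseless reference:

* per-detector efficiency ε(q),
* transmission-scaled empty-cell and buffer (D₂O) contributions,
* detailed-balance asymmetry exp(+ħω/(2·kB·T)) on raw QENS spectra,
* Poisson (or Gaussian) counting noise,
* a vanadium measurement carrying the resolution function and ε(q).

Every generated dataset embeds its ground truth and seed; regeneration with
the same seed is bit-identical.  Background shapes are smooth artifact
choices for exercising the reduction chain, not physical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import CONSTANTS
from .data_model import Condition, ElasticScanSet, QensDataset
from .eins_twostate import _model_matrix
from .eisf_geometry import EisfParams, eisf_model
from .qens_fit import _qens_shape, convolve_resolution, lorentzian
from .reduction import DEFAULT_DISPLACED_FRACTION, RawMeasurement

DEFAULT_Q_ELASTIC = np.round(np.linspace(0.2, 4.5, 25), 6)
DEFAULT_Q_QENS = np.round(np.linspace(0.6, 1.8, 7), 6)
DEFAULT_OMEGA = np.round(np.arange(-1.5, 1.5 + 1e-9, 0.02), 6)
DEFAULT_TEMPERATURES = np.arange(283.0, 364.0, 10.0)
DEFAULT_PRESSURES = (1.0, 150.0, 300.0, 600.0)


@dataclass
class ElasticTruth:
    """Two-state ground truth at one pressure; Δx0² is linear in T."""

    d: float = 1.4  # Å
    dH: float = 12.0  # kJ/mol
    dS: float = 25.0  # J/(mol·K)
    dx0_at_283: float = 0.15  # Å²
    dx0_slope: float = 2.5e-3  # Å²/K
    scale: float = 1.0

    def dx0_sq(self, temperatures):
        t = np.asarray(temperatures, dtype=float)
        return self.dx0_at_283 + self.dx0_slope * (t - 283.0)


@dataclass
class QensTruth:
    """Hall–Ross + localized-motion + EISF-geometry ground truth."""

    tau: float = 2.0  # ps
    jump_len: float = 1.2  # Å
    gamma_loc: float = 0.3  # meV
    scale_amp: float = 1.0
    dw_msd: float = 0.05  # Å²
    eisf: EisfParams = field(
        default_factory=lambda: EisfParams(p_immobile=0.25, s_confined=0.5, radius=3.0)
    )


@dataclass
class ResolutionSpec:
    shape: str = "gaussian"  # gaussian | lorentzian
    hwhm: float = 0.07  # meV

    def profile(self, omega):
        omega = np.asarray(omega, dtype=float)
        if self.shape == "gaussian":
            sig = self.hwhm / np.sqrt(2.0 * np.log(2.0))
            prof = np.exp(-(omega**2) / (2.0 * sig**2))
        elif self.shape == "lorentzian":
            prof = lorentzian(omega, self.hwhm)
        else:
            raise ValueError(f"unknown resolution shape '{self.shape}'")
        d_omega = omega[1] - omega[0]
        return prof / (prof.sum() * d_omega)


@dataclass
class NoiseSpec:
    model: str = "poisson"  # poisson | gaussian | none
    counts: float = 1e4  # Poisson: total counts per q channel (QENS) / per point (EINS)
    gaussian_frac: float = 0.02  # relative σ for the gaussian model


@dataclass
class BackgroundSpec:
    cell_amp: float = 0.08
    buffer_amp: float = 0.25
    transmission_sample: float = 0.92
    transmission_cell: float = 0.95
    transmission_buffer: float = 0.90
    efficiency_amp: float = 0.25
    displaced_fraction: float = DEFAULT_DISPLACED_FRACTION

    def efficiency(self, q):
        return 1.0 + self.efficiency_amp * np.cos(1.7 * np.asarray(q))


@dataclass
class GroundTruth:
    """Complete generating record for one synthetic study."""

    elastic: dict = field(default_factory=lambda: {p: ElasticTruth() for p in DEFAULT_PRESSURES})
    qens: dict = field(default_factory=dict)  # (T, P) -> QensTruth
    thermal_law: dict = field(
        default_factory=lambda: {"law": "arrhenius", "tau0": 0.05, "ea": 10.0}
    )
    backgrounds: BackgroundSpec = field(default_factory=BackgroundSpec)
    resolution: ResolutionSpec = field(default_factory=ResolutionSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    note: str = ""


def tau_of_temperature(thermal_law: dict, temperatures):
    """Residence time τ(T) from an Arrhenius or VFT generating law."""
    t = np.asarray(temperatures, dtype=float)
    law = thermal_law["law"]
    if law == "arrhenius":
        return thermal_law["tau0"] * np.exp(
            thermal_law["ea"] / (CONSTANTS.Rgas * t)
        )
    if law == "vft":
        t0 = thermal_law["t0"]
        return thermal_law["tau0"] * np.exp(
            thermal_law["d_strength"] * t0 / (t - t0)
        )
    raise ValueError(f"unknown thermal law '{law}'")


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def _apply_noise(values, noise: NoiseSpec, rng, counts_scale):
    """Counting noise on non-negative intensities; returns (noisy, sigma)."""
    if noise.model == "none":
        sigma = np.sqrt(np.clip(values, 1e-12, None) / counts_scale)
        return values.copy(), sigma
    if noise.model == "poisson":
        lam = np.clip(values, 0.0, None) * counts_scale
        counts = rng.poisson(lam)
        noisy = counts / counts_scale
        sigma = np.sqrt(np.maximum(counts, 1.0)) / counts_scale
        return noisy, sigma
    if noise.model == "gaussian":
        sigma = noise.gaussian_frac * np.clip(np.abs(values), 1e-12, None)
        return values + rng.normal(0.0, sigma), sigma.copy()
    raise ValueError(f"unknown noise model '{noise.model}'")


# ---------------------------------------------------------------------------
# elastic scans
# ---------------------------------------------------------------------------

def elastic_reference(
    truth: ElasticTruth,
    q=DEFAULT_Q_ELASTIC,
    temperatures=DEFAULT_TEMPERATURES,
    pressure: float = 1.0,
    sigma_frac: float = 0.02,
) -> ElasticScanSet:
    """Noiseless two-state elastic scans with nominal errors."""
    q = np.asarray(q, dtype=float)
    temps = np.asarray(temperatures, dtype=float)
    model = truth.scale * _model_matrix(q, truth.dx0_sq(temps), truth.d,
                                        truth.dH, truth.dS, temps)
    return ElasticScanSet(
        q=q,
        conditions=[Condition(float(t), pressure) for t in temps],
        intensity=model,
        sigma=np.clip(sigma_frac * model, 1e-12, None),
    )


def add_multiplicative_noise(scans: ElasticScanSet, frac: float, rng) -> ElasticScanSet:
    """Gaussian multiplicative noise with matching reported errors."""
    sigma = frac * scans.intensity
    noisy = scans.intensity * (1.0 + frac * rng.standard_normal(scans.intensity.shape))
    return ElasticScanSet(
        q=scans.q, conditions=list(scans.conditions),
        intensity=np.clip(noisy, 0.0, None),
        sigma=np.clip(sigma, 1e-12, None), mask=scans.mask.copy(),
    )


def generate_elastic_dataset(
    truth: GroundTruth,
    q=DEFAULT_Q_ELASTIC,
    temperatures=DEFAULT_TEMPERATURES,
    pressures=None,
    seed: int | None = None,
    include_backgrounds: bool = True,
):
    """Raw measurement set + noiseless reference for elastic scans.

    Raw sample/cell/buffer intensities share the detector efficiency and the
    transmissions of the background spec, so the reduction chain applied to
    the raw set recovers the reference exactly in the noiseless limit.
    Returns a dict with keys ``sample``, ``empty_cell``, ``buffer``,
    ``vanadium``, ``reference`` and ``truth``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    q = np.asarray(q, dtype=float)
    temps = np.asarray(temperatures, dtype=float)
    if pressures is None:
        pressures = sorted(truth.elastic)
    bg = truth.backgrounds
    eff = bg.efficiency(q)
    f = bg.displaced_fraction

    cell = bg.cell_amp * (1.0 + 0.05 * q) if include_backgrounds else np.zeros_like(q)
    buff = bg.buffer_amp * np.exp(-0.08 * q**2) if include_backgrounds else np.zeros_like(q)

    conditions, ref_rows = [], []
    for p in pressures:
        et = truth.elastic[p]
        model = et.scale * _model_matrix(q, et.dx0_sq(temps), et.d, et.dH, et.dS, temps)
        ref_rows.append(model)
        conditions.extend(Condition(float(t), float(p)) for t in temps)
    signal = np.vstack(ref_rows)

    n0 = truth.noise.counts

    def raw(kind, composition, transmission):
        values = eff[None, :] * transmission * composition
        noisy, sigma = _apply_noise(values, truth.noise, rng, n0)
        payload = ElasticScanSet(q=q, conditions=list(conditions),
                                 intensity=noisy, sigma=sigma)
        return RawMeasurement(kind=kind, transmission=transmission, data=payload)

    sample = raw("sample", cell[None, :] + (1 - f) * buff[None, :] + signal,
                 bg.transmission_sample)
    empty_cell = raw("empty_cell", np.broadcast_to(cell, signal.shape),
                     bg.transmission_cell)
    buffer_m = raw("buffer", np.broadcast_to(cell + buff, signal.shape),
                   bg.transmission_buffer)

    van_vals = eff[None, :] * np.ones((1, q.size))
    van_noisy, van_sigma = _apply_noise(van_vals, truth.noise, rng, n0)
    vanadium = RawMeasurement(
        kind="vanadium", transmission=1.0,
        data=ElasticScanSet(q=q, conditions=[Condition(295.0, 1.0, "vanadium")],
                            intensity=van_noisy, sigma=van_sigma),
    )
    reference = ElasticScanSet(
        q=q, conditions=list(conditions), intensity=signal,
        sigma=np.sqrt(np.clip(signal, 1e-12, None) / n0),
    )
    return {"sample": sample, "empty_cell": empty_cell, "buffer": buffer_m,
            "vanadium": vanadium, "reference": reference, "truth": truth}


# ---------------------------------------------------------------------------
# QENS maps
# ---------------------------------------------------------------------------

def qens_reference(
    truth: QensTruth,
    q=DEFAULT_Q_QENS,
    omega=DEFAULT_OMEGA,
    resolution: ResolutionSpec | None = None,
    condition: Condition | None = None,
    counts: float = 1e4,
) -> QensDataset:
    """Noiseless symmetric resolution-convolved model spectrum."""
    q = np.asarray(q, dtype=float)
    omega = np.asarray(omega, dtype=float)
    resolution = resolution or ResolutionSpec()
    res_prof = np.tile(resolution.profile(omega), (q.size, 1))
    a0 = eisf_model(q, truth.eisf)
    shape = _qens_shape(q, omega, a0, truth.tau, truth.jump_len, truth.gamma_loc)
    d_omega = float(omega[1] - omega[0])
    conv = convolve_resolution(shape, res_prof, d_omega)
    amp = truth.scale_amp * np.exp(-(q**2) * truth.dw_msd)
    s = amp[:, None] * conv
    n0_q = counts / np.clip(s.sum(axis=1) * d_omega, 1e-12, None)
    sigma = np.sqrt(np.clip(s, 1e-12, None) / n0_q[:, None])
    cond = condition or Condition(300.0, 1.0)
    return QensDataset(q=q, omega=omega, s_qw=s[None], sigma=sigma[None],
                       resolution=res_prof, conditions=[cond])


def generate_qens_dataset(
    truth: GroundTruth,
    q=DEFAULT_Q_QENS,
    omega=DEFAULT_OMEGA,
    seed: int | None = None,
    include_backgrounds: bool = True,
):
    """Raw measurement set + symmetric reference + vanadium for QENS.

    The raw sample carries the detailed-balance asymmetry
    exp(+ħω/(2·kB·T)), detector efficiency, transmissions and backgrounds;
    the reference is the symmetric noiseless convolved model.  Conditions
    are the keys of ``truth.qens``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    q = np.asarray(q, dtype=float)
    omega = np.asarray(omega, dtype=float)
    d_omega = float(omega[1] - omega[0])
    bg = truth.backgrounds
    eff = bg.efficiency(q)
    f = bg.displaced_fraction
    res_prof = np.tile(truth.resolution.profile(omega), (q.size, 1))

    conditions = [Condition(float(t), float(p)) for (t, p) in sorted(truth.qens)]
    signal_rows, ref_sigma_rows = [], []
    for c in conditions:
        qt = truth.qens[(c.temperature, c.pressure)]
        a0 = eisf_model(q, qt.eisf)
        shape = _qens_shape(q, omega, a0, qt.tau, qt.jump_len, qt.gamma_loc)
        conv = convolve_resolution(shape, res_prof, d_omega)
        amp = qt.scale_amp * np.exp(-(q**2) * qt.dw_msd)
        s = amp[:, None] * conv
        signal_rows.append(s)
        n0_q = truth.noise.counts / np.clip(s.sum(axis=1) * d_omega, 1e-12, None)
        ref_sigma_rows.append(np.sqrt(np.clip(s, 1e-12, None) / n0_q[:, None]))
    signal = np.stack(signal_rows)

    if include_backgrounds:
        cell = bg.cell_amp * (1.0 + 0.05 * q)[:, None] * (
            1.0 - 0.3 * (omega / max(abs(omega[0]), abs(omega[-1]))) ** 2
        )[None, :]
        buff = bg.buffer_amp * (1.0 + 0.1 * q)[:, None] * lorentzian(omega, 1.0)[None, :]
    else:
        cell = np.zeros((q.size, omega.size))
        buff = np.zeros_like(cell)

    temps = np.array([c.temperature for c in conditions])
    asym = np.exp(CONSTANTS.hbar * omega[None, None, :]
                  / (2.0 * CONSTANTS.kB * temps[:, None, None]))

    # per-(condition, q) counts normalization so each q channel collects
    # ~noise.counts counts in the sample measurement
    n0 = truth.noise.counts / np.clip(
        (signal + cell[None] + buff[None]).sum(axis=-1).mean() * d_omega, 1e-12, None
    )

    def raw_qens(kind, composition, transmission, asymmetric=True):
        values = eff[None, :, None] * transmission * composition
        if asymmetric:
            values = values * asym
        noisy, sigma = _apply_noise(values, truth.noise, rng, n0)
        payload = QensDataset(q=q, omega=omega, s_qw=noisy, sigma=sigma,
                              resolution=res_prof, conditions=list(conditions))
        return RawMeasurement(kind=kind, transmission=transmission, data=payload)

    sample = raw_qens("sample", cell[None] + (1 - f) * buff[None] + signal,
                      bg.transmission_sample)
    empty_cell = raw_qens("empty_cell",
                          np.broadcast_to(cell, signal.shape), bg.transmission_cell)
    buffer_m = raw_qens("buffer", np.broadcast_to(cell + buff, signal.shape),
                        bg.transmission_buffer)

    van_vals = eff[None, :, None] * res_prof[None]
    van_noisy, van_sigma = _apply_noise(van_vals, truth.noise, rng, n0)
    vanadium = RawMeasurement(
        kind="vanadium", transmission=1.0,
        data=QensDataset(q=q, omega=omega, s_qw=van_noisy, sigma=van_sigma,
                         resolution=res_prof,
                         conditions=[Condition(295.0, 1.0, "vanadium")]),
    )
    reference = QensDataset(q=q, omega=omega, s_qw=signal,
                            sigma=np.stack(ref_sigma_rows),
                            resolution=res_prof, conditions=conditions)
    return {"sample": sample, "empty_cell": empty_cell, "buffer": buffer_m,
            "vanadium": vanadium, "reference": reference, "truth": truth}


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("piezophile_like", "piezosensitive_like")

_PRESET_NOTE = (
    "synthetic preset: trend directions follow the study design "
    "(thermal law, pressure trends); magnitudes are fabricated defaults, "
    "not fitted values"
)


def preset_profiles(name: str, seed: int = 0) -> GroundTruth:
    """Documented parameter sets for the two qualitative behaviours.

    ``piezophile_like``: Arrhenius τ(T), pressure-flat inter-well distance d
    and confinement radius R.  ``piezosensitive_like``: VFT τ(T) with
    pressure-increasing fragility, pressure-decreasing d and
    pressure-increasing R.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset '{name}'; choose from {PRESET_NAMES}")
    temps_qens = tuple(DEFAULT_TEMPERATURES)
    if name == "piezophile_like":
        law = {"law": "arrhenius", "tau0": 0.05, "ea": 10.0}
        gamma_law = {"gamma0": 8.6, "ea": 8.0}
        elastic = {
            p: ElasticTruth(d=1.4, dH=12.0 - 2.0 * (p > 1), dS=25.0 - 5.0 * (p > 1))
            for p in DEFAULT_PRESSURES
        }
        radius = {1.0: 3.0, 150.0: 3.0, 300.0: 3.0}
        jump = {1.0: 1.2, 150.0: 1.2, 300.0: 1.2}
    else:
        law = {"law": "vft", "tau0": 0.15, "d_strength": 4.0, "t0": 180.0}
        gamma_law = {"gamma0": 12.0, "ea": 9.5}
        d_by_p = {1.0: 1.5, 150.0: 1.2, 300.0: 1.0, 600.0: 0.8}
        elastic = {
            p: ElasticTruth(d=d_by_p[p], dH=12.0 + 0.01 * p, dS=25.0 + 0.02 * p)
            for p in DEFAULT_PRESSURES
        }
        radius = {1.0: 3.0, 150.0: 3.4, 300.0: 3.8}
        jump = {1.0: 1.2, 150.0: 1.35, 300.0: 1.5}

    qens = {}
    for p, r in radius.items():
        tau_t = tau_of_temperature(law, temps_qens)
        if name == "piezosensitive_like":
            # fragility grows (D shrinks) with pressure
            d_p = {1.0: 4.0, 150.0: 3.5, 300.0: 3.0}[p]
            tau_t = law["tau0"] * np.exp(d_p * law["t0"] / (np.asarray(temps_qens) - law["t0"]))
        for t, tau in zip(temps_qens, tau_t):
            gloc = gamma_law["gamma0"] * np.exp(-gamma_law["ea"] / (CONSTANTS.Rgas * t))
            qens[(t, p)] = QensTruth(
                tau=float(tau), jump_len=jump[p], gamma_loc=float(gloc),
                scale_amp=1.0, dw_msd=0.05,
                eisf=EisfParams(p_immobile=0.25, s_confined=0.5, radius=r),
            )
    return GroundTruth(
        elastic=elastic, qens=qens, thermal_law=law,
        # production-quality counting statistics: measured spectra of this
        # kind carry point errors at the percent level, i.e. ~1e5 counts
        # collected per q channel
        noise=NoiseSpec(model="poisson", counts=1e5),
        seed=seed, note=_PRESET_NOTE,
    )


def truth_metadata(truth: GroundTruth) -> dict:
    """JSON-serializable record of a ground truth (embedded in outputs)."""
    meta = asdict(truth)
    meta["qens"] = {f"{t}K_{p}bar": asdict(v) for (t, p), v in truth.qens.items()}
    meta["elastic"] = {f"{p}bar": asdict(v) for p, v in truth.elastic.items()}
    return meta
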