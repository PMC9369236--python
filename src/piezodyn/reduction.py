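"""Reduction chain for raw neutron-scattering measurements.

Turns sample / empty-cell / buffer (D₂O) / vanadium measurements with their
transmissions into fit-ready :class:`~piezodyn.data_model.ElasticScanSet` and
:class:`~piezodyn.data_model.QensDataset` objects:

    transmission scaling → empty-cell and buffer subtraction → vanadium
    (detector-efficiency) normalization → detailed-balance symmetrization
    (QENS) → temperature binning / energy rebinning → up/down-scan merge.

No Paalman–Pings attenuation or multiple-scattering corrections are applied.
Counting errors are propagated in quadrature through every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import CONSTANTS
from .data_model import Condition, ElasticScanSet, QensDataset, ValidationError

log = logging.getLogger(__name__)

#: Default D₂O-displaced volume fraction: protein concentration 0.120 g/mL
#: times a partial specific volume of 0.73 mL/g.
DEFAULT_DISPLACED_FRACTION = 0.120 * 0.73


@dataclass
class RawMeasurement:
    """A raw measurement of one kind, with its transmission."""

    kind: str  # sample | empty_cell | buffer | vanadium
    transmission: float
    data: object  # ElasticScanSet- or QensDataset-shaped payload
    scan_direction: str = "up"  # up | down (elastic ramps)

    def __post_init__(self) -> None:
        if self.kind not in ("sample", "empty_cell", "buffer", "vanadium"):
            raise ValidationError(f"unknown measurement kind '{self.kind}'")
        if not (0 < self.transmission <= 1):
            raise ValidationError(
                f"transmission must be in (0, 1], got {self.transmission}"
            )
        if self.scan_direction not in ("up", "down"):
            raise ValidationError("scan_direction must be 'up' or 'down'")


def _arrays(payload):
    if isinstance(payload, QensDataset):
        return payload.s_qw, payload.sigma
    return payload.intensity, payload.sigma


def _rebuild(payload, values, sigma, clip_negative=True):
    n_clipped = int(np.sum(values < 0))
    if clip_negative and n_clipped:
        log.info("clipped %d negative channels to zero after subtraction", n_clipped)
        values = np.clip(values, 0.0, None)
    if isinstance(payload, QensDataset):
        return QensDataset(
            q=payload.q,
            omega=payload.omega,
            s_qw=values,
            sigma=sigma,
            resolution=payload.resolution,
            resolution_sigma=payload.resolution_sigma,
            conditions=list(payload.conditions),
        )
    return ElasticScanSet(
        q=payload.q,
        conditions=list(payload.conditions),
        intensity=values,
        sigma=sigma,
        mask=payload.mask.copy(),
    )


def _check_grids(a, b, what: str) -> None:
    if a.q.shape != b.q.shape or not np.allclose(a.q, b.q):
        raise ValidationError(f"q grids of sample and {what} do not match")
    if isinstance(a, QensDataset) and isinstance(b, QensDataset):
        if a.omega.shape != b.omega.shape or not np.allclose(a.omega, b.omega):
            raise ValidationError(f"omega grids of sample and {what} do not match")


def subtract_backgrounds(
    sample: RawMeasurement,
    empty_cell: RawMeasurement,
    buffer: RawMeasurement,
    displaced_fraction: float = DEFAULT_DISPLACED_FRACTION,
):
    """Transmission-scale and subtract empty-cell and buffer contributions.

    Returns ``(I_s/t_s − I_ec/t_ec) − (1 − f)·(I_b/t_b − I_ec/t_ec)`` where
    ``f`` is the volume fraction of buffer displaced by the protein.  Negative
    results are clipped to zero (counted in the log); errors propagate in
    quadrature.
    """
    if not (0 <= displaced_fraction < 1):
        raise ValidationError(
            f"displaced_fraction must be in [0, 1), got {displaced_fraction}"
        )
    _check_grids(sample.data, empty_cell.data, "empty cell")
    _check_grids(sample.data, buffer.data, "buffer")
    f = displaced_fraction
    i_s, s_s = _arrays(sample.data)
    i_ec, s_ec = _arrays(empty_cell.data)
    i_b, s_b = _arrays(buffer.data)
    t_s, t_ec, t_b = sample.transmission, empty_cell.transmission, buffer.transmission
    # coefficient of the empty-cell term collapses to −f after expansion
    values = i_s / t_s - (1 - f) * i_b / t_b - f * i_ec / t_ec
    sigma = np.sqrt(
        (s_s / t_s) ** 2 + ((1 - f) * s_b / t_b) ** 2 + (f * s_ec / t_ec) ** 2
    )
    return _rebuild(sample.data, values, sigma)


def normalize_vanadium(corrected, vanadium: RawMeasurement):
    """Divide each q channel by the vanadium elastic intensity at that q.

    Vanadium is a (nearly) purely elastic incoherent scatterer, so this
    removes the per-detector efficiency.  Channels where the vanadium signal
    is not positive are masked with a warning.
    """
    van = vanadium.data
    _check_grids(corrected, van, "vanadium")
    if isinstance(van, QensDataset):
        v = van.s_qw[0].sum(axis=-1) * van.d_omega  # elastic integral per q
        v_sig = np.sqrt((van.sigma[0] ** 2).sum(axis=-1)) * van.d_omega
    else:
        v = van.intensity[0]
        v_sig = van.sigma[0]

    bad = v <= 0
    if np.any(bad):
        log.warning("masking %d q channels with non-positive vanadium", int(bad.sum()))
    v_safe = np.where(bad, 1.0, v)

    values, sigma = _arrays(corrected)
    if isinstance(corrected, QensDataset):
        v_b = v_safe[None, :, None]
        vs_b = v_sig[None, :, None]
    else:
        v_b = v_safe[None, :]
        vs_b = v_sig[None, :]
    out = values / v_b
    out_sig = np.sqrt((sigma / v_b) ** 2 + (values * vs_b / v_b**2) ** 2)
    out_sig = np.where(out_sig > 0, out_sig, np.finfo(float).tiny)
    result = _rebuild(corrected, out, out_sig, clip_negative=False)
    if isinstance(result, ElasticScanSet):
        result.mask &= ~bad
    else:
        result.s_qw[:, bad, :] = 0.0
    return result


def detailed_balance_correct(spectrum: QensDataset) -> QensDataset:
    """Symmetrize measured spectra by multiplying with exp(−ħω/(2·kB·T)).

    A spectrum carrying the exact quantum asymmetry
    S(−ω) = exp(−ħω/kB T)·S(ω) becomes symmetric in ω.
    """
    for c in spectrum.conditions:
        if c.temperature <= 0:
            raise ValidationError("temperature must be positive for detailed balance")
    temps = np.array([c.temperature for c in spectrum.conditions])
    factor = np.exp(
        -CONSTANTS.hbar * spectrum.omega[None, None, :]
        / (2.0 * CONSTANTS.kB * temps[:, None, None])
    )
    return _rebuild(spectrum, spectrum.s_qw * factor, spectrum.sigma * factor,
                    clip_negative=False)


def detailed_balance_factor(omega, temperature: float):
    """Scalar/array symmetrization factor exp(−ħω/(2·kB·T))."""
    return np.exp(-CONSTANTS.hbar * np.asarray(omega) / (2.0 * CONSTANTS.kB * temperature))


def bin_temperature(scans: ElasticScanSet, width: float = 10.0) -> ElasticScanSet:
    """Bin a continuous temperature ramp into fixed-width intervals.

    Each raw scan carries its instantaneous temperature in its condition.
    Bin edges are anchored at the lowest (scan-start) temperature; intensities
    are combined per q channel by inverse-variance weighting, and the bin is
    labelled with the weighted mean temperature of its members.  Empty bins
    are dropped.  Conditions must share a single pressure.
    """
    if width <= 0:
        raise ValidationError("bin width must be positive")
    pressures = {c.pressure for c in scans.conditions}
    if len(pressures) != 1:
        raise ValidationError("bin_temperature expects a single-pressure ramp")
    pressure = pressures.pop()

    temps = np.array([c.temperature for c in scans.conditions])
    t0 = temps.min()
    bin_idx = np.floor((temps - t0) / width).astype(int)

    conditions, inten_rows, sig_rows = [], [], []
    for b in np.unique(bin_idx):
        members = np.where(bin_idx == b)[0]
        w = 1.0 / scans.sigma[members] ** 2  # (n_members, n_q)
        inten = (w * scans.intensity[members]).sum(axis=0) / w.sum(axis=0)
        sig = 1.0 / np.sqrt(w.sum(axis=0))
        t_w = w.sum(axis=1)  # per-scan total weight
        t_label = float((t_w * temps[members]).sum() / t_w.sum())
        conditions.append(Condition(t_label, pressure))
        inten_rows.append(inten)
        sig_rows.append(sig)
    return ElasticScanSet(
        q=scans.q,
        conditions=conditions,
        intensity=np.vstack(inten_rows),
        sigma=np.vstack(sig_rows),
        mask=scans.mask.copy(),
    )


class HysteresisError(RuntimeError):
    """Raised when up- and down-scans disagree beyond tolerance.

    ``discrepancy`` holds the per-(condition, q) significance map
    |I_up − I_down| / sqrt(σ_up² + σ_down²).
    """

    def __init__(self, message: str, discrepancy: np.ndarray):
        super().__init__(message)
        self.discrepancy = discrepancy


def merge_updown(
    up: ElasticScanSet,
    down: ElasticScanSet,
    tolerance_sigma: float = 3.0,
    max_discrepant_fraction: float = 0.01,
) -> ElasticScanSet:
    """Merge up- and down-scans after verifying the absence of hysteresis.

    Per (T, q) point the discrepancy |I_up − I_down|/σ_pair is compared with
    ``tolerance_sigma``; if more than ``max_discrepant_fraction`` of points
    exceed it, the merge is refused with the full discrepancy map attached.
    Otherwise the error-weighted average is returned.
    """
    if up.q.shape != down.q.shape or not np.allclose(up.q, down.q):
        raise ValidationError("up and down scans have different q grids")
    t_up = np.array([c.temperature for c in up.conditions])
    t_down = np.array([c.temperature for c in down.conditions])
    if t_up.shape != t_down.shape or not np.allclose(t_up, t_down, atol=1e-6):
        raise ValidationError("up and down scans have different temperature bins")

    z = np.abs(up.intensity - down.intensity) / np.sqrt(up.sigma**2 + down.sigma**2)
    frac = float(np.mean(z[:, up.mask] > tolerance_sigma))
    if frac > max_discrepant_fraction:
        raise HysteresisError(
            f"hysteresis detected: {frac:.1%} of points discrepant beyond "
            f"{tolerance_sigma}σ (limit {max_discrepant_fraction:.0%})",
            discrepancy=z,
        )
    w_up, w_down = 1.0 / up.sigma**2, 1.0 / down.sigma**2
    inten = (w_up * up.intensity + w_down * down.intensity) / (w_up + w_down)
    sigma = 1.0 / np.sqrt(w_up + w_down)
    return ElasticScanSet(
        q=up.q,
        conditions=list(up.conditions),
        intensity=inten,
        sigma=sigma,
        mask=up.mask & down.mask,
    )


def rebin_energy(
    spectrum: QensDataset,
    step: float = 0.02,
    window: tuple[float, float] = (-1.5, 1.5),
    q_keep: tuple[float, float] = (0.6, 1.8),
) -> QensDataset:
    """Flux-conserving rebin of S(q, ω) onto an even grid inside ``window``.

    Each native point is treated as the average over its own bin; the integral
    over any shared interval is preserved.  q channels outside ``q_keep`` are
    dropped.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    h = spectrum.d_omega
    lo, hi = window  # range of new bin centers, inclusive
    if (lo - step / 2 < spectrum.omega[0] - h / 2 - 1e-9
            or hi + step / 2 > spectrum.omega[-1] + h / 2 + 1e-9):
        raise ValidationError("requested window lies outside the data range")

    n_new = int(round((hi - lo) / step)) + 1
    new_edges = (lo - step / 2) + step * np.arange(n_new + 1)
    new_centers = 0.5 * (new_edges[:-1] + new_edges[1:])

    old_edges = np.concatenate([spectrum.omega - h / 2, [spectrum.omega[-1] + h / 2]])

    keep = (spectrum.q >= q_keep[0] - 1e-12) & (spectrum.q <= q_keep[1] + 1e-12)
    s = spectrum.s_qw[:, keep, :]
    sig = spectrum.sigma[:, keep, :]
    res = spectrum.resolution[keep, :]
    res_sig = spectrum.resolution_sigma[keep, :]

    # overlap fractions of old bins in each new bin
    s_new = np.zeros(s.shape[:-1] + (n_new,))
    var_new = np.zeros_like(s_new)
    res_new = np.zeros(res.shape[:-1] + (n_new,))
    res_var = np.zeros_like(res_new)
    for j in range(n_new):
        a, b = new_edges[j], new_edges[j + 1]
        ov = np.clip(np.minimum(old_edges[1:], b) - np.maximum(old_edges[:-1], a), 0, None)
        f = ov / step  # weight of each old bin in the new bin average
        s_new[..., j] = np.tensordot(s, f, axes=([-1], [0]))
        var_new[..., j] = np.tensordot(sig**2, f**2, axes=([-1], [0]))
        res_new[..., j] = res @ f
        res_var[..., j] = (res_sig**2) @ (f**2)

    d_new = step
    res_area = res_new.sum(axis=-1, keepdims=True) * d_new
    return QensDataset(
        q=spectrum.q[keep],
        omega=new_centers,
        s_qw=s_new,
        sigma=np.sqrt(np.maximum(var_new, np.finfo(float).tiny)),
        resolution=res_new / res_area,
        resolution_sigma=np.sqrt(res_var) / res_area,
        conditions=list(spectrum.conditions),
    )


def reduce_elastic(
    sample: RawMeasurement,
    empty_cell: RawMeasurement,
    buffer: RawMeasurement,
    vanadium: RawMeasurement,
    displaced_fraction: float = DEFAULT_DISPLACED_FRACTION,
) -> ElasticScanSet:
    """Full elastic reduction: subtraction then vanadium normalization."""
    corrected = subtract_backgrounds(sample, empty_cell, buffer, displaced_fraction)
    return normalize_vanadium(corrected, vanadium)


def reduce_qens(
    sample: RawMeasurement,
    empty_cell: RawMeasurement,
    buffer: RawMeasurement,
    vanadium: RawMeasurement,
    displaced_fraction: float = DEFAULT_DISPLACED_FRACTION,
    step: float | None = None,
    window: tuple[float, float] | None = None,
    q_keep: tuple[float, float] | None = None,
) -> QensDataset:
    """Full QENS reduction chain.

    Subtraction → vanadium/detector-efficiency normalization →
    detailed-balance symmetrization → optional flux-conserving rebin.
    """
    corrected = subtract_backgrounds(sample, empty_cell, buffer, displaced_fraction)
    corrected = normalize_vanadium(corrected, vanadium)
    corrected = detailed_balance_correct(corrected)
    if step is not None or window is not None or q_keep is not None:
        h = corrected.d_omega
        corrected = rebin_energy(
            corrected,
            step=step if step is not None else h,
            window=window
            if window is not None
            else (corrected.omega[0] - h / 2, corrected.omega[-1] + h / 2),
            q_keep=q_keep if q_keep is not None else (corrected.q[0], corrected.q[-1]),
        )
    return corrected
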