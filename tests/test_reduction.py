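"""Correction chain: subtraction, normalization, detailed balance, binning."""

import numpy as np
import pytest

from piezodyn import (
    CONSTANTS,
    Condition,
    ElasticScanSet,
    HysteresisError,
    QensDataset,
    RawMeasurement,
    ValidationError,
    bin_temperature,
    detailed_balance_correct,
    merge_updown,
    normalize_vanadium,
    rebin_energy,
    reduce_elastic,
    subtract_backgrounds,
)
from piezodyn import synthetic_data as sd
from piezodyn.reduction import detailed_balance_factor


def _meas(kind, scans, t=1.0):
    return RawMeasurement(kind=kind, transmission=t, data=scans)


def _flat_scans(value, n_q=6, sigma=0.01):
    q = np.linspace(0.5, 3.0, n_q)
    return ElasticScanSet(
        q=q, conditions=[Condition(300.0, 1.0)],
        intensity=np.full((1, n_q), float(value)),
        sigma=np.full((1, n_q), sigma),
    )


def test_self_subtraction_gives_zero():
    s = _flat_scans(0.4)
    out = subtract_backgrounds(_meas("sample", s), _meas("empty_cell", s),
                               _meas("buffer", s), displaced_fraction=0.0)
    assert np.allclose(out.intensity, 0.0, atol=1e-14)


def test_forward_composed_signal_recovered_with_transmissions(elastic_truth):
    bg = sd.BackgroundSpec(transmission_sample=0.9, transmission_cell=0.95,
                           transmission_buffer=0.92)
    truth = sd.GroundTruth(elastic={1.0: elastic_truth}, backgrounds=bg,
                           noise=sd.NoiseSpec(model="none"))
    out = sd.generate_elastic_dataset(truth, pressures=[1.0])
    red = reduce_elastic(out["sample"], out["empty_cell"], out["buffer"],
                         out["vanadium"], displaced_fraction=bg.displaced_fraction)
    ref = out["reference"]
    assert np.allclose(red.intensity, ref.intensity, rtol=1e-10, atol=0)


def test_displaced_fraction_bounds():
    s = _flat_scans(0.4)
    with pytest.raises(ValidationError):
        subtract_backgrounds(_meas("sample", s), _meas("empty_cell", s),
                             _meas("buffer", s), displaced_fraction=1.0)


def test_grid_mismatch_rejected():
    s = _flat_scans(0.4, n_q=6)
    other = _flat_scans(0.4, n_q=5)
    with pytest.raises(ValidationError, match="q grid"):
        subtract_backgrounds(_meas("sample", s), _meas("empty_cell", other),
                             _meas("buffer", s), displaced_fraction=0.0)


def test_flat_vanadium_preserves_shape():
    s = _flat_scans(0.4)
    s.intensity[0] = np.linspace(1.0, 0.2, s.q.size)
    van = _flat_scans(2.0)
    out = normalize_vanadium(s, _meas("vanadium", van))
    assert np.allclose(out.intensity, s.intensity / 2.0)


def test_vanadium_channel_scaling():
    s = _flat_scans(0.4)
    van = _flat_scans(1.0)
    van.intensity[0, 2] = 2.0  # channel c twice the others
    out = normalize_vanadium(s, _meas("vanadium", van))
    flat = normalize_vanadium(s, _meas("vanadium", _flat_scans(1.0)))
    assert out.intensity[0, 2] == pytest.approx(flat.intensity[0, 2] / 2.0)


def test_efficiency_profile_removed_by_vanadium(elastic_truth):
    truth = sd.GroundTruth(elastic={1.0: elastic_truth},
                           noise=sd.NoiseSpec(model="none"))
    out = sd.generate_elastic_dataset(truth, pressures=[1.0],
                                      include_backgrounds=False)
    red = reduce_elastic(out["sample"], out["empty_cell"], out["buffer"],
                         out["vanadium"],
                         displaced_fraction=truth.backgrounds.displaced_fraction)
    assert np.allclose(red.intensity, out["reference"].intensity, rtol=1e-10, atol=0)


def _asymmetric_spectrum(T=300.0):
    omega = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.02), 6)
    q = np.array([1.0])
    sym = (0.2 / np.pi) / (0.2**2 + omega**2)
    raw = sym * np.exp(CONSTANTS.hbar * omega / (2 * CONSTANTS.kB * T))
    res = np.exp(-(omega**2) / (2 * 0.03**2))
    res /= res.sum() * 0.02
    return QensDataset(
        q=q, omega=omega, s_qw=raw[None, None, :],
        sigma=np.full((1, 1, omega.size), 1e-3),
        resolution=res[None, :], conditions=[Condition(T, 1.0)],
    )


def test_detailed_balance_symmetrizes_quantum_asymmetry():
    spec = _asymmetric_spectrum()
    out = detailed_balance_correct(spec)
    s = out.s_qw[0, 0]
    asym = np.max(np.abs(s - s[::-1])) / s.max()
    assert asym < 1e-8


def test_detailed_balance_omega_zero_unchanged():
    spec = _asymmetric_spectrum()
    i0 = np.argmin(np.abs(spec.omega))
    out = detailed_balance_correct(spec)
    assert out.s_qw[0, 0, i0] == pytest.approx(spec.s_qw[0, 0, i0], rel=1e-14)


def test_detailed_balance_factor_value():
    # exp(−1/(2·kB·300)) with the package constants, frozen via sympy
    assert detailed_balance_factor(1.0, 300.0) == pytest.approx(
        0.98735029731485875, rel=1e-12
    )


def test_bin_temperature_single_bin_and_single_point():
    q = np.linspace(0.5, 2.0, 5)
    temps = np.arange(284.0, 293.0)
    scans = ElasticScanSet(
        q=q, conditions=[Condition(float(t), 1.0) for t in temps],
        intensity=np.ones((temps.size, q.size)),
        sigma=np.full((temps.size, q.size), 0.02),
    )
    binned = bin_temperature(scans, width=10.0)
    assert binned.n_conditions == 1
    single = bin_temperature(
        ElasticScanSet(q=q, conditions=[Condition(290.0, 1.0)],
                       intensity=np.ones((1, q.size)),
                       sigma=np.full((1, q.size), 0.02)),
        width=10.0,
    )
    assert single.conditions[0].temperature == pytest.approx(290.0)
    assert np.allclose(single.intensity, 1.0)


def test_bin_temperature_matches_weighted_mean_oracle(rng):
    q = np.linspace(0.5, 2.0, 4)
    temps = np.linspace(284.0, 291.0, 8)
    inten = rng.uniform(0.5, 1.5, size=(8, 4))
    sigma = rng.uniform(0.01, 0.1, size=(8, 4))  # heteroscedastic
    scans = ElasticScanSet(
        q=q, conditions=[Condition(float(t), 1.0) for t in temps],
        intensity=inten, sigma=sigma,
    )
    binned = bin_temperature(scans, width=10.0)
    w = 1.0 / sigma**2
    expected = (w * inten).sum(axis=0) / w.sum(axis=0)
    assert np.allclose(binned.intensity[0], expected, rtol=1e-12, atol=0)
    assert np.allclose(binned.sigma[0], 1 / np.sqrt(w.sum(axis=0)), rtol=1e-12)


def test_merge_identical_scans_reduces_sigma_sqrt2():
    s = _flat_scans(0.4)
    merged = merge_updown(s, s)
    assert np.allclose(merged.intensity, s.intensity)
    assert np.allclose(merged.sigma, s.sigma / np.sqrt(2.0), rtol=1e-12)


def test_merge_refuses_hysteresis_and_reports_map():
    up = _flat_scans(0.4)
    down = _flat_scans(0.4)
    down.intensity += 10.0 * np.sqrt(2.0) * down.sigma  # 10σ pair shift
    with pytest.raises(HysteresisError) as err:
        merge_updown(up, down)
    assert np.all(err.value.discrepancy > 3.0)


def test_merged_scan_beats_either_input(elastic_reference_set, rng):
    ref = elastic_reference_set
    wins = 0
    for _ in range(100):
        up = sd.add_multiplicative_noise(ref, 0.03, rng)
        down = sd.add_multiplicative_noise(ref, 0.03, rng)
        try:
            merged = merge_updown(up, down)
        except HysteresisError:
            continue  # a rare statistical refusal is not a win
        rmse = lambda s: np.sqrt(np.mean((s.intensity - ref.intensity) ** 2))
        wins += rmse(merged) < min(rmse(up), rmse(down))
    assert wins >= 95


def _lorentz_spectrum(gamma=0.2, step=0.02):
    omega = np.round(np.arange(-1.5, 1.5 + 1e-9, step), 9)
    q = np.array([0.8, 1.2])
    s = (gamma / np.pi) / (gamma**2 + omega**2)
    res = np.exp(-(omega**2) / (2 * 0.03**2))
    res /= res.sum() * step
    return QensDataset(
        q=q, omega=omega, s_qw=np.tile(s, (1, 2, 1)),
        sigma=np.full((1, 2, omega.size), 1e-3),
        resolution=np.tile(res, (2, 1)), conditions=[Condition(300.0, 1.0)],
    )


def test_rebin_identity_is_noop():
    spec = _lorentz_spectrum()
    out = rebin_energy(spec, step=0.02, window=(-1.5, 1.5), q_keep=(0.5, 1.5))
    assert np.allclose(out.omega, spec.omega, atol=1e-9)
    assert np.allclose(out.s_qw, spec.s_qw, rtol=1e-12)


def test_rebin_conserves_integral():
    # new bin edges (−1.01 … 0.99 in 0.04 steps) coincide with native edges,
    # so the shared interval's integral must be preserved exactly
    spec = _lorentz_spectrum(step=0.02)
    out = rebin_energy(spec, step=0.04, window=(-0.99, 0.97), q_keep=(0.5, 1.5))
    inner = (spec.omega >= -1.0 - 1e-9) & (spec.omega <= 0.98 + 1e-9)
    before = spec.s_qw[0, 0, inner].sum() * 0.02
    after = out.s_qw[0, 0].sum() * 0.04
    assert after == pytest.approx(before, rel=1e-9)


def test_rebin_matches_analytic_lorentzian_bin_averages():
    gamma, step = 0.2, 0.02
    spec = _lorentz_spectrum(gamma=gamma, step=step)
    # native samples are treated as averages over their own bins; build the
    # analytic fine-bin averages first so rebin input is exactly piecewise
    edges = np.concatenate([spec.omega - step / 2, [spec.omega[-1] + step / 2]])
    cdf = np.arctan(edges / gamma) / np.pi
    fine_avg = np.diff(cdf) / step
    spec.s_qw[0, :, :] = fine_avg
    out = rebin_energy(spec, step=2 * step, window=(-0.99, 0.97), q_keep=(0.5, 1.5))
    new_edges = np.concatenate([out.omega - step, [out.omega[-1] + step]])
    expected = np.diff(np.arctan(new_edges / gamma) / np.pi) / (2 * step)
    assert np.allclose(out.s_qw[0, 0], expected, rtol=1e-6)


def test_rebin_window_outside_data_rejected():
    spec = _lorentz_spectrum()
    with pytest.raises(ValidationError):
        rebin_energy(spec, step=0.02, window=(-2.0, 2.0), q_keep=(0.5, 1.5))


def test_propagated_errors_match_monte_carlo():
    """Reduced σ tracks a 2000-replicate Monte-Carlo of the full chain.

    Run with mild backgrounds/high counts so the clip-at-zero of negative
    subtraction results never triggers (clipping truncates the error
    distribution and is checked separately).
    """
    bg = sd.BackgroundSpec(cell_amp=0.01, buffer_amp=0.02)
    truth = sd.GroundTruth(noise=sd.NoiseSpec(model="poisson", counts=1e6),
                           backgrounds=bg)
    vals, sigs = [], []
    for s in range(2000):
        o = sd.generate_elastic_dataset(truth, pressures=[1.0], seed=s)
        r = reduce_elastic(o["sample"], o["empty_cell"], o["buffer"],
                           o["vanadium"], displaced_fraction=bg.displaced_fraction)
        vals.append(r.intensity)
        sigs.append(r.sigma)
    mc_sigma = np.stack(vals).std(axis=0)
    reported = np.median(np.stack(sigs), axis=0)
    assert np.all(np.abs(mc_sigma - reported) / reported < 0.10)
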