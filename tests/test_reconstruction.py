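"""Interferogram demodulation, unwrapping, flattening, round-trip fidelity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opdcyto.errors import CarrierNotFoundError, OrderOverlapError
from opdcyto.phantom import PhantomSpec, make_cell_phantom, synthesize_interferogram
from opdcyto.reconstruction import (
    DEFAULT_CARRIER,
    Interferogram,
    OPDMap,
    OpticsConfig,
    estimate_carrier,
    extract_complex_field,
    flatten_background,
    phase_to_opd,
    reconstruct_opd,
    unwrap_phase,
)

CFG = OpticsConfig(carrier_frequency=DEFAULT_CARRIER)


def _interior(shape, border=24):
    m = np.zeros(shape, dtype=bool)
    m[border:-border, border:-border] = True
    return m


# ---------------------------------------------------------------- carrier

def test_carrier_estimate_within_one_bin():
    ig = synthesize_interferogram(OPDMap(np.zeros((256, 256))), frame_shape=None)
    est = estimate_carrier(ig)
    for e, t in zip(est, DEFAULT_CARRIER):
        assert abs(e - t) < 1.0 / 256


def test_carrier_estimate_robust_to_noise():
    ig0 = synthesize_interferogram(OPDMap(np.zeros((256, 256))), frame_shape=None)
    ign = synthesize_interferogram(OPDMap(np.zeros((256, 256))), frame_shape=None,
                                   noise_sd=0.05, rng_seed=8)
    e0 = estimate_carrier(ig0)
    en = estimate_carrier(ign)
    for a, b in zip(e0, en):
        assert abs(a - b) < 1.0 / 256


def test_flat_image_has_no_carrier():
    flat = Interferogram(np.full((128, 128), 100, dtype=np.uint8))
    with pytest.raises(CarrierNotFoundError):
        estimate_carrier(flat)


# ---------------------------------------------------------- demodulation

def test_pure_carrier_gives_constant_phase():
    ig = synthesize_interferogram(OPDMap(np.zeros((256, 256))), frame_shape=None)
    field = extract_complex_field(ig, CFG)
    phase = np.angle(field)[_interior(ig.pixels.shape)]
    assert phase.max() - phase.min() < 1e-3  # <= 1 mrad variation


def test_gaussian_bump_phase_matches_analytic():
    """arg(field) reproduces 2*pi*OPD/lambda for a 200 nm Gaussian bump."""
    n = 256
    yy, xx = np.mgrid[0:n, 0:n]
    opd = 200.0 * np.exp(-(((yy - n / 2) ** 2 + (xx - n / 2) ** 2) / (2 * 20**2)))
    ig = synthesize_interferogram(OPDMap(opd), frame_shape=None)
    field = extract_complex_field(ig, CFG)
    phase = np.angle(field)
    inner = _interior(ig.pixels.shape)
    resid = phase - 2 * np.pi * opd / 630.0
    resid -= np.median(resid[inner])
    assert np.sqrt((resid[inner] ** 2).mean()) < 0.02  # rad


def test_fourier_peak_at_configured_carrier():
    ig = synthesize_interferogram(OPDMap(np.zeros((256, 256))), frame_shape=None)
    spec = np.abs(np.fft.fft2(ig.pixels.astype(float) - ig.pixels.mean()))
    fy = np.fft.fftfreq(256)
    half = np.zeros_like(spec, dtype=bool)
    half[:, fy > 0] = True
    iy, ix = np.unravel_index(np.argmax(np.where(half, spec, 0)), spec.shape)
    assert abs(fy[iy] - DEFAULT_CARRIER[0]) <= 1.0 / 256 + 1e-12
    assert abs(fy[ix] - DEFAULT_CARRIER[1]) <= 1.0 / 256 + 1e-12


def test_window_must_not_reach_other_orders():
    with pytest.raises(OrderOverlapError):
        OpticsConfig(carrier_frequency=(0.1, 0.1), fourier_window_radius=0.2)


# ------------------------------------------------------------- unwrapping

@pytest.mark.parametrize("method", ["reliability", "least_squares"])
def test_unwrap_recovers_linear_ramp(method):
    """A wrapped 6*pi ramp is restored to within 0.01 rad."""
    n = 128
    ramp = np.linspace(0, 6 * np.pi, n)[None, :] * np.ones((n, 1))
    wrapped = (ramp + np.pi) % (2 * np.pi) - np.pi
    out = unwrap_phase(wrapped, method=method)
    out = out - out[0, 0] + ramp[0, 0]
    assert np.abs(out - ramp).max() < 0.01


@pytest.mark.parametrize("method", ["reliability", "least_squares"])
def test_unwrap_recovers_gaussian_peak(method):
    n = 128
    yy, xx = np.mgrid[0:n, 0:n]
    true = 8.0 * np.exp(-(((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 15**2)))
    wrapped = (true + np.pi) % (2 * np.pi) - np.pi
    out = unwrap_phase(wrapped, method=method)
    out = out - np.median(out[true < 0.01])
    assert out.max() == pytest.approx(8.0, abs=0.05)


def test_unwrap_identity_when_no_wraps():
    rng = np.random.default_rng(0)
    smooth = 0.5 * np.sin(np.linspace(0, 3, 64))[None, :] * np.ones((64, 1))
    out = unwrap_phase(smooth)
    k = (out - smooth) / (2 * np.pi)
    assert np.allclose(k, np.round(k[0, 0]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_unwrap_congruent_mod_2pi(seed):
    """Output minus input is an exact integer multiple of 2*pi everywhere."""
    rng = np.random.default_rng(seed)
    wrapped = rng.uniform(-np.pi, np.pi, size=(24, 24))
    out = unwrap_phase(wrapped)
    k = (out - wrapped) / (2 * np.pi)
    np.testing.assert_allclose(k, np.round(k), atol=1e-9)


# -------------------------------------------------------------- flattening

def test_flatten_removes_injected_tilt(l_truth):
    values = l_truth.opd_map.values
    ny, nx = values.shape
    tilt = 0.5 * np.arange(nx)[None, :] * np.ones((ny, 1))
    tilted = OPDMap(values + tilt, l_truth.opd_map.object_pixel_pitch_um)
    flat = flatten_background(tilted, mask_exclude=l_truth.cell_mask)
    assert np.sqrt(((flat.values - values) ** 2).mean()) < 1.0


def test_flatten_idempotent_on_flat_map(l_truth):
    flat1 = flatten_background(l_truth.opd_map, mask_exclude=l_truth.cell_mask)
    flat2 = flatten_background(flat1, mask_exclude=l_truth.cell_mask)
    assert np.sqrt(((flat2.values - flat1.values) ** 2).mean()) < 0.1
    bg = ~l_truth.cell_mask
    assert abs(np.median(flat1.values[bg])) < 0.5


def test_flatten_preserves_cell_mass_under_tilt(l_truth):
    values = l_truth.opd_map.values
    ny, nx = values.shape
    tilt = 0.5 * np.arange(nx)[None, :] * np.ones((ny, 1))
    tilted = OPDMap(values + tilt, l_truth.opd_map.object_pixel_pitch_um)
    flat = flatten_background(tilted, mask_exclude=l_truth.cell_mask)
    mass = lambda v: v[l_truth.cell_mask].sum()
    assert mass(flat.values) == pytest.approx(mass(values), rel=0.01)


def test_flatten_requires_background(l_truth):
    from opdcyto.errors import InsufficientBackgroundError

    everything = np.ones_like(l_truth.cell_mask)
    with pytest.raises(InsufficientBackgroundError):
        flatten_background(l_truth.opd_map, mask_exclude=everything)


# ------------------------------------------------------------ conversions

@pytest.mark.parametrize("phase,lam,expected", [
    (2 * np.pi, 630.0, 630.0),
    (0.0, 630.0, 0.0),
    (np.pi, 630.0, 315.0),
])
def test_phase_to_opd_conversion(phase, lam, expected):
    out = phase_to_opd(np.full((4, 4), phase), lam)
    np.testing.assert_allclose(out.values, expected, atol=1e-9)


# -------------------------------------------------------------- round trip

@pytest.mark.parametrize("cls", ["H", "L"])
def test_roundtrip_noise_free_rmse(cls, h_truth, l_truth):
    truth = h_truth if cls == "H" else l_truth
    ig = synthesize_interferogram(truth, frame_shape=None)
    opd = reconstruct_opd(ig, CFG)
    err = opd.values[truth.cell_mask] - truth.opd_map.values[truth.cell_mask]
    assert np.sqrt((err**2).mean()) < 2.0


def test_roundtrip_with_intensity_noise(l_truth):
    ig = synthesize_interferogram(l_truth, noise_sd=0.01, frame_shape=None,
                                  rng_seed=21)
    opd = reconstruct_opd(ig, CFG)
    err = opd.values[l_truth.cell_mask] - l_truth.opd_map.values[l_truth.cell_mask]
    assert np.sqrt((err**2).mean()) < 10.0


def test_roundtrip_zero_opd_stays_flat():
    ig = synthesize_interferogram(OPDMap(np.zeros((200, 200))), frame_shape=None)
    opd = reconstruct_opd(ig, CFG)
    inner = _interior(opd.values.shape)
    assert np.abs(opd.values[inner]).max() < 2.0


def test_roundtrip_linearity(l_truth):
    """Scaling the phantom OPD by c scales the reconstructed mean by c (1%)."""
    means = {}
    for c in (0.5, 1.0, 2.0):
        spec = PhantomSpec.for_class(
            "L", rng_seed=12,
            target_dry_mass_pg=c * 96.0)
        truth = make_cell_phantom(spec)
        ig = synthesize_interferogram(truth, frame_shape=None)
        opd = reconstruct_opd(ig, CFG)
        means[c] = opd.values[truth.cell_mask].mean()
    assert means[2.0] / means[1.0] == pytest.approx(2.0, rel=0.01)
    assert means[0.5] / means[1.0] == pytest.approx(0.5, rel=0.01)


def test_roundtrip_dry_mass_within_2pct(h_truth):
    from opdcyto.morphometry import compute_features

    ig = synthesize_interferogram(h_truth, frame_shape=None)
    opd = reconstruct_opd(ig, CFG)
    feats = compute_features(opd, h_truth.cell_mask)
    assert feats.dry_mass_pg == pytest.approx(h_truth.true_dry_mass_pg, rel=0.02)


def test_reconstruct_with_estimated_carrier(l_truth):
    """Auto carrier estimation is good enough for the same contract."""
    ig = synthesize_interferogram(l_truth, frame_shape=None)
    opd = reconstruct_opd(ig)  # no carrier supplied
    err = opd.values[l_truth.cell_mask] - l_truth.opd_map.values[l_truth.cell_mask]
    assert np.sqrt((err**2).mean()) < 2.0
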