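"""Off-axis interferogram demodulation and OPD-map reconstruction.

An off-axis interferogram records ``I = a + b*cos(2*pi*f.r + phi)`` where
``f`` is the carrier spatial frequency introduced by the tilted reference
beam and ``phi = 2*pi*OPD/lambda`` is the sample phase. In the Fourier
domain the +1 order sits at ``f``; cropping a window around it, returning
to the spatial domain and removing the carrier ramp yields the complex
sample field in a single shot. The phase is then unwrapped, converted to
optical path delay (nm) and flattened against a low-order polynomial
background surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray
from scipy import fft as spfft
from skimage import restoration

from opdcyto.errors import (
    CarrierNotFoundError,
    InsufficientBackgroundError,
    OrderOverlapError,
)

#: Sensor geometry of the 8-bit CMOS camera: 1280 x 1024 pixels of 5.2 um.
CAMERA_SHAPE: tuple[int, int] = (1024, 1280)
CAMERA_PIXEL_PITCH_UM: float = 5.2
MAGNIFICATION: float = 60.0
WAVELENGTH_NM: float = 630.0
#: Object-plane pixel pitch: camera pitch / magnification.
OBJECT_PIXEL_PITCH_UM: float = CAMERA_PIXEL_PITCH_UM / MAGNIFICATION

#: Default carrier: 3.5 pixels/fringe at 45 degrees (fy = fx = 0.2
#: cycles/px, |f| ~ 0.283). This puts the +1 order far enough out that the
#: half-magnitude demodulation window (~0.14 cycles/px) passes most of the
#: optical band while staying clear of the DC and -1 orders.
DEFAULT_CARRIER: tuple[float, float] = (0.2, 0.2)


@dataclass
class Interferogram:
    """8-bit off-axis interferogram with acquisition metadata.

    ``pixels`` is a 2D uint8 raster; ``pixel_pitch_camera_um`` and
    ``magnification`` fix the object-plane sampling; ``wavelength_nm`` is
    the illumination wavelength.
    """

    pixels: NDArray[np.uint8]
    pixel_pitch_camera_um: float = CAMERA_PIXEL_PITCH_UM
    magnification: float = MAGNIFICATION
    wavelength_nm: float = WAVELENGTH_NM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("interferogram must be a 2D raster")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def object_pixel_pitch_um(self) -> float:
        return self.pixel_pitch_camera_um / self.magnification


@dataclass
class OpticsConfig:
    """Optical and demodulation parameters.

    carrier_frequency is (fy, fx) in cycles/pixel; ``None`` means estimate
    it from the spectrum. fourier_window_radius is the crop radius in
    cycles/pixel; ``None`` means 0.8x the carrier magnitude — wide enough
    to pass the phase-gradient sidebands of steep cell rims, while the
    raised-cosine taper keeps the (narrow, high-visibility) DC order and
    the -1 order out.
    """

    wavelength_nm: float = WAVELENGTH_NM
    object_pixel_pitch_um: float = OBJECT_PIXEL_PITCH_UM
    carrier_frequency: tuple[float, float] | None = None
    fourier_window_radius: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.object_pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.carrier_frequency is not None:
            mag = float(np.hypot(*self.carrier_frequency))
            if not 0.0 < mag < 0.5:
                raise OrderOverlapError(
                    f"carrier magnitude {mag:.3f} must lie in (0, 0.5) cycles/px"
                )
            if self.fourier_window_radius is not None and (
                self.fourier_window_radius >= mag
            ):
                raise OrderOverlapError(
                    "window radius must be smaller than the carrier magnitude"
                )
        if self.fourier_window_radius is not None and self.fourier_window_radius <= 0:
            raise ValueError("window radius must be positive")


@dataclass
class OPDMap:
    """2D optical-path-delay raster in nanometres.

    The OPD at a pixel is the integral refractive-index difference between
    object and medium times the object thickness; only the product is
    observable, never the factors separately.
    """

    values: NDArray[np.float64]
    object_pixel_pitch_um: float = OBJECT_PIXEL_PITCH_UM
    provenance: Literal["simulated", "reconstructed"] = "simulated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("OPD map must be a 2D raster")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OPD map contains non-finite values")
        if self.object_pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.object_pixel_pitch_um**2


def _border_taper(shape: tuple[int, int], frac: float = 0.08) -> NDArray:
    """Separable Tukey-style window: flat interior, cosine taper at borders."""

    def axis_window(n: int) -> NDArray:
        w = np.ones(n)
        t = max(4, int(round(frac * n)))
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(t) + 0.5) / t))
        w[:t] = ramp
        w[-t:] = ramp[::-1]
        return w

    return axis_window(shape[0])[:, None] * axis_window(shape[1])[None, :]


def _freq_grids(shape: tuple[int, int]) -> tuple[NDArray, NDArray]:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return fy, fx


def estimate_carrier(
    ig: Interferogram,
    dc_exclusion: float = 0.05,
    min_peak_ratio: float = 10.0,
    subpixel: bool = True,
) -> tuple[float, float]:
    """Locate the +1-order carrier peak in the Fourier spectrum.

    Returns (fy, fx) in cycles/pixel. The DC neighbourhood (radius
    ``dc_exclusion`` cycles/px) is excluded and the search is restricted to
    the half-plane ``fx > 0`` (or fx == 0, fy > 0), which selects the +1
    rather than the conjugate order. Raises :class:`CarrierNotFoundError`
    when the best peak is weaker than ``min_peak_ratio`` times the median
    spectral magnitude (no fringes).
    """
    img = ig.pixels.astype(np.float64)
    spectrum = np.abs(spfft.fft2((img - img.mean()) * _border_taper(img.shape)))
    fy, fx = _freq_grids(spectrum.shape)
    valid = (np.hypot(fy, fx) > dc_exclusion) & (
        (fx > 0) | ((fx == 0) & (fy > 0))
    )
    if not valid.any():
        raise CarrierNotFoundError("raster too small to search for a carrier")
    masked = np.where(valid, spectrum, 0.0)
    iy, ix = np.unravel_index(int(np.argmax(masked)), masked.shape)
    peak = masked[iy, ix]
    floor = np.median(spectrum[valid])
    if floor == 0 or peak / floor < min_peak_ratio:
        raise CarrierNotFoundError(
            f"carrier peak indistinct (peak/median {peak / max(floor, 1e-300):.1f} "
            f"< {min_peak_ratio})"
        )
    cy = float(fy[iy, 0])
    cx = float(fx[0, ix])
    if subpixel:
        # parabolic refinement, one axis at a time, in log magnitude
        def refine(center: float, minus: float, plus: float, step: float) -> float:
            lm, lc, lp = np.log(minus + 1e-30), np.log(center + 1e-30), np.log(plus + 1e-30)
            denom = lm - 2 * lc + lp
            if denom >= 0:
                return 0.0
            return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5)) * step
        ny, nx = spectrum.shape
        cy += refine(spectrum[iy, ix], spectrum[(iy - 1) % ny, ix],
                     spectrum[(iy + 1) % ny, ix], 1.0 / ny)
        cx += refine(spectrum[iy, ix], spectrum[iy, (ix - 1) % nx],
                     spectrum[iy, (ix + 1) % nx], 1.0 / nx)
    return cy, cx


def extract_complex_field(
    ig: Interferogram, cfg: OpticsConfig | None = None
) -> NDArray[np.complex128]:
    """Demodulate the +1 Fourier order into a complex sample field.

    The spectrum is multiplied by a raised-cosine (flat inner 60%, cosine
    taper to the rim) circular window centred on the carrier, inverse
    transformed, and the residual carrier ramp removed by pointwise
    multiplication with ``exp(-2i*pi*f.r)`` — exact for non-integer
    carriers. The output raster has the input dimensions.
    """
    cfg = cfg or OpticsConfig()
    carrier = cfg.carrier_frequency
    if carrier is None:
        carrier = estimate_carrier(ig)
    cy, cx = carrier
    fmag = float(np.hypot(cy, cx))
    if not 0.0 < fmag < 0.5:
        raise OrderOverlapError("carrier magnitude must lie in (0, 0.5) cycles/px")
    radius = cfg.fourier_window_radius
    if radius is None:
        radius = 0.8 * fmag
    if radius >= fmag:
        raise OrderOverlapError(
            "window radius must be smaller than the carrier magnitude "
            "(orders would overlap)"
        )
    img = ig.pixels.astype(np.float64)
    img = img - img.mean()
    # Tukey border taper: the raster is not periodic, and without it the
    # truncated carrier leaks sinc tails across the whole spectrum.
    img = img * _border_taper(img.shape)
    spectrum = spfft.fft2(img)
    fy, fx = _freq_grids(img.shape)
    # distance to carrier on the periodic frequency torus
    dy = (fy - cy + 0.5) % 1.0 - 0.5
    dx = (fx - cx + 0.5) % 1.0 - 0.5
    rho = np.hypot(dy, dx)
    inner = 0.6 * radius
    window = np.zeros_like(rho)
    window[rho <= inner] = 1.0
    taper = (rho > inner) & (rho < radius)
    window[taper] = 0.5 * (1 + np.cos(np.pi * (rho[taper] - inner) / (radius - inner)))
    field = spfft.ifft2(spectrum * window)
    yy = np.arange(img.shape[0])[:, None]
    xx = np.arange(img.shape[1])[None, :]
    field *= np.exp(-2j * np.pi * (cy * yy + cx * xx))
    return field


def _unwrap_least_squares(wrapped: NDArray) -> NDArray:
    """Weightless least-squares (DCT/Poisson) phase unwrapping."""

    def wrap(d: NDArray) -> NDArray:
        return (d + np.pi) % (2 * np.pi) - np.pi

    ny, nx = wrapped.shape
    dy = np.zeros_like(wrapped)
    dx = np.zeros_like(wrapped)
    dy[:-1, :] = wrap(np.diff(wrapped, axis=0))
    dx[:, :-1] = wrap(np.diff(wrapped, axis=1))
    rho = np.zeros_like(wrapped)
    rho += dy
    rho[1:, :] -= dy[:-1, :]
    rho += dx
    rho[:, 1:] -= dx[:, :-1]
    dct = spfft.dctn(rho, norm="ortho")
    i = np.arange(ny)[:, None]
    j = np.arange(nx)[None, :]
    eig = 2 * (np.cos(np.pi * i / ny) + np.cos(np.pi * j / nx) - 2)
    eig[0, 0] = 1.0
    dct /= eig
    dct[0, 0] = 0.0
    return spfft.idctn(dct, norm="ortho")


def unwrap_phase(
    wrapped: NDArray,
    method: Literal["reliability", "least_squares"] = "reliability",
    invalid: NDArray[np.bool_] | None = None,
) -> NDArray[np.float64]:
    """Unwrap a 2D phase raster (values in (-pi, pi]) into a continuous one.

    ``reliability`` sorts pixels by local phase quality before integrating
    (robust around residues); ``least_squares`` solves the discrete Poisson
    equation for the unwrapped surface via DCT. ``invalid`` marks pixels
    with meaningless phase (e.g. zero fringe amplitude) to keep out of the
    unwrapping; they are returned wrapped. Either way the output is forced
    to be congruent to the input: output - input is an exact integer
    multiple of 2*pi at every pixel.
    """
    wrapped = np.asarray(wrapped, dtype=np.float64)
    if method == "reliability":
        if invalid is not None and invalid.any():
            masked = np.ma.array(wrapped, mask=invalid)
            out = np.ma.filled(restoration.unwrap_phase(masked), 0.0)
            out[invalid] = wrapped[invalid]
        else:
            out = np.asarray(restoration.unwrap_phase(wrapped))
    elif method == "least_squares":
        out = _unwrap_least_squares(wrapped)
        # the Poisson solution is zero-mean; recentre it so the residual
        # against the wrapped input clusters at a 2*pi integer before
        # congruence rounding (otherwise half-integer offsets flip branches)
        out = out + np.angle(np.exp(1j * (wrapped - out)).mean())
    else:
        raise ValueError(f"unknown unwrapping method: {method!r}")
    k = np.round((out - wrapped) / (2 * np.pi))
    return wrapped + 2 * np.pi * k


def _poly_terms(order: int, ys: NDArray, xs: NDArray) -> NDArray:
    cols = [
        (ys**p) * (xs**q)
        for p in range(order + 1)
        for q in range(order + 1 - p)
    ]
    return np.column_stack(cols)


def flatten_background(
    opd: OPDMap,
    mask_exclude: NDArray[np.bool_] | None = None,
    order: int = 2,
) -> OPDMap:
    """Remove a low-order polynomial background surface from an OPD map.

    A total-degree-``order`` polynomial is least-squares fitted to the
    pixels outside ``mask_exclude`` (the presumed empty background) and
    subtracted everywhere; the background median is then zeroed. At least
    10% of the raster must be background.
    """
    values = opd.values
    if mask_exclude is None:
        bg = np.ones(values.shape, dtype=bool)
    else:
        bg = ~np.asarray(mask_exclude, dtype=bool)
    if bg.sum() < 0.1 * values.size:
        raise InsufficientBackgroundError(
            f"only {bg.sum()} background pixels out of {values.size} (< 10%)"
        )
    ny, nx = values.shape
    ys = (np.arange(ny) / max(ny - 1, 1) * 2 - 1)[:, None] * np.ones((1, nx))
    xs = np.ones((ny, 1)) * (np.arange(nx) / max(nx - 1, 1) * 2 - 1)[None, :]
    keep = bg.copy()
    for _ in range(3):  # MAD-robust refit: unwrap sheets / hot pixels
        a = _poly_terms(order, ys[keep], xs[keep])
        coeffs, *_ = np.linalg.lstsq(a, values[keep], rcond=None)
        res = values[keep] - a @ coeffs
        mad = np.median(np.abs(res - np.median(res)))
        if mad == 0:
            break
        good = np.abs(res - np.median(res)) < 6 * 1.4826 * mad
        if good.all() or good.sum() < 0.05 * values.size:
            break
        nxt = np.zeros_like(keep)
        nxt[keep] = good
        keep = nxt
    surface = (_poly_terms(order, ys.ravel(), xs.ravel()) @ coeffs).reshape(values.shape)
    flat = values - surface
    flat -= np.median(flat[keep])
    return OPDMap(flat, opd.object_pixel_pitch_um, opd.provenance)


def phase_to_opd(
    phase: NDArray,
    wavelength_nm: float = WAVELENGTH_NM,
    object_pixel_pitch_um: float = OBJECT_PIXEL_PITCH_UM,
) -> OPDMap:
    """Convert a continuous phase raster (rad) to OPD (nm): OPD = phi*lambda/(2*pi)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    values = np.asarray(phase, dtype=np.float64) * wavelength_nm / (2 * np.pi)
    return OPDMap(values, object_pixel_pitch_um, provenance="reconstructed")


def reconstruct_opd(
    ig: Interferogram,
    cfg: OpticsConfig | None = None,
    mask_exclude: NDArray[np.bool_] | None = None,
    flatten_order: int = 2,
    unwrap_method: Literal["reliability", "least_squares"] = "reliability",
    auto_mask: bool = True,
    auto_mask_threshold_nm: float = 30.0,
    auto_mask_dilation_px: int = 5,
) -> OPDMap:
    """Full interferogram-to-OPD pipeline.

    Demodulates the +1 order, unwraps the phase, converts it to OPD and
    flattens the background. When no exclusion mask is given and
    ``auto_mask`` is set, a provisional flattening is used to find the
    sample region (OPD above ``auto_mask_threshold_nm``, dilated), and the
    surface is refitted excluding it — this keeps the cell's own OPD out of
    the background model.
    """
    from skimage.morphology import dilation, disk  # local: optional path

    cfg = cfg or OpticsConfig(wavelength_nm=ig.wavelength_nm,
                              object_pixel_pitch_um=ig.object_pixel_pitch_um)
    field = extract_complex_field(ig, cfg)
    # the border-taper frame carries near-zero fringe amplitude and random
    # phase; keep it out of the unwrapping and the background surface fit
    amplitude = np.abs(field)
    invalid = amplitude < 0.2 * np.median(amplitude)
    ny, nx = invalid.shape
    ty = max(4, int(round(0.08 * ny)))
    tx = max(4, int(round(0.08 * nx)))
    invalid[:ty, :] = invalid[-ty:, :] = True
    invalid[:, :tx] = invalid[:, -tx:] = True
    phase = unwrap_phase(np.angle(field), method=unwrap_method, invalid=invalid)
    opd = phase_to_opd(phase, cfg.wavelength_nm, cfg.object_pixel_pitch_um)

    def finish(flat: OPDMap) -> OPDMap:
        # the invalid border has no meaningful phase: report it as empty
        # background rather than leaking wrapped-phase garbage downstream
        vals = flat.values.copy()
        vals[invalid] = 0.0
        return OPDMap(vals, flat.object_pixel_pitch_um, flat.provenance)

    if mask_exclude is not None:
        return finish(flatten_background(
            opd, np.asarray(mask_exclude, dtype=bool) | invalid,
            order=flatten_order))
    if not auto_mask:
        return finish(flatten_background(
            opd, invalid if invalid.any() else None, order=flatten_order))
    # iterative background estimation: refit the surface while clipping
    # positive outliers (the cell). The clipping passes use a plane
    # (order <= 1), which cannot cup into a cell that covers a large
    # raster fraction; the final fit uses the requested order.
    exclude = invalid.copy()
    clip_order = min(flatten_order, 1)
    for _ in range(6):
        flat = flatten_background(opd, exclude if exclude.any() else None,
                                  order=clip_order)
        bg = ~exclude
        resid = flat.values
        # noise scale from the lower residual side only: the cell
        # contaminates the upper side
        med = np.median(resid[bg])
        lower = med - resid[bg][resid[bg] < med]
        mad = np.median(lower) if lower.size else 0.0
        cut = max(4 * 1.4826 * mad, 0.1 * auto_mask_threshold_nm)
        cell = dilation(resid > cut, disk(auto_mask_dilation_px))
        new_exclude = invalid | cell
        if (~new_exclude).sum() < 0.1 * invalid.size:
            break
        if (new_exclude == exclude).all():
            break
        exclude = new_exclude
    return finish(flatten_background(opd, exclude if exclude.any() else None,
                                     order=flatten_order))
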