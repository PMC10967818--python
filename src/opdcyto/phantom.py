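"""Ground-truthed synthetic neutrophil phantoms, cohorts and interferograms.

The study's raw images are not publicly deposited, so this module emulates
them. Two cell classes with the same 2D geometry statistics but distinct 3D
(OPD) statistics are generated:

* **H cells** — round or banded nucleus with *lower* OPD than the
  cytoplasm (decondensed chromatin), plus focal high-OPD vesicles
  (ROS-containing granules); mean <OPD> ~120 nm, mean dry mass ~59 pg.
* **L cells** — multilobed (polymorphonuclear) nucleus with *higher* OPD
  than the cytoplasm, no vesicles; mean <OPD> ~200 nm, dry mass ~96 pg.

Cohorts mix H cells at ~20% (healthy-donor-like, "BBD") or ~4%
(high-risk-MDS-like). Per-cell feature draws use truncated normals with
SDs defaulting to 15% of the mean; each rendered phantom is globally
rescaled so its integrated dry mass hits the drawn target exactly.
Interferograms are rendered as ``I = a*(1 + v*cos(2*pi*f.r +
2*pi*OPD/lambda))``, optionally with Gaussian intensity noise, quantized
to 8 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import ndimage, stats

from opdcyto.errors import InconsistentMorphologyError, RasterTooSmallError
from opdcyto.morphometry import ALPHA_UM3_PER_PG, perimeter_length_um
from opdcyto.reconstruction import (
    CAMERA_PIXEL_PITCH_UM,
    CAMERA_SHAPE,
    DEFAULT_CARRIER,
    Interferogram,
    OpticsConfig,
    OPDMap,
    OBJECT_PIXEL_PITCH_UM,
)

CellClass = Literal["H", "L"]
NucleusModel = Literal["round", "banded", "lobed"]

#: Nominal (pre-rescale) peak cytoplasmic OPD of the dome profile, nm.
NOMINAL_PEAK_OPD_NM = 250.0
#: Gaussian edge-smoothing applied to the ideal profile, px. Roughly the
#: diffraction-limited PSF of the 60x/1.42 objective at 630 nm sampled at
#: 0.087 um/px.
DEFAULT_SMOOTHING_SIGMA_PX = 2.5

#: Printed per-class feature means (area um^2, perimeter um, <OPD> nm,
#: dry mass pg) for sorted H and L neutrophils.
H_FEATURE_MEANS = {
    "area_um2": 100.0,
    "perimeter_um": 54.0,
    "avg_opd_nm": 120.0,
    "dry_mass_pg": 59.0,
}
L_FEATURE_MEANS = {
    "area_um2": 98.0,
    "perimeter_um": 51.0,
    "avg_opd_nm": 200.0,
    "dry_mass_pg": 96.0,
}
#: Intra-class SDs are not reported; default to 15% of the mean.
RELATIVE_SD = 0.15

H_FRACTION_BBD = 0.20
H_FRACTION_MDS = 0.04


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cell.

    H cells must have ``nucleus_opd_contrast < 1`` (nucleus dimmer than
    cytoplasm) and at least one vesicle; L cells the reverse with no
    vesicles.
    """

    cell_class: CellClass
    cell_radius_um: float = 5.64
    nucleus_model: NucleusModel = "round"
    lobe_count: int = 1
    nucleus_opd_contrast: float = 0.6
    vesicle_count: int = 2
    vesicle_radius_um: float = 0.5
    vesicle_opd_nm: float = 150.0
    target_dry_mass_pg: float = 59.0
    pixel_pitch_um: float = OBJECT_PIXEL_PITCH_UM
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_class not in ("H", "L"):
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.target_dry_mass_pg <= 0:
            raise ValueError("target dry mass must be positive")
        if self.cell_radius_um <= 0:
            raise ValueError("cell radius must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.lobe_count < 1:
            raise ValueError("lobe count must be >= 1")
        if self.vesicle_count < 0:
            raise ValueError("vesicle count must be >= 0")
        if self.cell_class == "H":
            if self.nucleus_opd_contrast >= 1 or self.vesicle_count < 1:
                raise InconsistentMorphologyError(
                    "H cells require nucleus_opd_contrast < 1 and >= 1 vesicle"
                )
        else:
            if self.nucleus_opd_contrast <= 1 or self.vesicle_count != 0:
                raise InconsistentMorphologyError(
                    "L cells require nucleus_opd_contrast > 1 and no vesicles"
                )

    @classmethod
    def for_class(cls, cell_class: CellClass, rng_seed: int = 0, **overrides):
        """Class-typical spec: H = round dim nucleus + vesicles at 59 pg,
        L = 3-lobed bright nucleus at 96 pg."""
        if cell_class == "H":
            base = dict(
                cell_class="H", nucleus_model="round", lobe_count=1,
                nucleus_opd_contrast=0.6, vesicle_count=3,
                target_dry_mass_pg=H_FEATURE_MEANS["dry_mass_pg"],
            )
        else:
            base = dict(
                cell_class="L", nucleus_model="lobed", lobe_count=3,
                nucleus_opd_contrast=1.6, vesicle_count=0,
                target_dry_mass_pg=L_FEATURE_MEANS["dry_mass_pg"],
            )
        base.update(overrides)
        return cls(rng_seed=rng_seed, **base)


@dataclass
class PhantomTruth:
    """A rendered phantom with its ground truth."""

    opd_map: OPDMap
    cell_mask: NDArray[np.bool_]
    nucleus_mask: NDArray[np.bool_]
    vesicle_mask: NDArray[np.bool_]
    true_dry_mass_pg: float
    true_area_um2: float
    true_perimeter_um: float
    spec: PhantomSpec

    @property
    def label(self) -> CellClass:
        return self.spec.cell_class


@dataclass
class CohortParams:
    """Parameters of a synthetic cohort: an H/L mixture with per-class
    feature distributions (truncated normal, truncated at 0)."""

    group_label: Literal["BBD", "MDS"] = "BBD"
    n_cells: int = 400
    h_fraction: float | None = None
    h_feature_means: dict = field(default_factory=lambda: dict(H_FEATURE_MEANS))
    l_feature_means: dict = field(default_factory=lambda: dict(L_FEATURE_MEANS))
    h_feature_sds: dict | None = None
    l_feature_sds: dict | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.h_fraction is None:
            self.h_fraction = (
                H_FRACTION_BBD if self.group_label == "BBD" else H_FRACTION_MDS
            )
        if not 0.0 <= self.h_fraction <= 1.0:
            raise ValueError("h_fraction must lie in [0, 1]")
        if self.h_feature_sds is None:
            self.h_feature_sds = {k: RELATIVE_SD * v for k, v in self.h_feature_means.items()}
        if self.l_feature_sds is None:
            self.l_feature_sds = {k: RELATIVE_SD * v for k, v in self.l_feature_means.items()}
        for sds in (self.h_feature_sds, self.l_feature_sds):
            if any(s <= 0 for s in sds.values()):
                raise ValueError("feature SDs must be positive")


def _disk(yy: NDArray, xx: NDArray, cy: float, cx: float, r: float) -> NDArray:
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _nucleus_mask(
    spec: PhantomSpec, yy: NDArray, xx: NDArray, cy: float, cx: float,
    r_px: float, rng: np.random.Generator,
) -> NDArray[np.bool_]:
    mask = np.zeros(np.broadcast_shapes(yy.shape, xx.shape), dtype=bool)
    if spec.nucleus_model == "round":
        off = rng.uniform(-0.1, 0.1, size=2) * r_px
        mask |= _disk(yy, xx, cy + off[0], cx + off[1], 0.45 * r_px)
    elif spec.nucleus_model == "banded":
        # curved rod: disks along a ~240 degree arc
        phase = rng.uniform(0, 2 * np.pi)
        for t in np.linspace(0, 4 * np.pi / 3, 9):
            mask |= _disk(
                yy, xx,
                cy + 0.42 * r_px * np.sin(phase + t),
                cx + 0.42 * r_px * np.cos(phase + t),
                0.18 * r_px,
            )
    elif spec.nucleus_model == "lobed":
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(spec.lobe_count):
            ang = phase + 2 * np.pi * i / spec.lobe_count + rng.uniform(-0.2, 0.2)
            rad = 0.42 * r_px * rng.uniform(0.9, 1.1)
            mask |= _disk(yy, xx, cy + rad * np.sin(ang), cx + rad * np.cos(ang),
                          0.27 * r_px)
    else:
        raise ValueError(f"unknown nucleus model {spec.nucleus_model!r}")
    return mask


def make_cell_phantom(
    spec: PhantomSpec,
    shape: tuple[int, int] | None = None,
    smoothing_sigma_px: float = DEFAULT_SMOOTHING_SIGMA_PX,
) -> PhantomTruth:
    """Render one cell phantom as an OPD map with ground truth.

    The cell body is a smooth dome ``(1 - (rho/r)^2)^1.5`` (zero-valued and
    C1-continuous at the rim), the nucleus region is multiplied by the
    class OPD contrast, vesicles add focal Gaussian bumps, and the whole
    profile is Gaussian-smoothed then masked to exactly zero outside the
    cell. A final global rescale makes the integrated dry mass equal
    ``spec.target_dry_mass_pg`` exactly.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pitch = spec.pixel_pitch_um
    r_px = spec.cell_radius_um / pitch
    # generous margin: keeps the cell fraction of the raster low enough
    # for background-surface estimation after demodulation
    margin = int(np.ceil(0.6 * r_px + 3 * smoothing_sigma_px)) + 8
    if shape is None:
        n = 2 * int(np.ceil(r_px)) + 2 * margin
        shape = (n, n)
    need = 2 * (r_px + 5)
    if min(shape) < need:
        raise RasterTooSmallError(
            f"raster {shape} cannot contain a cell of radius {r_px:.0f} px "
            f"(needs >= {need:.0f})"
        )
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    yy = np.arange(shape[0], dtype=np.float64)[:, None]
    xx = np.arange(shape[1], dtype=np.float64)[None, :]
    rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / r_px
    # plateau-with-cosine-rim thickness: flat central pad (neutrophils are
    # pancake-like under coverslip/flow), C1-continuous zero at the rim
    rim_start = 0.8
    dome = np.zeros_like(rho)
    dome[rho <= rim_start] = 1.0
    rim = (rho > rim_start) & (rho < 1.0)
    dome[rim] = 0.5 * (1 + np.cos(np.pi * (rho[rim] - rim_start) / (1 - rim_start)))

    cell_mask = rho <= 1.0
    nucleus = _nucleus_mask(spec, yy, xx, cy, cx, r_px, rng) & cell_mask

    profile = NOMINAL_PEAK_OPD_NM * dome
    profile[nucleus] *= spec.nucleus_opd_contrast

    vesicles = np.zeros(shape, dtype=bool)
    if spec.vesicle_count > 0:
        rv_px = spec.vesicle_radius_um / pitch
        placed = 0
        attempts = 0
        while placed < spec.vesicle_count and attempts < 200:
            attempts += 1
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.35, 0.7) * r_px
            vy, vx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            spot = _disk(yy, xx, vy, vx, rv_px)
            if (spot & nucleus).any():
                continue
            profile += spec.vesicle_opd_nm * np.exp(
                -((yy - vy) ** 2 + (xx - vx) ** 2) / (2 * (rv_px / 1.5) ** 2)
            )
            vesicles |= spot
            placed += 1
    vesicles &= cell_mask

    if smoothing_sigma_px > 0:
        profile = ndimage.gaussian_filter(profile, smoothing_sigma_px)
    profile[~cell_mask] = 0.0

    # global rescale: dry mass (pg) = pitch^2 (um^2) * sum(OPD um) / alpha
    mass = pitch**2 * profile.sum() / 1000.0 / ALPHA_UM3_PER_PG
    if mass <= 0:
        raise RasterTooSmallError("degenerate phantom: zero integrated OPD")
    profile *= spec.target_dry_mass_pg / mass

    return PhantomTruth(
        opd_map=OPDMap(profile, pitch, provenance="simulated"),
        cell_mask=cell_mask,
        nucleus_mask=nucleus,
        vesicle_mask=vesicles,
        true_dry_mass_pg=spec.target_dry_mass_pg,
        true_area_um2=float(cell_mask.sum()) * pitch**2,
        true_perimeter_um=perimeter_length_um(cell_mask, pitch),
        spec=spec,
    )


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Normal(mean, sd) truncated at 0 from below."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def sample_class_features(
    cell_class: CellClass,
    n: int,
    means: dict,
    sds: dict,
    rng: np.random.Generator,
    sample_id: str = "sample",
    start_index: int = 0,
) -> pd.DataFrame:
    """Draw n per-cell feature rows for one class."""
    cols = {
        k: _truncated_normal(means[k], sds[k], n, rng)
        for k in ("area_um2", "perimeter_um", "avg_opd_nm", "dry_mass_pg")
    }
    df = pd.DataFrame(cols)
    df.insert(0, "sample_id", sample_id)
    df.insert(
        0, "cell_id",
        [f"{sample_id}-{cell_class}{start_index + i:04d}" for i in range(n)],
    )
    df["label"] = cell_class
    return df


def sample_cohort_features(params: CohortParams, sample_id: str | None = None) -> pd.DataFrame:
    """Draw the per-cell feature table of one cohort (no rendering).

    Each cell is H with probability ``h_fraction`` (independent Bernoulli);
    features are truncated-normal draws from the class distributions. The
    result is reproducible from ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    sample_id = sample_id or params.group_label
    is_h = rng.random(params.n_cells) < params.h_fraction
    n_h = int(is_h.sum())
    feature_names = ("area_um2", "perimeter_um", "avg_opd_nm", "dry_mass_pg")
    cols = {k: np.empty(params.n_cells) for k in feature_names}
    for k in feature_names:
        if n_h:
            cols[k][is_h] = _truncated_normal(
                params.h_feature_means[k], params.h_feature_sds[k], n_h, rng)
        if params.n_cells - n_h:
            cols[k][~is_h] = _truncated_normal(
                params.l_feature_means[k], params.l_feature_sds[k],
                params.n_cells - n_h, rng)
    df = pd.DataFrame(cols)
    df.insert(0, "sample_id", sample_id)
    df.insert(0, "cell_id", [f"{sample_id}-{i:04d}" for i in range(len(df))])
    df["label"] = np.where(is_h, "H", "L")
    return df


def spec_from_features(row, rng_seed: int, pixel_pitch_um: float = OBJECT_PIXEL_PITCH_UM) -> PhantomSpec:
    """Phantom spec matching a drawn feature row: the radius reproduces the
    drawn area, the mass target the drawn dry mass; morphology is the
    class-typical one."""
    radius = math.sqrt(float(row["area_um2"]) / math.pi)
    return PhantomSpec.for_class(
        row["label"], rng_seed=rng_seed,
        cell_radius_um=radius,
        target_dry_mass_pg=float(row["dry_mass_pg"]),
        pixel_pitch_um=pixel_pitch_um,
    )


def sample_cohort(
    params: CohortParams,
    sample_id: str | None = None,
    shape: tuple[int, int] | None = None,
    smoothing_sigma_px: float = DEFAULT_SMOOTHING_SIGMA_PX,
) -> list[PhantomTruth]:
    """Draw a cohort and render every cell as a phantom.

    Cell radii are set from the drawn areas and mass targets from the
    drawn dry masses (perimeter and <OPD> then follow from the rendered
    geometry). Deterministic given ``params.rng_seed``.
    """
    df = sample_cohort_features(params, sample_id=sample_id)
    seed_rng = np.random.default_rng(params.rng_seed + 1)
    seeds = seed_rng.integers(0, 2**31 - 1, size=len(df))
    return [
        make_cell_phantom(spec_from_features(row, int(seeds[i])), shape=shape,
                          smoothing_sigma_px=smoothing_sigma_px)
        for i, (_, row) in enumerate(df.iterrows())
    ]


def embed_center(values: NDArray, shape: tuple[int, int]) -> tuple[NDArray, tuple[int, int]]:
    """Zero-pad a raster into the centre of a larger frame.

    Returns the padded raster and the (row, col) offset of the original's
    top-left corner.
    """
    if values.shape[0] > shape[0] or values.shape[1] > shape[1]:
        raise ValueError(f"cannot embed {values.shape} into {shape}")
    out = np.zeros(shape, dtype=values.dtype)
    oy = (shape[0] - values.shape[0]) // 2
    ox = (shape[1] - values.shape[1]) // 2
    out[oy:oy + values.shape[0], ox:ox + values.shape[1]] = values
    return out, (oy, ox)


def synthesize_interferogram(
    truth: PhantomTruth | OPDMap,
    optics: OpticsConfig | None = None,
    noise_sd: float = 0.0,
    frame_shape: tuple[int, int] | Literal["camera"] | None = "camera",
    visibility: float = 0.8,
    mean_level: float = 110.0,
    rng_seed: int = 0,
) -> Interferogram:
    """Render an off-axis interferogram of an OPD map.

    ``I = a*(1 + v*cos(2*pi*f.r + 2*pi*OPD/lambda))`` plus optional
    Gaussian intensity noise of SD ``noise_sd * a``, quantized to 8 bits.
    By default the map is embedded in the full 1280 x 1024 camera frame;
    ``frame_shape=None`` keeps the map's own raster.
    """
    optics = optics or OpticsConfig()
    opd = truth.opd_map if isinstance(truth, PhantomTruth) else truth
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    carrier = optics.carrier_frequency or DEFAULT_CARRIER
    fmag = float(np.hypot(*carrier))
    if not 0.0 < fmag < 0.5:
        raise ValueError("carrier spatial frequency must lie below Nyquist")
    if frame_shape == "camera":
        frame_shape = CAMERA_SHAPE
    values = opd.values
    if frame_shape is not None and frame_shape != values.shape:
        values, _ = embed_center(values, frame_shape)
    cy, cx = carrier
    yy = np.arange(values.shape[0])[:, None]
    xx = np.arange(values.shape[1])[None, :]
    phase = 2 * np.pi * (cy * yy + cx * xx) + 2 * np.pi * values / optics.wavelength_nm
    intensity = mean_level * (1.0 + visibility * np.cos(phase))
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        intensity = intensity + rng.normal(0.0, noise_sd * mean_level,
                                           size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    magnification = CAMERA_PIXEL_PITCH_UM / optics.object_pixel_pitch_um
    return Interferogram(
        pixels=pixels,
        pixel_pitch_camera_um=CAMERA_PIXEL_PITCH_UM,
        magnification=magnification,
        wavelength_nm=optics.wavelength_nm,
    )
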