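"""En-face OCT-A quantification: flow deficits, perfusion, ETDRS geometry.

Converts grayscale en-face angiograms into per-zone indices:

- choriocapillaris slabs are binarized with a local adaptive threshold; the
  dark (below-threshold) pixels are flow deficits, summarised as count,
  magnification-corrected mean size (µm²) and density (%);
- deep-choroid slabs are binarized globally; dark pixels are vasculature,
  summarised as perfusion density (%);
- a modified ETDRS grid (sub-foveal 1 mm disk, sub-parafoveal 2.5 mm and
  sub-perifoveal 5 mm annuli, with ±45° quadrants) is scaled per eye by the
  ocular magnification correction factor so every participant is measured
  over the same physical retinal region;
- large-vessel projection masks are excluded from both numerator and
  denominator of every density;
- sessions are co-registered by translation-only phase correlation.

Ocular magnification: transverse scale grows with axial length, so the
correction factor defaults to a linear axial-length ratio against a reference
eye of 24.46 mm; a reduced-eye (Bennett-style) alternative is provided.
Corrected flow-deficit size = size × factor².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local, threshold_otsu
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "EnFaceImage",
    "MagnificationModel",
    "ETDRSGrid",
    "MaskedBinaryMap",
    "FlowDeficitMetrics",
    "PerfusionMetrics",
    "RegistrationResult",
    "GridGeometryError",
    "compute_correction_factor",
    "correct_flow_deficit_size",
    "build_etdrs_grid",
    "binarize",
    "apply_vessel_mask",
    "register_sessions",
    "flow_deficit_metrics",
    "perfusion_density",
    "average_replicates",
    "ZONE_RADII_UM",
    "ZONES_BY_SCAN_MM",
    "REFERENCE_AXIAL_LENGTH_MM",
]

#: Physical outer radii (µm) of the modified ETDRS zones: sub-foveal disk of
#: 1 mm diameter, sub-parafoveal annulus to 2.5 mm, sub-perifoveal to 5 mm.
ZONE_RADII_UM: dict[str, tuple[float, float]] = {
    "sub_foveal": (0.0, 500.0),
    "sub_parafoveal": (500.0, 1250.0),
    "sub_perifoveal": (1250.0, 2500.0),
}

#: Zones measured on each scan size: inner zones from the 3 mm scan, the
#: perifoveal annulus from the 6 mm scan.
ZONES_BY_SCAN_MM: dict[float, tuple[str, ...]] = {
    3.0: ("sub_foveal", "sub_parafoveal"),
    6.0: ("sub_perifoveal",),
}

QUADRANTS = ("superior", "inferior", "nasal", "temporal")

#: Reference (emmetropic) axial length, mm; factor = 1 for this eye.
REFERENCE_AXIAL_LENGTH_MM = 24.46


class GridGeometryError(ValueError):
    """Raised when a scaled ETDRS zone does not fit within the image."""


@dataclass
class EnFaceImage:
    """Single-layer en-face angiogram with its scan geometry.

    ``pixels`` is a 2-D grayscale array (any numeric dtype; higher intensity
    = more detected flow).  ``layer`` tags the slab: ``"choriocapillaris"``
    (flow deficits appear dark) or ``"deep_choroid"`` (vasculature appears
    dark).  ``fovea_center_px`` defaults to the image center.
    """

    pixels: np.ndarray
    scan_width_mm: float
    layer: str
    fovea_center_px: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.scan_width_mm <= 0:
            raise ValueError("scan_width_mm must be positive")
        if self.layer not in ("choriocapillaris", "deep_choroid"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.fovea_center_px is None:
            h, w = self.pixels.shape
            self.fovea_center_px = ((h - 1) / 2.0, (w - 1) / 2.0)
        r, c = self.fovea_center_px
        h, w = self.pixels.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("fovea center must lie inside the image")

    @property
    def nominal_pixel_pitch_um(self) -> float:
        """Nominal transverse pixel pitch, µm/px (scan width / columns)."""
        return self.scan_width_mm * 1000.0 / self.pixels.shape[1]

    @property
    def nominal_pixel_area_um2(self) -> float:
        return self.nominal_pixel_pitch_um**2


@dataclass(frozen=True)
class MagnificationModel:
    """Per-eye transverse magnification correction.

    ``correction_factor`` is the ratio of true to nominal transverse scale:
    1 for the reference eye, > 1 for longer (myopic) eyes whose retina is
    imaged at a larger true pitch than the instrument's nominal one.
    """

    axial_length_mm: float
    correction_factor: float
    corneal_radius_mm: float | None = None
    reference_axial_length_mm: float = REFERENCE_AXIAL_LENGTH_MM
    method: str = "linear"


def compute_correction_factor(
    axial_length_mm: float,
    corneal_radius_mm: float | None = None,
    reference_axial_length_mm: float = REFERENCE_AXIAL_LENGTH_MM,
    method: str = "linear",
    sanity_band_mm: tuple[float, float] = (20.0, 30.0),
) -> MagnificationModel:
    """Per-eye magnification correction factor from ocular biometry.

    ``method="linear"`` (default) scales transverse dimensions proportionally
    to axial length: factor = AL / AL_ref.  ``method="reduced_eye"`` uses the
    Bennett reduced-eye relation where the retinal scale is proportional to
    (AL − 1.82 mm), the distance from the eye's single refracting surface's
    nodal point to the retina.  Both equal 1 at the reference axial length
    and increase monotonically with axial length.  ``corneal_radius_mm`` is
    validated and carried on the model for schematic-eye variants but does
    not enter either default formula.
    """
    lo, hi = sanity_band_mm
    if not lo <= axial_length_mm <= hi:
        raise ValueError(
            f"axial length {axial_length_mm} mm outside sanity band [{lo}, {hi}]"
        )
    if corneal_radius_mm is not None and not 6.0 <= corneal_radius_mm <= 10.0:
        raise ValueError("corneal radius outside plausible 6-10 mm band")
    if method == "linear":
        factor = axial_length_mm / reference_axial_length_mm
    elif method == "reduced_eye":
        factor = (axial_length_mm - 1.82) / (reference_axial_length_mm - 1.82)
    else:
        raise ValueError(f"unknown magnification method {method!r}")
    return MagnificationModel(
        axial_length_mm=axial_length_mm,
        correction_factor=factor,
        corneal_radius_mm=corneal_radius_mm,
        reference_axial_length_mm=reference_axial_length_mm,
        method=method,
    )


def correct_flow_deficit_size(size_um2: float, correction_factor: float) -> float:
    """Magnification-corrected flow-deficit area: size × factor²."""
    if size_um2 < 0:
        raise ValueError("flow deficit size must be >= 0")
    if correction_factor <= 0:
        raise ValueError("correction factor must be positive")
    return size_um2 * correction_factor**2


@dataclass
class ETDRSGrid:
    """Magnification-scaled ETDRS zone and quadrant pixel geometry.

    Physical zone radii are fixed on the retina; their pixel radii are
    physical / (nominal pitch × correction factor), so a larger eye (factor
    > 1) has a smaller pixel footprint for the same retinal region.
    Quadrants split each annulus along the ±45° image diagonals (labels use
    the right-eye convention: nasal = image left, temporal = image right).
    """

    center_px: tuple[float, float]
    zone_radii_um: Mapping[str, tuple[float, float]]
    zone_radii_px: Mapping[str, tuple[float, float]]
    zone_masks: Mapping[str, np.ndarray]
    quadrant_masks: Mapping[str, np.ndarray]
    correction_factor: float
    pixel_pitch_um: float

    def zone_mask(self, zone: str, quadrant: str | None = None) -> np.ndarray:
        mask = self.zone_masks[zone]
        if quadrant is not None:
            mask = mask & self.quadrant_masks[quadrant]
        return mask

    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(self.zone_masks)


def build_etdrs_grid(
    image: EnFaceImage,
    correction_factor: float = 1.0,
    zones: tuple[str, ...] | None = None,
) -> ETDRSGrid:
    """Build zone/quadrant membership maps for ``image``.

    ``zones`` defaults to the zones measured on the image's scan size (inner
    two on 3 mm, perifoveal annulus on 6 mm).  Membership is decided by
    pixel-center distance from the fovea center.  Raises
    :class:`GridGeometryError` if the outermost requested zone does not fit.
    """
    if correction_factor <= 0:
        raise ValueError("correction factor must be positive")
    if zones is None:
        try:
            zones = ZONES_BY_SCAN_MM[float(image.scan_width_mm)]
        except KeyError:
            raise GridGeometryError(
                f"no default zone assignment for a {image.scan_width_mm} mm scan"
            ) from None
    pitch = image.nominal_pixel_pitch_um
    cr, cc = image.fovea_center_px
    h, w = image.pixels.shape
    rr, ccg = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - cr, ccg - cc)

    radii_um = {z: ZONE_RADII_UM[z] for z in zones}
    radii_px = {
        z: (r_in / (pitch * correction_factor), r_out / (pitch * correction_factor))
        for z, (r_in, r_out) in radii_um.items()
    }
    outer = max(r_out for _, r_out in radii_px.values())
    edge = min(cr, cc, h - 1 - cr, w - 1 - cc)
    if outer > edge:
        raise GridGeometryError(
            f"outer zone radius {outer:.1f} px exceeds distance to image edge {edge:.1f} px"
        )
    zone_masks = {}
    for z, (r_in, r_out) in radii_px.items():
        zone_masks[z] = (dist >= r_in) & (dist < r_out) if r_in > 0 else dist < r_out

    # quadrants along the +-45 deg diagonals; angle measured from +x (image
    # right), y up (image rows increase downward)
    ang = np.degrees(np.arctan2(-(rr - cr), ccg - cc))
    quadrant_masks = {
        "superior": (ang > 45.0) & (ang <= 135.0),
        "inferior": (ang > -135.0) & (ang <= -45.0),
        "temporal": (ang > -45.0) & (ang <= 45.0),
        "nasal": (ang > 135.0) | (ang <= -135.0),
    }
    return ETDRSGrid(
        center_px=(cr, cc),
        zone_radii_um=radii_um,
        zone_radii_px=radii_px,
        zone_masks=zone_masks,
        quadrant_masks=quadrant_masks,
        correction_factor=correction_factor,
        pixel_pitch_um=pitch,
    )


@dataclass
class MaskedBinaryMap:
    """Binary foreground with an exclusion set.

    For choriocapillaris maps foreground marks flow deficits; for deep
    choroid it marks vasculature.  ``excluded`` pixels (large-vessel shadows,
    registration gaps) are removed from both the numerator and denominator of
    any density.  ``polarity`` records what foreground means.
    """

    foreground: np.ndarray
    excluded: np.ndarray
    polarity: str = "dark_foreground"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.foreground.shape != self.excluded.shape:
            raise ValueError("foreground and excluded must share a shape")
        # enforce the disjointness invariant
        self.foreground = self.foreground & ~self.excluded


def binarize(
    image: EnFaceImage,
    block_size: int = 51,
    offset: float = 25.0,
) -> MaskedBinaryMap:
    """Binarize an en-face image into a dark-foreground map.

    Choriocapillaris: local adaptive (Gaussian-weighted mean) thresholding —
    a pixel is a flow-deficit pixel when its intensity is below the local
    mean minus ``offset`` (intensity units).  Deep choroid: global Otsu
    threshold; dark pixels are vasculature.  A constant image yields an empty
    foreground with a logged warning.  The exact algorithm and window of the
    original analysis are not published; these defaults are implementation
    choices and are recorded in ``params``.
    """
    pixels = np.asarray(image.pixels, dtype=float)
    excluded = np.zeros(pixels.shape, dtype=bool)
    if np.ptp(pixels) == 0:
        logger.warning("constant image: binarization yields empty foreground")
        fg = np.zeros(pixels.shape, dtype=bool)
        params = {"method": "constant", "layer": image.layer}
        return MaskedBinaryMap(fg, excluded, params=params)
    if image.layer == "choriocapillaris":
        if block_size % 2 == 0:
            raise ValueError("block_size must be odd")
        local = threshold_local(pixels, block_size=block_size, method="gaussian")
        fg = pixels < (local - offset)
        params = {
            "method": "local_gaussian_mean",
            "block_size": block_size,
            "offset": offset,
            "layer": image.layer,
        }
    else:
        thr = threshold_otsu(pixels)
        fg = pixels < thr
        params = {"method": "otsu_global", "threshold": float(thr), "layer": image.layer}
    return MaskedBinaryMap(fg, excluded, params=params)


def apply_vessel_mask(bmap: MaskedBinaryMap, vessel_mask: np.ndarray) -> MaskedBinaryMap:
    """Exclude large-vessel projection pixels from a binary map."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != bmap.foreground.shape:
        raise ValueError("vessel mask shape does not match the map")
    return MaskedBinaryMap(
        foreground=bmap.foreground & ~vessel_mask,
        excluded=bmap.excluded | vessel_mask,
        polarity=bmap.polarity,
        params=dict(bmap.params),
    )


@dataclass(frozen=True)
class RegistrationResult:
    dx_px: float
    dy_px: float
    registered: EnFaceImage
    confidence: float
    ok: bool


def register_sessions(
    reference: EnFaceImage,
    moving: EnFaceImage,
    confidence_floor: float = 0.5,
    upsample_factor: int = 1,
) -> RegistrationResult:
    """Rigid translation registration of ``moving`` onto ``reference``.

    Uses phase correlation.  The returned ``(dx_px, dy_px)`` is the estimated
    translation of the moving image's content relative to the reference
    (dx: +right, dy: +down), i.e. the inverse shift is applied to resample
    ``moving`` onto the reference frame.  ``confidence`` is the Pearson
    correlation between the reference and the registered image, clipped to
    [0, 1]; results below ``confidence_floor`` are flagged (``ok=False``) so
    the session can be excluded.
    """
    if moving.pixels.shape != reference.pixels.shape:
        raise ValueError("images must share a shape")
    if moving.layer != reference.layer or moving.scan_width_mm != reference.scan_width_mm:
        raise ValueError("images must share layer and scan size")
    ref = np.asarray(reference.pixels, dtype=float)
    mov = np.asarray(moving.pixels, dtype=float)
    shift, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample_factor, normalization="phase"
    )
    # phase correlation returns the shift to apply to `mov`; content moved by
    # the negative of that
    dy, dx = -float(shift[0]), -float(shift[1])
    registered_px = ndimage.shift(mov, (-dy, -dx), order=1, mode="nearest")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ref.ravel(), registered_px.ravel())[0, 1]
    confidence = float(np.clip(0.0 if np.isnan(corr) else corr, 0.0, 1.0))
    ok = confidence >= confidence_floor
    if not ok:
        logger.warning(
            "registration confidence %.3f below floor %.3f", confidence, confidence_floor
        )
    registered = EnFaceImage(
        pixels=registered_px,
        scan_width_mm=reference.scan_width_mm,
        layer=reference.layer,
        fovea_center_px=reference.fovea_center_px,
        metadata={**moving.metadata, "registered_to_reference": True},
    )
    return RegistrationResult(dx, dy, registered, confidence, ok)


@dataclass(frozen=True)
class FlowDeficitMetrics:
    """Per-zone choriocapillaris flow-deficit indices.

    ``count`` is the number of 8-connected deficit components intersecting
    the zone; ``mean_size_um2`` the magnification-corrected mean component
    area (None when no deficit); ``density_percent`` the deficit fraction of
    the non-excluded zone area.
    """

    count: float | None
    mean_size_um2: float | None
    density_percent: float | None
    zone: str
    quadrant: str | None = None
    flags: tuple[str, ...] = ()

    @property
    def missing(self) -> bool:
        return self.density_percent is None


@dataclass(frozen=True)
class PerfusionMetrics:
    """Per-zone deep-choroid perfusion density (%)."""

    density_percent: float | None
    zone: str
    quadrant: str | None = None
    flags: tuple[str, ...] = ()

    @property
    def missing(self) -> bool:
        return self.density_percent is None


_STRUCTURE_8 = np.ones((3, 3), dtype=int)


def flow_deficit_metrics(
    bmap: MaskedBinaryMap,
    grid: ETDRSGrid,
    zone: str,
    pixel_area_um2: float,
    correction_factor: float = 1.0,
    quadrant: str | None = None,
    min_size_px: int = 1,
) -> FlowDeficitMetrics:
    """Flow-deficit count, mean corrected size (µm²) and density (%) in a zone.

    A deficit is an 8-connected component of foreground pixels; a component
    is counted in every zone it intersects, with its full area entering the
    size average and only its in-zone pixels entering the density.  A single
    unconnected pixel counts as a deficit (``min_size_px=1``).
    """
    zone_mask = grid.zone_mask(zone, quadrant)
    valid = zone_mask & ~bmap.excluded
    n_valid = int(valid.sum())
    if n_valid == 0:
        return FlowDeficitMetrics(
            None, None, None, zone, quadrant, flags=("zone_fully_excluded",)
        )
    labels, n_labels = ndimage.label(bmap.foreground, structure=_STRUCTURE_8)
    in_zone_ids = np.unique(labels[valid & bmap.foreground])
    in_zone_ids = in_zone_ids[in_zone_ids > 0]
    if in_zone_ids.size:
        sizes = ndimage.sum_labels(
            np.ones_like(labels), labels, index=in_zone_ids
        ).astype(int)
        keep = sizes >= min_size_px
        sizes = sizes[keep]
    else:
        sizes = np.array([], dtype=int)
    count = int(sizes.size)
    if count:
        mean_size = correct_flow_deficit_size(
            float(sizes.mean()) * pixel_area_um2, correction_factor
        )
    else:
        mean_size = None
    n_fg = int((bmap.foreground & valid).sum())
    density = 100.0 * n_fg / n_valid
    return FlowDeficitMetrics(count, mean_size, density, zone, quadrant)


def perfusion_density(
    bmap: MaskedBinaryMap,
    grid: ETDRSGrid,
    zone: str,
    quadrant: str | None = None,
) -> PerfusionMetrics:
    """Deep-choroid perfusion density (%) over the non-excluded zone pixels."""
    zone_mask = grid.zone_mask(zone, quadrant)
    valid = zone_mask & ~bmap.excluded
    n_valid = int(valid.sum())
    if n_valid == 0:
        return PerfusionMetrics(None, zone, quadrant, flags=("zone_fully_excluded",))
    n_fg = int((bmap.foreground & valid).sum())
    return PerfusionMetrics(100.0 * n_fg / n_valid, zone, quadrant)


def _avg_field(a: float | None, b: float | None) -> tuple[float | None, bool]:
    if a is None and b is None:
        return None, False
    if a is None:
        return b, True
    if b is None:
        return a, True
    return (a + b) / 2.0, False


def average_replicates(
    metrics_a: FlowDeficitMetrics | PerfusionMetrics,
    metrics_b: FlowDeficitMetrics | PerfusionMetrics,
) -> FlowDeficitMetrics | PerfusionMetrics:
    """Session value: arithmetic mean of the two replicate scans, per field.

    If one replicate is missing the other is used and the result is flagged
    ``single_replicate``; non-integer averaged counts (e.g. 272.5) are valid
    session values.
    """
    if type(metrics_a) is not type(metrics_b):
        raise ValueError("replicates must be the same metric type")
    if metrics_a.zone != metrics_b.zone or metrics_a.quadrant != metrics_b.quadrant:
        raise ValueError("replicates must describe the same zone/quadrant")
    flags: list[str] = []
    if isinstance(metrics_a, FlowDeficitMetrics):
        count, f1 = _avg_field(metrics_a.count, metrics_b.count)
        size, f2 = _avg_field(metrics_a.mean_size_um2, metrics_b.mean_size_um2)
        dens, f3 = _avg_field(metrics_a.density_percent, metrics_b.density_percent)
        if f1 or f2 or f3:
            flags.append("single_replicate")
        if count is None and size is None and dens is None:
            flags.append("both_missing")
        return FlowDeficitMetrics(
            count, size, dens, metrics_a.zone, metrics_a.quadrant, tuple(flags)
        )
    dens, f1 = _avg_field(metrics_a.density_percent, metrics_b.density_percent)
    if f1:
        flags.append("single_replicate")
    if dens is None:
        flags.append("both_missing")
    return PerfusionMetrics(dens, metrics_a.zone, metrics_a.quadrant, tuple(flags))
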