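"""Synthetic en-face angiograms and diurnal cohorts with exact ground truth.

Two families of generators live here.  The image generators emit single-layer
en-face angiogram stand-ins (choriocapillaris speckle with dark flow-deficit
blobs; deep-choroid fields with dark curvilinear vessels) together with an
:class:`ImageTruth` that records the exact pixel sets placed, so that any
quantification step can be checked against a pixel-count oracle.  The cohort
generator draws per-subject rhythm parameters from group-level distributions
and evaluates a single 24-h cosine at the session times, recording the drawn
parameters as a truth table.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chorodiurnal.quantify import EnFaceImage

__all__ = [
    "RhythmParams",
    "CohortConfig",
    "ImageTruth",
    "PlacementError",
    "generate_choriocapillaris_image",
    "generate_deep_choroid_image",
    "generate_projection_vessel_mask",
    "shift_image",
    "generate_diurnal_cohort",
    "default_cohort_config",
]

HOURS_PER_DAY = 24.0


class PlacementError(RuntimeError):
    """Raised when non-overlapping deficit placement fails after bounded retries."""


@dataclass(frozen=True)
class RhythmParams:
    """Group-level generative parameters of a 24-h cosine rhythm.

    ``amplitude_pt`` is the peak-to-trough amplitude (curve maximum minus
    minimum), matching the downstream amplitude convention; the cosine
    coefficient is therefore ``amplitude_pt / 2``.  ``acrophase_h`` is the
    peak time in hours since the study start (9 AM).  The three ``sd_*``
    fields are between-subject standard deviations and ``noise_sd`` is the
    per-measurement (session-to-session) noise, all in index units except
    ``sd_acrophase_h`` (hours).
    """

    mesor: float
    amplitude_pt: float
    acrophase_h: float
    sd_mesor: float = 0.0
    sd_amplitude: float = 0.0
    sd_acrophase_h: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_pt < 0:
            raise ValueError("amplitude_pt must be >= 0")
        if not 0.0 <= self.acrophase_h < HOURS_PER_DAY:
            raise ValueError("acrophase_h must lie in [0, 24)")
        for name in ("sd_mesor", "sd_amplitude", "sd_acrophase_h", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def evaluate(self, times_h: np.ndarray) -> np.ndarray:
        """Noise-free group-mean curve at ``times_h`` (hours since 9 AM)."""
        t = np.asarray(times_h, dtype=float)
        return self.mesor + (self.amplitude_pt / 2.0) * np.cos(
            2.0 * np.pi * (t - self.acrophase_h) / HOURS_PER_DAY
        )


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated 7-session diurnal cohort.

    ``groups`` maps a group label to a mapping ``(index, region) ->
    RhythmParams``.  ``n_per_group`` is either a single count applied to every
    group or a mapping from group label to count (the study design of 24
    myopes and 20 non-myopes needs unequal groups).  ``session_times_h`` are
    hours since the 9 AM study start; the default places 7 sessions every 4 h
    over 24 h, so the first and last sessions share a circadian phase.
    """

    groups: Mapping[str, Mapping[tuple[str, str], RhythmParams]]
    n_per_group: int | Mapping[str, int] = 20
    session_times_h: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.session_times_h, dtype=float)
        if times.size < 2:
            raise ValueError("at least 2 sessions are required")
        if not np.all(np.diff(times) > 0):
            raise ValueError("session times must be strictly increasing")
        for label in self.groups:
            if self.group_size(label) < 2:
                raise ValueError(f"n_per_group for {label!r} must be >= 2")

    def group_size(self, label: str) -> int:
        if isinstance(self.n_per_group, Mapping):
            return int(self.n_per_group[label])
        return int(self.n_per_group)


@dataclass
class ImageTruth:
    """Exact ground truth attached to a generated en-face image."""

    deficit_pixel_sets: list[set[tuple[int, int]]] = field(default_factory=list)
    vessel_mask: np.ndarray | None = None
    true_density_percent: float = 0.0
    perfusion_density_percent: float | None = None

    @property
    def deficit_count(self) -> int:
        return len(self.deficit_pixel_sets)

    def validate(self, shape: tuple[int, int]) -> None:
        """Check internal consistency (disjoint sets, densities from counts)."""
        seen: set[tuple[int, int]] = set()
        total = 0
        for pixels in self.deficit_pixel_sets:
            if seen & pixels:
                raise ValueError("deficit pixel sets overlap")
            seen |= pixels
            total += len(pixels)
        density = 100.0 * total / (shape[0] * shape[1])
        if not math.isclose(density, self.true_density_percent, abs_tol=1e-9):
            raise ValueError("stored density disagrees with pixel count")


def _rasterize_ellipse(
    center_rc: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Pixel-center rasterization of a rotated ellipse; (N, 2) row/col array."""
    cr, cc = center_rc
    a, b = semi_axes
    reach = int(math.ceil(max(a, b))) + 1
    r0, r1 = max(0, int(cr) - reach), min(shape[0], int(cr) + reach + 1)
    c0, c1 = max(0, int(cc) - reach), min(shape[1], int(cc) + reach + 1)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_grid - cc
    u = dc * math.cos(angle) + dr * math.sin(angle)
    v = -dc * math.sin(angle) + dr * math.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.column_stack([rr[inside], cc_grid[inside]])


def generate_choriocapillaris_image(
    width_px: int = 256,
    height_px: int = 256,
    scan_mm: float = 3.0,
    deficit_count: int = 25,
    deficit_size_range_um2: tuple[float, float] = (200.0, 2000.0),
    contrast: float = 0.85,
    noise_sd: float = 10.0,
    seed: int = 0,
    background_mean: float = 180.0,
    max_retries: int = 200,
) -> tuple[EnFaceImage, ImageTruth]:
    """Bright speckled choriocapillaris field with dark flow-deficit blobs.

    Deficits are non-overlapping (and non-adjacent, so 8-connected labelling
    recovers each blob as one component) random ellipses whose areas are drawn
    uniformly from ``deficit_size_range_um2`` and converted to pixels through
    the nominal pixel pitch.  Deficit pixels sit at intensity
    ``background_mean * (1 - contrast)``; Gaussian speckle of ``noise_sd`` is
    added everywhere.  The returned truth records the exact pixel set of every
    blob and the resulting density over the full image.
    """
    if deficit_count < 0:
        raise ValueError("deficit_count must be >= 0")
    lo, hi = deficit_size_range_um2
    if lo <= 0 or hi < lo:
        raise ValueError("deficit sizes must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    pitch_um = scan_mm * 1000.0 / width_px
    pixel_area_um2 = pitch_um**2

    claimed = np.zeros(shape, dtype=bool)  # blobs plus a 1-px separation ring
    deficit_mask = np.zeros(shape, dtype=bool)
    pixel_sets: list[set[tuple[int, int]]] = []
    for k in range(deficit_count):
        placed = False
        for _ in range(max_retries):
            area_px = rng.uniform(lo, hi) / pixel_area_um2
            ratio = rng.uniform(0.5, 2.0)
            a = math.sqrt(max(area_px, 1.0) / math.pi * ratio)
            b = max(area_px, 1.0) / math.pi / a
            angle = rng.uniform(0.0, math.pi)
            margin = max(a, b) + 2.0
            cr = rng.uniform(margin, height_px - margin)
            cc = rng.uniform(margin, width_px - margin)
            coords = _rasterize_ellipse((cr, cc), (a, b), angle, shape)
            if coords.shape[0] == 0:
                coords = np.array([[int(round(cr)), int(round(cc))]])
            rrs, ccs = coords[:, 0], coords[:, 1]
            # require a clear 1-px ring around the candidate blob
            r0, r1 = rrs.min() - 1, rrs.max() + 2
            c0, c1 = ccs.min() - 1, ccs.max() + 2
            if r0 < 0 or c0 < 0 or r1 > height_px or c1 > width_px:
                continue
            if claimed[r0:r1, c0:c1].any():
                continue
            claimed[r0:r1, c0:c1] = True
            deficit_mask[rrs, ccs] = True
            pixel_sets.append({(int(r), int(c)) for r, c in coords})
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place deficit {k + 1}/{deficit_count} without overlap"
            )

    pixels = np.full(shape, background_mean, dtype=float)
    pixels[deficit_mask] = background_mean * (1.0 - contrast)
    if noise_sd > 0:
        pixels += rng.normal(0.0, noise_sd, shape)
    pixels = np.clip(pixels, 0.0, 255.0)

    image = EnFaceImage(
        pixels=pixels,
        scan_width_mm=scan_mm,
        layer="choriocapillaris",
        metadata={"generator": "generate_choriocapillaris_image", "seed": seed},
    )
    n_fg = int(deficit_mask.sum())
    truth = ImageTruth(
        deficit_pixel_sets=pixel_sets,
        true_density_percent=100.0 * n_fg / (height_px * width_px),
    )
    return image, truth


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    h, w = mask.shape
    rad = int(math.ceil(radius))
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2


def generate_deep_choroid_image(
    width_px: int = 256,
    height_px: int = 256,
    scan_mm: float = 3.0,
    target_perfusion_percent: float = 55.0,
    vessel_width_px: int = 6,
    seed: int = 0,
    background_mean: float = 200.0,
    vessel_mean: float = 40.0,
    noise_sd: float = 8.0,
) -> tuple[EnFaceImage, ImageTruth]:
    """Deep-choroid field: dark curvilinear vessels on a bright background.

    Vessel strokes are random walks with slowly drifting heading, stamped as
    disks of diameter ``vessel_width_px``, added until the dark fraction
    reaches ``target_perfusion_percent``; the achieved (exact) fraction is
    stored in the truth and is guaranteed within 2 percentage points of the
    target.
    """
    if not 0.0 < target_perfusion_percent < 100.0:
        raise ValueError("target_perfusion_percent must lie in the open interval (0, 100)")
    if vessel_width_px < 1:
        raise ValueError("vessel_width_px must be >= 1")
    shape = (height_px, width_px)
    total = height_px * width_px
    stamp_area = math.pi * (vessel_width_px / 2.0) ** 2
    if stamp_area / total > 0.02:
        raise ValueError(
            "vessel_width_px too large for the image: a single stroke step "
            "exceeds the 2-percentage-point tolerance on the target"
        )
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    target_frac = target_perfusion_percent / 100.0
    radius = vessel_width_px / 2.0
    step = max(1.0, radius)
    max_steps = int(20 * total * target_frac / stamp_area) + 1000
    steps = 0
    while mask.sum() / total < target_frac:
        # new stroke from a random point, heading drifts as it walks
        r = rng.uniform(0, height_px)
        c = rng.uniform(0, width_px)
        heading = rng.uniform(0, 2 * math.pi)
        length = int(rng.uniform(0.3, 1.2) * max(height_px, width_px))
        for _ in range(length):
            _stamp_disk(mask, r, c, radius)
            steps += 1
            if mask.sum() / total >= target_frac:
                break
            heading += rng.normal(0.0, 0.25)
            r += step * math.sin(heading)
            c += step * math.cos(heading)
            if not (0 <= r < height_px and 0 <= c < width_px):
                break
            if steps > max_steps:
                raise ValueError("target perfusion unreachable with given vessel width")

    achieved = 100.0 * mask.sum() / total
    pixels = np.full(shape, background_mean, dtype=float)
    pixels[mask] = vessel_mean
    if noise_sd > 0:
        pixels += rng.normal(0.0, noise_sd, shape)
    pixels = np.clip(pixels, 0.0, 255.0)
    image = EnFaceImage(
        pixels=pixels,
        scan_width_mm=scan_mm,
        layer="deep_choroid",
        metadata={"generator": "generate_deep_choroid_image", "seed": seed},
    )
    truth = ImageTruth(
        vessel_mask=mask,
        perfusion_density_percent=achieved,
        true_density_percent=achieved,
    )
    return image, truth


def generate_projection_vessel_mask(
    width_px: int = 256,
    height_px: int = 256,
    n_vessels: int = 4,
    vessel_width_px: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Binary mask of large superficial-retinal vessel projections.

    Emulates the shadow mask of the larger overlying retinal vessels: thick,
    nearly straight strokes crossing the field.  Returns a boolean array where
    True marks masked (to-be-excluded) pixels.
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    mask = np.zeros(shape, dtype=bool)
    radius = vessel_width_px / 2.0
    diag = math.hypot(height_px, width_px)
    for _ in range(n_vessels):
        r = rng.uniform(0, height_px)
        c = rng.uniform(0, width_px)
        heading = rng.uniform(0, 2 * math.pi)
        for _ in range(int(diag / max(1.0, radius)) * 2):
            _stamp_disk(mask, r, c, radius)
            heading += rng.normal(0.0, 0.03)  # nearly straight
            r += max(1.0, radius) * math.sin(heading)
            c += max(1.0, radius) * math.cos(heading)
            if not (-radius <= r < height_px + radius and -radius <= c < width_px + radius):
                break
    return mask


def shift_image(
    image: EnFaceImage,
    dx_px: float,
    dy_px: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EnFaceImage:
    """Translate image content by (dx, dy) pixels (dx: +right, dy: +down).

    Edge fill replicates the nearest edge value (recorded in metadata).  Used
    as the fixture for registration round-trips: recovering (dx, dy) with
    :func:`chorodiurnal.quantify.register_sessions` is the contract.
    """
    from scipy import ndimage

    h, w = image.pixels.shape
    if abs(dx_px) >= w or abs(dy_px) >= h:
        raise ValueError("shift must be smaller than the image extent")
    shifted = ndimage.shift(image.pixels, (dy_px, dx_px), order=1, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        shifted = shifted + rng.normal(0.0, noise_sd, shifted.shape)
    meta = dict(image.metadata)
    meta.update({"shift_dx_px": dx_px, "shift_dy_px": dy_px, "edge_fill": "nearest"})
    return EnFaceImage(
        pixels=shifted,
        scan_width_mm=image.scan_width_mm,
        layer=image.layer,
        fovea_center_px=image.fovea_center_px,
        metadata=meta,
    )


def generate_diurnal_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a timed measurement cohort from group rhythm parameters.

    Each subject receives, for every (index, region), parameters drawn from
    the group's :class:`RhythmParams`: mesor and amplitude normal (amplitude
    truncated at 0), acrophase wrapped-normal modulo 24 h.  The measurement at
    time ``t`` is ``mesor + (amplitude/2)·cos(2π(t − acrophase)/24)`` plus
    i.i.d. Gaussian noise.

    Returns
    -------
    cohort : DataFrame
        Long format: subject_id, group, session_time_h, region, index, value.
    truth : DataFrame
        Drawn per-subject parameters: subject_id, group, region, index,
        mesor, amplitude_pt, acrophase_h.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.session_times_h, dtype=float)
    rows = []
    truth_rows = []
    subject_no = 0
    for group_label in config.groups:
        params_map = config.groups[group_label]
        for _ in range(config.group_size(group_label)):
            subject_no += 1
            sid = f"S{subject_no:03d}"
            for (index_name, region), params in params_map.items():
                mesor_s = params.mesor + rng.normal(0.0, 1.0) * params.sd_mesor
                amp_s = max(
                    0.0, params.amplitude_pt + rng.normal(0.0, 1.0) * params.sd_amplitude
                )
                acro_s = (
                    params.acrophase_h + rng.normal(0.0, 1.0) * params.sd_acrophase_h
                ) % HOURS_PER_DAY
                clean = mesor_s + (amp_s / 2.0) * np.cos(
                    2.0 * np.pi * (times - acro_s) / HOURS_PER_DAY
                )
                noise = (
                    rng.normal(0.0, params.noise_sd, times.size)
                    if params.noise_sd > 0
                    else np.zeros(times.size)
                )
                values = clean + noise
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "group": group_label,
                        "region": region,
                        "index": index_name,
                        "mesor": mesor_s,
                        "amplitude_pt": amp_s,
                        "acrophase_h": acro_s,
                    }
                )
                for t, v in zip(times, values):
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": group_label,
                            "session_time_h": t,
                            "region": region,
                            "index": index_name,
                            "value": v,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def default_cohort_config(seed: int = 0, noise_sd: float = 0.5) -> CohortConfig:
    """Study-design defaults: 24 myopes vs 20 non-myopes, 7 sessions over 24 h.

    Group rhythm parameters follow the reported refractive-group contrasts for
    sub-foveal choriocapillaris flow-deficit density (myopes: amplitude
    3.16 ± 1.92 %, acrophase 1:31 AM ± 3.58 h; non-myopes: 2.02 ± 1.10 %,
    5:14 AM ± 3.97 h) and sub-foveal deep-choroid perfusion density (myopes
    1.76 ± 0.90 % vs non-myopes 1.25 ± 0.53 %, shared acrophase 4:48 AM).
    Acrophases are stored as hours after the 9 AM study start (1:31 AM →
    16.517 h).  ``noise_sd`` (session-to-session measurement noise, index
    units) has no reported counterpart and is a simulator choice.
    """
    fdd = "flow_deficit_density"
    dpd = "deep_perfusion_density"
    sf = "sub_foveal"
    groups = {
        "myope": {
            (fdd, sf): RhythmParams(
                mesor=15.0, amplitude_pt=3.16, acrophase_h=16.0 + 31.0 / 60.0,
                sd_mesor=6.7, sd_amplitude=1.92, sd_acrophase_h=3.58, noise_sd=noise_sd,
            ),
            (dpd, sf): RhythmParams(
                mesor=57.22, amplitude_pt=1.76, acrophase_h=19.8,
                sd_mesor=4.41, sd_amplitude=0.90, sd_acrophase_h=4.54, noise_sd=noise_sd,
            ),
        },
        "non_myope": {
            (fdd, sf): RhythmParams(
                mesor=13.1, amplitude_pt=2.02, acrophase_h=20.0 + 14.0 / 60.0,
                sd_mesor=6.7, sd_amplitude=1.10, sd_acrophase_h=3.97, noise_sd=noise_sd,
            ),
            (dpd, sf): RhythmParams(
                mesor=57.22, amplitude_pt=1.25, acrophase_h=19.8,
                sd_mesor=4.41, sd_amplitude=0.53, sd_acrophase_h=4.54, noise_sd=noise_sd,
            ),
        },
    }
    return CohortConfig(
        groups=groups, n_per_group={"myope": 24, "non_myope": 20}, seed=seed
    )
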