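"""Synthetic OCT volumes, fluorescein photographs and longitudinal healing series.

The generators stand in for the raw animal data of a two-arm corneal
debridement study: a spherical-cap anterior cornea inside a 7.5 x 7.5 x 1 mm
scan volume, a circular 6-mm epithelial wound, cobalt-blue fluorescein
photographs with a ruler in frame, and per-animal linear radial wound closure
measured at 0/12/24/36/48/72 h.  Every generator is deterministic for a fixed
seed and records its ground truth in metadata so the measurement pipelines can
be validated against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import CorneaModel, ScanSpec, ValidationError, WoundSpec

__all__ = [
    "NoiseSpec",
    "HealingParams",
    "StudyDesign",
    "OCTVolume",
    "Photo",
    "generate_oct_volume",
    "generate_fluoro_photo",
    "simulate_healing_series",
    "apply_measurement_noise",
]

# Reflectivity levels of the noise-free phantom (arbitrary units).  The en face
# contrast between de-epithelialized stroma and intact epithelium is what the
# segmentation relies on; defaults give a window-averaged contrast well above
# the documented 1.5x minimum.
SURFACE_REFLECTIVITY = 1.0
EPITHELIUM_REFLECTIVITY = 0.12
STROMA_REFLECTIVITY = 0.45


@dataclass(frozen=True)
class NoiseSpec:
    """Noise structure of the two measurement methods.

    ``speckle_contrast`` is the standard deviation of the unit-mean
    multiplicative speckle applied voxel-wise to OCT volumes.  The series-level
    model multiplies true areas by lognormal noise with coefficients of
    variation ``oct_area_cv`` / ``fluoro_area_cv``; ``fluoro_bias`` (>= 1) makes
    fluorescein planimetry read systematically larger than OCT, the direction
    observed when the two methods are compared on the same wounds.
    """

    speckle_contrast: float = 0.35
    background_level: float = 0.03
    oct_area_cv: float = 0.03
    fluoro_bias: float = 1.25
    fluoro_area_cv: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.speckle_contrast < 1:
            raise ValidationError("speckle_contrast must be in [0, 1)")
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")
        if self.oct_area_cv < 0 or self.fluoro_area_cv < 0:
            raise ValidationError("area cv values must be >= 0")
        if self.fluoro_bias < 1:
            raise ValidationError("fluoro_bias must be >= 1")


@dataclass(frozen=True)
class HealingParams:
    """Linear radial closure kinetics: r(t) = max(0, r0 - v t).

    ``closure_speed_mean``/``closure_speed_sd`` are the between-animal mean and
    SD of the radial closure speed v in um/h; ``initial_chord_diameter`` is the
    trephine diameter in mm.
    """

    closure_speed_mean: float = 35.0
    closure_speed_sd: float = 5.0
    initial_chord_diameter: float = 6.0

    def __post_init__(self) -> None:
        if self.closure_speed_mean < 0 or self.closure_speed_sd < 0:
            raise ValidationError("closure speeds must be >= 0")
        if not self.initial_chord_diameter > 0:
            raise ValidationError("initial_chord_diameter must be > 0")


def _default_healing() -> dict:
    return {
        "placebo": HealingParams(closure_speed_mean=35.0),
        "cnac": HealingParams(closure_speed_mean=55.0),
    }


@dataclass(frozen=True)
class StudyDesign:
    """Two-arm parallel-group design with repeated measurements.

    Defaults: 10 animals per arm (20 total), placebo vs C-NAC, measurements at
    wound induction and 12/24/36/48/72 h after it.
    """

    n_per_arm: int = 10
    arms: tuple[str, str] = ("placebo", "cnac")
    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 72.0)
    healing: dict = field(default_factory=_default_healing)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (int(self.n_per_arm) == self.n_per_arm and self.n_per_arm >= 1):
            raise ValidationError("n_per_arm must be a positive integer")
        if len(self.arms) != 2 or len(set(self.arms)) != 2:
            raise ValidationError("exactly two distinct arms required")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 1 or tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValidationError("timepoints must be strictly increasing with first = 0 (baseline)")
        for arm in self.arms:
            if arm not in self.healing:
                raise ValidationError(f"no HealingParams for arm {arm!r}")

    @property
    def n_animals(self) -> int:
        return 2 * self.n_per_arm


@dataclass
class OCTVolume:
    """Reconstructed OCT intensity volume with physical voxel spacing.

    ``intensity`` has shape ``scan.samples`` = (nx, ny, nz), nonnegative finite
    reflectivity, depth along the last axis increasing away from the instrument.
    """

    intensity: np.ndarray
    scan: ScanSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.intensity.shape) != tuple(self.scan.samples):
            raise ValidationError(
                f"intensity shape {self.intensity.shape} != scan samples {self.scan.samples}"
            )
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValidationError("intensities must be finite and >= 0")


@dataclass
class Photo:
    """8-bit RGB photograph, with generator ground truth in metadata when synthetic."""

    rgb: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValidationError("photo must be an (h, w, 3) RGB array")


def generate_oct_volume(
    model: CorneaModel,
    wound: WoundSpec,
    scan: ScanSpec,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    stromal_crater_um: float = 0.0,
    crater_radius_mm: float = 1.0,
) -> OCTVolume:
    """Render a noise-modelled OCT volume of a debrided spherical cornea.

    The phantom contains a bright anterior-surface interface along the model's
    spherical cap; below it, outside the wound, a low-scattering epithelial
    band of the model's thickness followed by brighter stroma; inside the wound
    footprint the epithelial band is absent and stromal reflectivity begins at
    the surface.  Columns whose surface lies beyond the scan depth (peripheral
    cornea) contain background only.  ``stromal_crater_um`` > 0 additionally
    depresses the surface inside a central crater of ``crater_radius_mm`` to
    emulate stromal damage.  Multiplicative speckle per ``noise``; deterministic
    for a fixed seed.
    """
    noise = noise or NoiseSpec()
    nx, ny, nz = scan.samples
    if min(nx, ny, nz) < 32:
        raise ValidationError("degenerate scan: every sample count must be >= 32")
    if wound.chord_diameter > 0:
        wound.check_fits(scan)

    dx, dy, dz = scan.pitch
    X, Y = scan.lateral_grid()
    zsurf = model.surface_depth(X, Y)  # (nx, ny), NaN outside rho < R

    footprint = wound.footprint(scan) if wound.chord_diameter > 0 else np.zeros((nx, ny), bool)

    crater_depth = np.zeros((nx, ny))
    if stromal_crater_um > 0:
        cx, cy = wound.center
        rc = np.hypot(X - cx, Y - cy)
        # smooth-edged crater: full depth in the inner half, cosine taper to rim
        taper = np.clip((crater_radius_mm - rc) / (0.5 * crater_radius_mm), 0.0, 1.0)
        crater_depth = (stromal_crater_um / 1000.0) * np.sin(0.5 * math.pi * taper) ** 2
        zsurf = zsurf + crater_depth

    valid = np.isfinite(zsurf) & (zsurf < scan.extent[2])
    zs = np.where(valid, zsurf, np.inf)  # invalid columns: background only

    t_epi = model.epithelium_thickness / 1000.0  # mm
    interface_hw = max(0.004, 1.5 * dz)  # bright interface band width, mm

    zc = (np.arange(nz) + 0.5) * dz  # (nz,) pixel-centre depths
    intensity = np.empty((nx, ny, nz), dtype=np.float32)

    rng = np.random.default_rng(seed)
    # chunk over x to bound the (chunk, ny, nz) temporaries
    chunk = max(1, int(8e6 / (ny * nz)) or 1)
    for i0 in range(0, nx, chunk):
        i1 = min(nx, i0 + chunk)
        rel = zc[None, None, :] - zs[i0:i1, :, None]  # depth below surface, mm
        fp = footprint[i0:i1, :, None]
        block = np.full(rel.shape, noise.background_level, dtype=np.float32)
        in_tissue = rel >= 0
        # epithelial band only outside the wound; stroma from the surface inside
        epi = in_tissue & (rel < t_epi) & ~fp
        stroma = in_tissue & (epi == False)  # noqa: E712 (array comparison)
        block[stroma] = STROMA_REFLECTIVITY
        block[epi] = EPITHELIUM_REFLECTIVITY
        block[in_tissue & (rel < interface_hw)] = SURFACE_REFLECTIVITY
        if noise.speckle_contrast > 0:
            # unit-mean multiplicative speckle (exponential law, scaled contrast)
            g = 1.0 + noise.speckle_contrast * (rng.exponential(1.0, size=rel.shape) - 1.0)
            block *= g.astype(np.float32)
        intensity[i0:i1] = np.maximum(block, 0.0)

    meta = {
        "seed": int(seed),
        "model": model,
        "wound": wound,
        "noise": noise,
        "stromal_crater_um": float(stromal_crater_um),
        "crater_radius_mm": float(crater_radius_mm),
        "footprint_pixels": int(footprint.sum()),
        "footprint_area_mm2": float(footprint.sum() * dx * dy),
        "true_planar_area_mm2": wound.planar_area,
        "true_cap_area_mm2": wound.cap_area(model.radius_of_curvature) if wound.radius > 0 else 0.0,
        "valid_fraction": float(valid.mean()),
    }
    return OCTVolume(intensity=intensity, scan=scan, metadata=meta)


def generate_fluoro_photo(
    model: CorneaModel,
    wound: WoundSpec,
    mm_per_px: float = 0.043,
    ruler_tick_mm: float = 1.0,
    seed: int = 0,
    fluoro_bias: float = 1.0,
    shape: tuple[int, int] = (480, 640),
    photo_noise_sd: float = 4.0,
) -> Photo:
    """Render a cobalt-blue fluorescein photograph with a ruler in frame.

    The fluorescein pool renders as a bright green quasi-circle whose projected
    diameter is ``chord_diameter * sqrt(fluoro_bias)`` (fluorescein visualizes
    the erosion boundary indirectly and tends to overestimate it); the ruler
    occupies a band at the image bottom with dark ticks every ``ruler_tick_mm``.
    Ground-truth scale and wound geometry go into ``metadata``.
    """
    if mm_per_px <= 0 or ruler_tick_mm <= 0:
        raise ValidationError("mm_per_px and ruler_tick_mm must be > 0")
    if fluoro_bias < 1:
        raise ValidationError("fluoro_bias must be >= 1")
    h, w = shape
    ruler_h = max(40, h // 8)
    eye_h = h - ruler_h

    photo_diam_mm = wound.chord_diameter * math.sqrt(fluoro_bias)
    diam_px = photo_diam_mm / mm_per_px
    if diam_px > min(eye_h, w) - 20:
        raise ValidationError(
            f"wound ({photo_diam_mm:.1f} mm = {diam_px:.0f} px) larger than the photo frame"
        )

    rng = np.random.default_rng(seed)
    img = np.zeros((h, w, 3), dtype=float)
    img[..., 0], img[..., 1], img[..., 2] = 38.0, 58.0, 112.0  # cobalt-blue cornea

    rows, cols = np.mgrid[0:eye_h, 0:w]
    cy_px, cx_px = eye_h / 2.0, w / 2.0
    r_px = np.hypot(rows - cy_px, cols - cx_px)
    if wound.radius > 0:
        if wound.shape == "irregular" and wound.irregularity > 0:
            theta = np.arctan2(rows - cy_px, cols - cx_px)
            bound = wound._boundary_radius(theta) * math.sqrt(fluoro_bias) / mm_per_px
        else:
            bound = diam_px / 2.0
        # soft 1.5-px edge emulating dye pooling at the boundary
        blend = np.clip((bound - r_px) / 1.5 + 0.5, 0.0, 1.0)
        for c, level in enumerate((62.0, 224.0, 120.0)):  # fluorescein green
            img[:eye_h, :, c] = img[:eye_h, :, c] * (1 - blend) + level * blend

    # ruler band: light substrate, dark ticks every ruler_tick_mm
    tick_px = ruler_tick_mm / mm_per_px
    img[eye_h:, :, :] = 205.0
    margin = 8
    n_ticks = 0
    pos = float(margin)
    while pos < w - margin:
        j = int(round(pos))
        img[eye_h + 6 : h - 6, max(j - 1, 0) : j + 1, :] = 25.0
        n_ticks += 1
        pos += tick_px

    if photo_noise_sd > 0:
        img += rng.normal(0.0, photo_noise_sd, size=img.shape)
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    meta = {
        "seed": int(seed),
        "mm_per_px": float(mm_per_px),
        "ruler_tick_mm": float(ruler_tick_mm),
        "ruler_tick_px": float(tick_px),
        "n_ticks": int(n_ticks),
        "ruler_region": (int(eye_h), int(h), 0, int(w)),  # (row0, row1, col0, col1)
        "wound_center_px": (float(cy_px), float(cx_px)),
        "wound_diameter_px": float(diam_px),
        "fluoro_bias": float(fluoro_bias),
        "true_planar_area_mm2": wound.planar_area,
        "photo_truth_area_mm2": wound.planar_area * fluoro_bias,
        "wound": wound,
    }
    return Photo(rgb=rgb, metadata=meta)


def _truncnorm_speeds(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Per-animal closure speeds ~ Normal(mean, sd) truncated at 0 (resampled)."""
    v = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = v < 0
        if not bad.any():
            break
        v[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(v, 0.0)


def _radius_matrix(design: StudyDesign, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal wound radii r(t), shape (n_arms, n_per_arm, n_timepoints), mm.

    Returns (radii, speeds_um_per_h)."""
    t = np.asarray(design.timepoints, dtype=float)
    radii = np.empty((len(design.arms), design.n_per_arm, len(t)))
    speeds = np.empty((len(design.arms), design.n_per_arm))
    for a, arm in enumerate(design.arms):
        hp = design.healing[arm]
        v = _truncnorm_speeds(rng, hp.closure_speed_mean, hp.closure_speed_sd, design.n_per_arm)
        speeds[a] = v
        r0 = hp.initial_chord_diameter / 2.0
        radii[a] = np.maximum(0.0, r0 - (v[:, None] / 1000.0) * t[None, :])
    return radii, speeds


def simulate_healing_series(design: StudyDesign) -> pd.DataFrame:
    """Simulate per-animal true wound trajectories under linear radial closure.

    Returns a long table with one row per animal x timepoint: columns
    ``animal_id, arm, timepoint_h, true_chord_diameter_mm, true_planar_area_mm2``.
    Deterministic for a fixed ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    radii, speeds = _radius_matrix(design, rng)
    t = np.asarray(design.timepoints, dtype=float)
    rows = []
    for a, arm in enumerate(design.arms):
        for s in range(design.n_per_arm):
            animal = f"{arm}-{s + 1:02d}"
            for k, tp in enumerate(t):
                r = radii[a, s, k]
                rows.append(
                    {
                        "animal_id": animal,
                        "arm": arm,
                        "timepoint_h": tp,
                        "true_chord_diameter_mm": 2.0 * r,
                        "true_planar_area_mm2": math.pi * r * r,
                        "closure_speed_um_per_h": speeds[a, s],
                    }
                )
    return pd.DataFrame(rows)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median multiplicative lognormal noise with sample CV = cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(0.0, sigma, size=size)


def apply_measurement_noise(
    series: pd.DataFrame, noise: NoiseSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Apply the series-level measurement model to a truth table.

    Adds ``oct_area_mm2 = truth * LN(cv_oct)`` and
    ``fluoro_area_mm2 = truth * fluoro_bias * LN(cv_fluo)``; a closed wound
    (truth 0) reads 0 under both methods.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    out = series.copy()
    truth = out["true_planar_area_mm2"].to_numpy(dtype=float)
    n = len(truth)
    oct_noise = _lognormal_factor(rng, noise.oct_area_cv, n)
    flu_noise = _lognormal_factor(rng, noise.fluoro_area_cv, n)
    out["oct_area_mm2"] = np.where(truth > 0, truth * oct_noise, 0.0)
    out["fluoro_area_mm2"] = np.where(truth > 0, truth * noise.fluoro_bias * flu_noise, 0.0)
    return out


def simulate_measured_areas(
    design: StudyDesign, noise: NoiseSpec | None = None, seed: int | None = None, n_reps: int = 1
) -> dict[str, np.ndarray]:
    """Vectorized fast-mode study replicates as arrays (for Monte-Carlo work).

    Returns dict with ``truth``, ``oct``, ``fluoro`` arrays of shape
    (n_reps, n_arms, n_per_arm, n_timepoints).  ``seed`` defaults to
    ``design.seed``.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    shape = (n_reps, len(design.arms), design.n_per_arm, len(design.timepoints))
    t = np.asarray(design.timepoints, dtype=float)
    truth = np.empty(shape)
    for a, arm in enumerate(design.arms):
        hp = design.healing[arm]
        v = _truncnorm_speeds(rng, hp.closure_speed_mean, hp.closure_speed_sd, (n_reps, design.n_per_arm))
        r = np.maximum(0.0, hp.initial_chord_diameter / 2.0 - (v[..., None] / 1000.0) * t)
        truth[:, a] = math.pi * r * r
    oct_area = np.where(truth > 0, truth * _lognormal_factor(rng, noise.oct_area_cv, shape), 0.0)
    fluo = np.where(
        truth > 0, truth * noise.fluoro_bias * _lognormal_factor(rng, noise.fluoro_area_cv, shape), 0.0
    )
    return {"truth": truth, "oct": oct_area, "fluoro": fluo}
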