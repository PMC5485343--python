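"""Orchestration of the full in-silico wound-healing study.

``run_simulated_study`` replays the whole experiment: simulate per-animal
healing trajectories, measure every animal-timepoint with both planimetry
methods (either through the full image pipelines, ``images`` mode, or the
series-level measurement-noise model, ``fast`` mode), then run the
longitudinal statistics.  Every run writes the exact configuration used, so
manifest + config fully determine all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as chio
from .fluoro import measure_photo_wound
from .geometry import CorneaModel, ScanSpec, ValidationError, WoundSpec
from .octpipe import (
    OCTConfig,
    SurfaceMap,
    _robust_quadric_fit,
    detect_anterior_surface,
    measure_oct_wound,
)
from .stats import compare_methods, mixed_anova_arrays, rm_anova, summarize_groups
from .synthetic import (
    NoiseSpec,
    OCTVolume,
    StudyDesign,
    apply_measurement_noise,
    generate_fluoro_photo,
    generate_oct_volume,
    simulate_healing_series,
    simulate_measured_areas,
)

__all__ = [
    "RunConfig",
    "StudyOutputs",
    "run_simulated_study",
    "exclude_stromal_damage",
    "replicate_interaction_pvalues",
]

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Everything a study run needs; serializable to a single YAML/JSON file."""

    design: StudyDesign = field(default_factory=StudyDesign)
    model: CorneaModel = field(default_factory=CorneaModel)
    scan: ScanSpec = field(default_factory=ScanSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    oct: OCTConfig = field(default_factory=OCTConfig)
    mode: str = "fast"           # fast | images
    resolution: int | None = 128   # samples/axis in images mode (None = use scan as-is)
    mm_per_px: float = 0.043
    ruler_tick_mm: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("fast", "images"):
            raise ValidationError("mode must be 'fast' or 'images'")

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    "__type__": type(obj).__name__,
                    **{f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)},
                }
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .synthetic import HealingParams

        types = {
            "RunConfig": cls,
            "StudyDesign": StudyDesign,
            "CorneaModel": CorneaModel,
            "ScanSpec": ScanSpec,
            "NoiseSpec": NoiseSpec,
            "OCTConfig": OCTConfig,
            "HealingParams": HealingParams,
        }

        def conv(obj):
            if isinstance(obj, dict) and "__type__" in obj:
                obj = dict(obj)
                klass = types[obj.pop("__type__")]
                fields_ = {f.name for f in dataclasses.fields(klass)}
                kwargs = {}
                for k, v in obj.items():
                    if k not in fields_:
                        continue
                    v = conv(v)
                    if isinstance(v, list):
                        v = tuple(v)
                    kwargs[k] = v
                return klass(**kwargs)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj

        return conv(d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyOutputs:
    """In-memory results of a study run (everything is also written to disk)."""

    outdir: Path
    measurements: pd.DataFrame
    anova: dict
    agreement: object
    summary: pd.DataFrame
    excluded_animals: list


def exclude_stromal_damage(
    volume: OCTVolume,
    surface: SurfaceMap,
    threshold_um: float = 20.0,
    min_area_mm2: float = 0.05,
) -> bool:
    """Baseline exclusion rule: flag volumes whose wound floor dips into the stroma.

    A robust quadric is fitted to the detected surface (craters are rejected
    as outliers); where the detected surface lies more than ``threshold_um``
    below the fit over at least ``min_area_mm2`` of contiguous area, the
    debridement is judged to have damaged the stroma and the animal is
    excluded.  An epithelium-only wound leaves the anterior surface on the
    fitted sphere and is not flagged.
    """
    scan = surface.scan
    X, Y = scan.lateral_grid()
    fit, _, _ = _robust_quadric_fit(X, Y, surface.depth, surface.valid)
    deficit_mm = surface.depth - fit  # positive = deeper than the sphere
    deep = surface.valid & (deficit_mm > threshold_um / 1000.0)
    if not deep.any():
        return False
    from scipy import ndimage

    deep = ndimage.binary_opening(deep, structure=np.ones((3, 3), bool))
    labels, n = ndimage.label(deep)
    if n == 0:
        return False
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return bool(sizes.max() * scan.pixel_area_mm2 >= min_area_mm2)


def _measure_images_mode(
    truth: pd.DataFrame, config: RunConfig, rng: np.random.Generator, raw_dir: Path | None
) -> tuple[pd.DataFrame, list]:
    """Render and measure a volume + photo for every animal-timepoint row."""
    scan = config.scan
    if config.resolution is not None:
        scan = ScanSpec.reduced(config.resolution, extent=config.scan.extent)
    rows = []
    excluded = []
    for _, rec in truth.iterrows():
        d = float(rec["true_chord_diameter_mm"])
        wound = WoundSpec(chord_diameter=d)
        vseed = int(rng.integers(0, 2**31 - 1))
        pseed = int(rng.integers(0, 2**31 - 1))
        volume = generate_oct_volume(config.model, wound, scan, config.noise, seed=vseed)
        if raw_dir is not None:
            chio.write_volume(
                raw_dir / f"{rec['animal_id']}_t{int(rec['timepoint_h']):03d}.tiff", volume
            )
        m_oct = measure_oct_wound(volume, config.model, config.oct)

        if rec["timepoint_h"] == 0:
            surface = detect_anterior_surface(
                volume, config.oct.smoothing_um, config.oct.threshold_quantile
            )
            if exclude_stromal_damage(volume, surface):
                excluded.append(rec["animal_id"])

        photo = generate_fluoro_photo(
            config.model,
            wound,
            mm_per_px=config.mm_per_px,
            ruler_tick_mm=config.ruler_tick_mm,
            seed=pseed,
            fluoro_bias=config.noise.fluoro_bias,
        )
        if raw_dir is not None:
            chio.write_photo(
                raw_dir / f"{rec['animal_id']}_t{int(rec['timepoint_h']):03d}.png", photo
            )
        m_flu = measure_photo_wound(photo, tick_spacing_mm=config.ruler_tick_mm)

        rows.append(
            {
                "animal_id": rec["animal_id"],
                "arm": rec["arm"],
                "timepoint_h": rec["timepoint_h"],
                "true_area_mm2": rec["true_planar_area_mm2"],
                "oct_area_mm2": m_oct.projected_area_mm2,
                "oct_corrected_area_mm2": m_oct.corrected_area_mm2,
                "fluoro_area_mm2": m_flu.area_mm2,
            }
        )
    out = pd.DataFrame(rows)
    excluded = sorted(set(excluded))
    if excluded:
        out = out[~out["animal_id"].isin(excluded)]
    return out, excluded


def _to_long(paired: pd.DataFrame) -> pd.DataFrame:
    keys = ["animal_id", "arm", "timepoint_h"]
    long = paired.melt(
        id_vars=keys,
        value_vars=["oct_area_mm2", "fluoro_area_mm2"],
        var_name="method",
        value_name="area_mm2",
    )
    long["method"] = long["method"].map({"oct_area_mm2": "OCT", "fluoro_area_mm2": "FLUO"})
    return long.sort_values(keys + ["method"]).reset_index(drop=True)


def run_simulated_study(config: RunConfig, outdir: str | Path, write_raw: bool = False) -> StudyOutputs:
    """Simulate, measure and analyze a full two-arm study; write all outputs.

    Output directory contents: ``measurements.csv`` (paired wide table),
    ``measurements_long.csv``, ``anova_oct.csv`` / ``anova_fluo.csv``,
    ``agreement.json``, ``summary.csv``, ``config.yaml`` and ``manifest.json``.
    In ``images`` mode with ``write_raw`` the rendered volumes/photos land in
    ``raw/``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_series, seed_noise, seed_images = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    design = replace(config.design, seed=seed_series)
    truth = simulate_healing_series(design)

    excluded: list = []
    if config.mode == "fast":
        paired = apply_measurement_noise(truth, config.noise, seed=seed_noise)
        paired = paired.rename(columns={"true_planar_area_mm2": "true_area_mm2"})
        paired = paired[
            ["animal_id", "arm", "timepoint_h", "true_area_mm2", "oct_area_mm2", "fluoro_area_mm2"]
        ]
    else:
        raw_dir = None
        if write_raw:
            raw_dir = outdir / "raw"
            raw_dir.mkdir(exist_ok=True)
        paired, excluded = _measure_images_mode(
            truth, config, np.random.default_rng(seed_images), raw_dir
        )

    long = _to_long(paired)
    chio.write_series(outdir / "measurements.csv", paired)
    long.to_csv(outdir / "measurements_long.csv", index=False)

    anova = {}
    for method, fname in (("OCT", "anova_oct.csv"), ("FLUO", "anova_fluo.csv")):
        try:
            res = rm_anova(long, method=method)
        except ValidationError:
            # smoke-scale designs (1 animal/arm) cannot support the ANOVA
            anova[method] = None
            continue
        anova[method] = res
        res.anova_table.to_csv(outdir / fname)

    agreement = compare_methods(paired)
    (outdir / "agreement.json").write_text(
        json.dumps(dataclasses.asdict(agreement), indent=1, default=float)
    )

    summary = summarize_groups(long)
    summary.to_csv(outdir / "summary.csv", index=False)

    config.save(outdir / "config.yaml")
    manifest = {
        "package": "corneaheal",
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": {"series": seed_series, "noise": seed_noise, "images": seed_images},
        "mode": config.mode,
        "n_measurements": int(len(long)),
        "excluded_animals": excluded,
        "interaction_p": {m: (r.interaction_p if r is not None else None) for m, r in anova.items()},
        "pearson_r": agreement.pearson_r,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return StudyOutputs(
        outdir=outdir,
        measurements=paired,
        anova=anova,
        agreement=agreement,
        summary=summary,
        excluded_animals=excluded,
    )


def replicate_interaction_pvalues(
    design: StudyDesign,
    noise: NoiseSpec | None = None,
    n_reps: int = 500,
    seed: int = 0,
    which: str = "oct",
    correction: str | None = None,
) -> np.ndarray:
    """Interaction p-values of ``n_reps`` independent fast-mode study replicates.

    Vectorized across replicates: simulates per-animal trajectories, applies
    the measurement-noise model, and runs the split-plot ANOVA in one batched
    call.  Used for type-I-error and power checks.  ``correction="gg"``
    applies the Greenhouse–Geisser sphericity adjustment per replicate; under
    the generator's between-animal closure-speed heterogeneity (a random-slope
    covariance structure) the uncorrected univariate F is anti-conservative,
    while the adjusted test holds its nominal size.
    """
    from scipy import stats as sps

    from .stats import _gg_epsilon

    sim = simulate_measured_areas(design, noise, seed=seed, n_reps=n_reps)
    Y = sim[which]
    res = mixed_anova_arrays(Y)
    if correction is None:
        return np.asarray(res["p_interaction"])
    if correction != "gg":
        raise ValidationError("correction must be None or 'gg'")
    df = res["df"]
    eps = np.array([_gg_epsilon(y) for y in Y])
    return np.asarray(
        sps.f.sf(res["f_interaction"], eps * df["time:treatment"], eps * df["residual"])
    )
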