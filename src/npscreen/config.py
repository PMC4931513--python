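"""Configuration objects for simulation, image analysis and screen statistics.

All tunable parameters of the pipeline live in three small dataclasses that can
be round-tripped through a single YAML file (see :func:`load_run_config`), so a
run is fully described by one config plus one seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SimulationConfig",
    "AnalysisParams",
    "StatsParams",
    "RunConfig",
    "load_run_config",
    "save_run_config",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic 384-well screen field generator.

    The defaults describe the nominal imaging conditions the generator
    emulates: a 40x widefield screening field holding a couple of dozen
    adherent cells with punctate lysosomal (LAMP1) staining, a nanoparticle
    channel split between lysosome-associated puncta and diffuse cytoplasmic
    signal, a slowly varying additive background and camera noise.

    Attributes
    ----------
    field_shape:
        (height, width) of one field in pixels.
    n_cells_per_field:
        Number of cells planted per field.
    nucleus_radius_range, cell_radius_range, spot_radius_range:
        (min, max) radii in pixels for nuclei, whole cells and LAMP1 spots.
    spots_per_cell_mean:
        Poisson mean of the number of LAMP1 spots per healthy cell (at least
        one spot is always planted so the in-spot NP fraction is realizable).
    np_total_per_cell:
        Total pre-noise nanoparticle intensity deposited in each cell.
    base_in_spot_fraction:
        f0, the fraction of a control cell's NP signal placed inside LAMP1
        spots; a treatment with effect multiplier e plants
        ``clamp(f0 * e, 0, 1)``.
    background_gradient_amplitude:
        Peak-to-trough amplitude of the low-order polynomial background
        surface added to the LAMP1 and NP channels.
    noise_gaussian_sd:
        Additive Gaussian read-noise standard deviation (intensity units).
    noise_poisson:
        If true, replace each pre-noise pixel value by a Poisson draw
        (shot noise).
    apoptotic_fraction, mitotic_fraction, border_cell_fraction:
        Fractions of planted cells rendered as small bright apoptotic nuclei,
        condensed bright mitotic nuclei without a cytoplasm ring, or cells
        whose mask touches the field border.
    bit_depth:
        8 or 16; pixel values are clipped to the corresponding range.
    pixel_size_um:
        Nominal physical pixel size (metadata only; no algorithm uses it).
    seed:
        Default seed when an operation is not given one explicitly.
    """

    field_shape: tuple[int, int] = (256, 256)
    n_cells_per_field: int = 15
    nucleus_radius_range: tuple[float, float] = (3.5, 5.0)
    cell_radius_range: tuple[float, float] = (6.5, 9.0)
    spots_per_cell_mean: float = 4.0
    spot_radius_range: tuple[float, float] = (1.2, 1.8)
    np_total_per_cell: float = 20000.0
    base_in_spot_fraction: float = 0.5
    background_gradient_amplitude: float = 30.0
    noise_gaussian_sd: float = 3.0
    noise_poisson: bool = True
    apoptotic_fraction: float = 0.0
    mitotic_fraction: float = 0.0
    border_cell_fraction: float = 0.0
    bit_depth: int = 16
    pixel_size_um: float = 0.16
    seed: int = 0

    # intensity levels of the rendered structures (arbitrary camera units)
    nucleus_intensity: float = 120.0
    cytoplasm_intensity: float = 10.0
    spot_intensity: float = 150.0
    nuclei_base_level: float = 8.0

    def __post_init__(self) -> None:
        self.field_shape = tuple(int(v) for v in self.field_shape)  # type: ignore[assignment]
        for name in ("apoptotic_fraction", "mitotic_fraction", "border_cell_fraction",
                     "base_in_spot_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nucleus_radius_range", "cell_radius_range", "spot_radius_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < min <= max, got {(lo, hi)}")
        if self.n_cells_per_field < 0:
            raise ValueError("n_cells_per_field must be >= 0")
        if self.spots_per_cell_mean < 0:
            raise ValueError("spots_per_cell_mean must be >= 0")
        if self.np_total_per_cell < 0:
            raise ValueError("np_total_per_cell must be >= 0")
        if self.noise_gaussian_sd < 0:
            raise ValueError("noise_gaussian_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if len(self.field_shape) != 2 or min(self.field_shape) < 8:
            raise ValueError("field_shape must be a (height, width) pair >= 8 px")

    @property
    def max_intensity(self) -> float:
        return float(2 ** self.bit_depth - 1)


@dataclass
class AnalysisParams:
    """Image-analysis parameters: background correction, segmentation,
    spot detection and per-cell QC gates.

    The QC gates are calibrated against the synthetic generator's defaults:
    segmented healthy nuclei measure >= ~33 px^2 with mean intensity <= ~126,
    apoptotic nuclei stay below ~22 px^2 and mitotic nuclei exceed ~150 mean
    intensity, so the default gates (25 px^2, 140) separate the classes with
    a clear margin on both sides.
    """

    rolling_ball_radius: int = 10

    nucleus_smooth_sigma: float = 1.0
    nucleus_min_area: int = 6
    nucleus_split_min_distance: int = 4

    cell_smooth_sigma: float = 1.0
    cell_mask_method: str = "adaptive"  # or "triangle", "otsu"

    spot_tophat_radius: int = 3
    spot_min_contrast: float = 40.0
    spot_min_area: int = 2
    spot_max_area: int = 200
    spot_dilation: int = 0

    apoptotic_area_gate: float = 25.0
    mitotic_intensity_gate: float = 140.0

    coloc_threshold_method: str = "otsu"  # or "percentile"
    coloc_threshold_percentile: float = 75.0


@dataclass
class StatsParams:
    """Screen-statistics parameters: viability rule, normalization scope,
    SD-based phenotype thresholds, validation rule and test settings."""

    min_cells_per_well: int = 50
    min_cells_total: int = 150
    n_replicates: int = 3

    norm_scope: str = "plate_replicate"  # or "plate", "screen"
    mild_sd: float = 2.0
    strong_sd: float = 3.0

    validation_k: int = 2
    direction: str = "decrease"  # screened direction for validation
    welch: bool = False


@dataclass
class RunConfig:
    """End-to-end run description consumed by the CLI."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    fields_per_well: int = 2
    n_replicates: int = 3
    n_neg_wells: int = 4
    treatments: dict[str, float] = field(default_factory=dict)  # treatment -> effect
    genes: dict[str, str] = field(default_factory=dict)  # treatment -> gene (optional)
    well_jitter_cv: float = 0.05
    replicate_cv: float = 0.03


def _asdict(cfg: Any) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    doc = {
        "seed": cfg.seed,
        "fields_per_well": cfg.fields_per_well,
        "n_replicates": cfg.n_replicates,
        "n_neg_wells": cfg.n_neg_wells,
        "treatments": dict(cfg.treatments),
        "genes": dict(cfg.genes),
        "well_jitter_cv": cfg.well_jitter_cv,
        "replicate_cv": cfg.replicate_cv,
        "simulation": _asdict(cfg.simulation),
        "analysis": _asdict(cfg.analysis),
        "stats": _asdict(cfg.stats),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_run_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = doc.get("simulation", {})
    for key in ("field_shape", "nucleus_radius_range", "cell_radius_range",
                "spot_radius_range"):
        if key in sim:
            sim[key] = tuple(sim[key])
    return RunConfig(
        simulation=SimulationConfig(**sim),
        analysis=AnalysisParams(**doc.get("analysis", {})),
        stats=StatsParams(**doc.get("stats", {})),
        seed=int(doc.get("seed", 0)),
        fields_per_well=int(doc.get("fields_per_well", 2)),
        n_replicates=int(doc.get("n_replicates", 3)),
        n_neg_wells=int(doc.get("n_neg_wells", 4)),
        treatments={str(k): float(v) for k, v in (doc.get("treatments") or {}).items()},
        genes={str(k): str(v) for k, v in (doc.get("genes") or {}).items()},
        well_jitter_cv=float(doc.get("well_jitter_cv", 0.05)),
        replicate_cv=float(doc.get("replicate_cv", 0.03)),
    )
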