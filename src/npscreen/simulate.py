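"""Seeded synthetic screen generator with ground truth.

Emulates the statistical structure of a 384-well nanoparticle-trafficking
RNAi screen: fields of segmentable cells (elliptical nuclei inside convex
cytoplasm), punctate LAMP1 staining, an NP channel split between
LAMP1-positive spots and diffuse cytoplasm, polynomial background surfaces,
shot + read noise, and planted per-treatment trafficking effects.

The central planted quantity is the per-cell in-spot NP fraction

    f_cell = clamp(f0 * effect, 0, 1)

where ``f0`` is the control (NEG) in-spot fraction and ``effect`` the
treatment's trafficking-efficiency multiplier (NEG == 1.0).  Pre-noise, the
NP intensity placed inside a cell's spot masks is exactly ``f_cell`` times
the cell's total NP intensity, so every downstream estimate can be checked
against exact ground truth.

Three entry points, from slowest/most realistic to fastest:

- :func:`simulate_field` — one multi-channel field plus ground-truth masks.
- :func:`simulate_screen` — all fields of a plate layout, with per-replicate
  and per-well variability injected into the planted effects.
- :func:`simulate_well_table` — imageless per-well records for testing the
  screen statistics at full 348-gene scale in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import SimulationConfig
from .io import FieldImage, validate_layout

__all__ = [
    "GroundTruth",
    "ScreenTruth",
    "DegenerateGeometryError",
    "simulate_field",
    "simulate_screen",
    "simulate_well_table",
]


class DegenerateGeometryError(ValueError):
    """Raised when the configured cells cannot be placed in the field."""


@dataclass
class GroundTruth:
    """Planted truth for one field: label maps, per-cell table, background.

    ``cells`` columns: cell_id, cy, cx, nucleus_radius, cell_radius,
    is_apoptotic, is_mitotic, is_border, n_spots, f_cell, np_total.
    ``f_cell`` is the realized pre-noise in-spot NP fraction (0 for cells
    rendered without spots).
    """

    cells: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    spot_labels: np.ndarray
    spot_to_cell: dict[int, int]
    background: np.ndarray
    effect: float

    def true_field_ratio(self) -> float:
        """Planted (sum NP in spots) / (sum NP in cells) for this field."""
        t = self.cells
        tot = float((t["np_total"]).sum())
        if tot == 0:
            return float("nan")
        return float((t["f_cell"] * t["np_total"]).sum() / tot)


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen: per-well planted effects and the
    per-field GroundTruth objects keyed like the emitted FieldImages."""

    well_table: pd.DataFrame
    field_truths: list[GroundTruth] = dataclass_field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_mask(shape, cy, cx, ry, rx, theta):
    h, w = shape
    y0 = max(0, int(np.floor(cy - max(ry, rx) - 1)))
    y1 = min(h, int(np.ceil(cy + max(ry, rx) + 2)))
    x0 = max(0, int(np.floor(cx - max(ry, rx) - 1)))
    x1 = min(w, int(np.ceil(cx + max(ry, rx) + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    local = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    mask = np.zeros(shape, bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator):
    """Choose cell centers, radii and special-status flags.

    Non-border cells are kept a full cell radius away from every edge; border
    cells are deliberately pushed so their mask crosses an edge.  Centers are
    rejected until all pairwise distances exceed ~the sum of cell radii.
    """
    h, w = cfg.field_shape
    n = cfg.n_cells_per_field
    n_border = int(round(cfg.border_cell_fraction * n))
    n_apo = int(round(cfg.apoptotic_fraction * n))
    n_mit = int(round(cfg.mitotic_fraction * n))
    if n_border + 0 > n:
        raise DegenerateGeometryError("border_cell_fraction exceeds cell count")

    flags = []
    for i in range(n):
        flags.append({
            "is_border": i < n_border,
            "is_apoptotic": n_border <= i < n_border + n_apo,
            "is_mitotic": n_border + n_apo <= i < n_border + n_apo + n_mit,
        })

    cells = []
    max_attempts = 500 * max(n, 1)
    attempts = 0
    for flag in flags:
        cr = rng.uniform(*cfg.cell_radius_range)
        nr = rng.uniform(*cfg.nucleus_radius_range)
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise DegenerateGeometryError(
                    f"could not place {n} cells of radius ~{cr:.0f} px "
                    f"in a {h}x{w} field"
                )
            if flag["is_border"]:
                edge = rng.integers(0, 4)
                off = rng.uniform(0.2, 0.6) * cr
                if edge == 0:
                    cy, cx = off, rng.uniform(cr, w - cr)
                elif edge == 1:
                    cy, cx = h - 1 - off, rng.uniform(cr, w - cr)
                elif edge == 2:
                    cy, cx = rng.uniform(cr, h - cr), off
                else:
                    cy, cx = rng.uniform(cr, h - cr), w - 1 - off
            else:
                if 2 * (cr + 1) >= min(h, w):
                    raise DegenerateGeometryError(
                        f"cell radius {cr:.0f} px cannot fit inside a "
                        f"{h}x{w} field away from the border"
                    )
                cy = rng.uniform(cr + 1, h - 2 - cr)
                cx = rng.uniform(cr + 1, w - 2 - cr)
            ok = all(
                np.hypot(cy - c["cy"], cx - c["cx"]) >= 0.95 * (cr + c["cell_radius"])
                for c in cells
            )
            if ok:
                break
        cells.append({
            "cy": cy, "cx": cx, "cell_radius": cr, "nucleus_radius": nr,
            "theta": rng.uniform(0, np.pi), **flag,
        })
    return cells


# ---------------------------------------------------------------------------


def simulate_field(
    config: SimulationConfig,
    effect: float = 1.0,
    seed: int | None = None,
) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic 3-channel field with planted ground truth.

    With noise and background switched off
    (``noise_gaussian_sd=0, noise_poisson=False,
    background_gradient_amplitude=0``) the NP channel satisfies exactly:
    sum over a cell's spot pixels == ``f_cell`` times the sum over the cell
    mask, with ``f_cell = clamp(f0 * effect, 0, 1)``.
    """
    if effect < 0:
        raise ValueError(f"effect multiplier must be >= 0, got {effect}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.field_shape
    placed = _place_cells(config, rng)

    nucleus_labels = np.zeros((h, w), np.int32)
    cell_labels = np.zeros((h, w), np.int32)
    spot_labels = np.zeros((h, w), np.int32)
    spot_to_cell: dict[int, int] = {}

    ch_nuc = np.full((h, w), config.nuclei_base_level, float)
    ch_lamp = np.zeros((h, w), float)
    ch_np = np.zeros((h, w), float)

    f_base = min(max(config.base_in_spot_fraction * effect, 0.0), 1.0)
    rows = []
    spot_id = 0
    for cid, c in enumerate(placed, start=1):
        nr, cr, theta = c["nucleus_radius"], c["cell_radius"], c["theta"]
        aspect = rng.uniform(0.75, 1.0)
        if c["is_apoptotic"]:
            nry = nrx = nr * 0.35
            nuc_gain = 2.5
        elif c["is_mitotic"]:
            nry = nrx = nr * 0.8
            nuc_gain = 2.0
        else:
            nry, nrx = nr, nr * rng.uniform(0.85, 1.0)
            nuc_gain = 1.0
        # keep the nucleus comfortably inside the cytoplasm ellipse
        cap = 0.7 * cr * aspect
        nry, nrx = min(nry, cap), min(nrx, cap)

        nuc_mask = _ellipse_mask((h, w), c["cy"], c["cx"], nry, nrx, theta)
        if c["is_apoptotic"] or c["is_mitotic"]:
            cell_mask = ndi.binary_dilation(nuc_mask, iterations=2)
        else:
            cell_mask = _ellipse_mask((h, w), c["cy"], c["cx"], cr, cr * aspect, theta)
        cell_mask &= cell_labels == 0
        nuc_mask &= cell_mask
        if not cell_mask.any() or not nuc_mask.any():
            continue
        cell_labels[cell_mask] = cid
        nucleus_labels[nuc_mask] = cid
        ch_nuc[nuc_mask] += config.nucleus_intensity * nuc_gain * rng.uniform(0.9, 1.1)

        # LAMP1 spots (healthy cells only)
        cell_spot_pixels = np.zeros((h, w), bool)
        n_spots = 0
        if not (c["is_apoptotic"] or c["is_mitotic"]):
            ch_lamp[cell_mask] += config.cytoplasm_intensity
            k = int(rng.poisson(config.spots_per_cell_mean))
            if f_base > 0:
                k = max(k, 1)
            interior = cell_mask & ~nuc_mask
            dist_in = ndi.distance_transform_edt(cell_mask)
            for _ in range(k):
                sr = rng.uniform(*config.spot_radius_range)
                cand = interior & (dist_in >= sr + 0.5) & (spot_labels == 0)
                coords = np.argwhere(cand)
                if coords.size == 0:
                    coords = np.argwhere(interior & (spot_labels == 0))
                    if coords.size == 0:
                        continue
                sy, sx = coords[rng.integers(len(coords))]
                smask = _ellipse_mask((h, w), sy, sx, sr, sr, 0.0)
                smask &= cell_mask & (spot_labels == 0)
                if not smask.any():
                    continue
                spot_id += 1
                spot_labels[smask] = spot_id
                spot_to_cell[spot_id] = cid
                cell_spot_pixels |= smask
                ch_lamp[smask] += config.spot_intensity * rng.uniform(0.8, 1.2)
                n_spots += 1
        else:
            ch_lamp[cell_mask] += config.cytoplasm_intensity * 0.5

        # NP channel: exact split between spot and diffuse components
        T = config.np_total_per_cell
        f_cell = f_base if cell_spot_pixels.any() else 0.0
        n_spot_px = int(cell_spot_pixels.sum())
        diffuse_mask = cell_mask & ~cell_spot_pixels
        n_diff_px = int(diffuse_mask.sum())
        if n_spot_px:
            ch_np[cell_spot_pixels] += f_cell * T / n_spot_px
        if n_diff_px:
            ch_np[diffuse_mask] += (1.0 - f_cell) * T / n_diff_px
        elif n_spot_px:  # pathological tiny cell: everything in spots
            ch_np[cell_spot_pixels] += (1.0 - f_cell) * T / n_spot_px
            f_cell = 1.0

        rows.append({
            "cell_id": cid, "cy": c["cy"], "cx": c["cx"],
            "nucleus_radius": nr, "cell_radius": cr,
            "is_apoptotic": c["is_apoptotic"], "is_mitotic": c["is_mitotic"],
            "is_border": bool(
                cell_mask[0, :].any() or cell_mask[-1, :].any()
                or cell_mask[:, 0].any() or cell_mask[:, -1].any()
            ),
            "n_spots": n_spots, "f_cell": f_cell, "np_total": T,
        })

    # mild blur for optical realism on the stained channels; the NP channel
    # is left un-blurred so the planted in-spot fraction stays exact
    ch_nuc = ndi.gaussian_filter(ch_nuc, 0.7)
    ch_lamp = ndi.gaussian_filter(ch_lamp, 0.5)

    # low-order polynomial background surface on the corrected channels
    yy, xx = np.mgrid[0:h, 0:w]
    u, v = yy / max(h - 1, 1), xx / max(w - 1, 1)
    coeffs = rng.normal(size=5)
    surf = (coeffs[0] * u + coeffs[1] * v + coeffs[2] * u * v
            + coeffs[3] * u ** 2 + coeffs[4] * v ** 2)
    rngd = surf.max() - surf.min()
    surf = (surf - surf.min()) / rngd if rngd > 0 else np.zeros_like(surf)
    background = config.background_gradient_amplitude * surf
    ch_lamp = ch_lamp + background
    ch_np = ch_np + background
    ch_nuc = ch_nuc + 0.3 * background

    channels = {}
    for name, arr in (("nuclei", ch_nuc), ("lamp1", ch_lamp), ("np", ch_np)):
        out = arr
        if config.noise_poisson:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if config.noise_gaussian_sd > 0:
            out = out + rng.normal(0, config.noise_gaussian_sd, out.shape)
        channels[name] = np.clip(out, 0, config.max_intensity)

    cells = pd.DataFrame(rows, columns=[
        "cell_id", "cy", "cx", "nucleus_radius", "cell_radius",
        "is_apoptotic", "is_mitotic", "is_border", "n_spots", "f_cell",
        "np_total",
    ])
    truth = GroundTruth(
        cells=cells,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        spot_labels=spot_labels,
        spot_to_cell=spot_to_cell,
        background=background,
        effect=effect,
    )
    image = FieldImage(channels=channels, pixel_size_um=config.pixel_size_um)
    return image, truth


def simulate_screen(
    layout: pd.DataFrame,
    effects: dict[str, float],
    config: SimulationConfig,
    fields_per_well: int = 2,
    seed: int = 0,
    well_jitter_cv: float = 0.05,
    replicate_cv: float = 0.03,
    keep_truth_masks: bool = True,
) -> tuple[list[FieldImage], ScreenTruth]:
    """Simulate every field of a plate layout.

    Effects are treatment-level trafficking multipliers; negative-control
    wells are forced to 1.0.  Replicate-to-replicate variability enters as a
    shared multiplicative offset per replicate (sd ``replicate_cv``) plus an
    independent per-well jitter (sd ``well_jitter_cv``); the realized per-well
    effect is recorded in the truth table.
    """
    validate_layout(layout)
    for tid in layout.loc[~layout["is_negative_control"], "treatment_id"].unique():
        if tid not in effects:
            raise KeyError(f"no planted effect for treatment {tid!r}")

    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    reps = sorted(layout["replicate_id"].unique())
    rep_offset = {r: 1.0 + master.normal(0, replicate_cv) for r in reps}

    fields: list[FieldImage] = []
    truths: list[GroundTruth] = []
    well_rows = []
    children = ss.spawn(len(layout) * fields_per_well)
    child_iter = iter(children)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])

    for _, row in layout.iterrows():
        nominal = 1.0 if row["is_negative_control"] else float(effects[row["treatment_id"]])
        realized = nominal * rep_offset[row["replicate_id"]] * (
            1.0 + jitter_rng.normal(0, well_jitter_cv)
        )
        realized = max(realized, 0.0)
        f_planted = []
        for fid in range(1, fields_per_well + 1):
            child = next(child_iter)
            fld_seed = int(child.generate_state(1)[0] % (2 ** 31))
            img, tr = simulate_field(config, effect=realized, seed=fld_seed)
            img.plate_id = str(row["plate_id"])
            img.well_id = str(row["well_id"])
            img.replicate_id = int(row["replicate_id"])
            img.field_id = fid
            fields.append(img)
            f_planted.append(tr.true_field_ratio())
            if keep_truth_masks:
                truths.append(tr)
        well_rows.append({
            "plate_id": row["plate_id"], "well_id": row["well_id"],
            "replicate_id": row["replicate_id"],
            "treatment_id": row["treatment_id"],
            "is_negative_control": row["is_negative_control"],
            "effect_nominal": nominal, "effect_realized": realized,
            "f_planted": float(np.nanmean(f_planted)),
        })
    truth = ScreenTruth(well_table=pd.DataFrame(well_rows), field_truths=truths)
    return fields, truth


def simulate_well_table(
    layout: pd.DataFrame,
    effects: dict[str, float],
    neg_cv: float = 0.05,
    cells_per_well_dist: tuple = ("poisson", 120),
    seed: int = 0,
    baseline_ratio: float = 0.5,
    lamp1_effects: dict[str, float] | None = None,
    lamp1_mean: float = 100.0,
    lamp1_cv: float = 0.05,
    with_lyso: bool = False,
) -> pd.DataFrame:
    """Imageless per-well records for screen-statistics testing at scale.

    Each well's LAMP1-associated NP ratio is drawn as
    ``clip(baseline_ratio * effect * (1 + N(0, neg_cv)), 0, 1)`` and its
    analyzed-cell count from ``cells_per_well_dist`` — one of
    ``("poisson", mean)``, ``("normal", mean, sd)`` or ``("constant", n)``.
    """
    validate_layout(layout)
    if neg_cv < 0:
        raise ValueError("neg_cv must be >= 0")
    for tid in layout.loc[~layout["is_negative_control"], "treatment_id"].unique():
        if tid not in effects:
            raise KeyError(f"no planted effect for treatment {tid!r}")

    rng = np.random.default_rng(seed)
    kind = cells_per_well_dist[0]
    rows = []
    for _, row in layout.iterrows():
        eff = 1.0 if row["is_negative_control"] else float(effects[row["treatment_id"]])
        ratio = baseline_ratio * eff * (1.0 + rng.normal(0, neg_cv)) if neg_cv > 0 \
            else baseline_ratio * eff
        ratio = float(np.clip(ratio, 0.0, 1.0))
        if kind == "poisson":
            n_cells = int(rng.poisson(cells_per_well_dist[1]))
        elif kind == "normal":
            n_cells = max(0, int(round(rng.normal(*cells_per_well_dist[1:3]))))
        elif kind == "constant":
            n_cells = int(cells_per_well_dist[1])
        else:
            raise ValueError(f"unknown cells_per_well_dist kind {kind!r}")
        l_eff = 1.0 if row["is_negative_control"] else \
            float((lamp1_effects or {}).get(row["treatment_id"], 1.0))
        rec = {
            "plate_id": row["plate_id"], "well_id": row["well_id"],
            "replicate_id": row["replicate_id"],
            "treatment_id": row["treatment_id"],
            "gene": row["gene"], "sirna_id": row["sirna_id"],
            "is_negative_control": row["is_negative_control"],
            "n_cells_analyzed": n_cells,
            "lamp1_np_ratio": ratio,
            "mean_lamp1_intensity_per_cell": float(
                lamp1_mean * l_eff * (1.0 + rng.normal(0, lamp1_cv))
            ),
        }
        if with_lyso:
            rec["mean_lyso_spot_count"] = float(rng.normal(60, 5))
            rec["mean_lyso_intensity"] = float(rng.normal(80, 5))
        rows.append(rec)
    return pd.DataFrame(rows)
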