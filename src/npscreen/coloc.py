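"""Rank Weighted Colocalization (RWC) of nanoparticle and marker signal.

RWC measures how much of the NP signal sits in pixels where the two
channels' intensity *ranks* agree.  Over the n pixels of one cell mask, each
channel's intensities are ranked descending (rank 1 = brightest, ties get
the average rank).  With D_i = |rank_np(i) - rank_marker(i)| and weight
W_i = (n - D_i) / n,

    RWC = sum_{i in C} I_np(i) * W_i  /  sum_{i in A} I_np(i)

where A is the set of pixels with NP intensity above the NP threshold and
C the subset also above the marker threshold.  RWC is a fraction of NP
signal, lies in [0, 1], equals 1 when the channels are identical and
everything is above threshold, and is 0 when no pixel is colocalized.
Because only ranks enter the weights, RWC is invariant under strictly
increasing transforms of either channel (with thresholds mapped along).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.filters import threshold_otsu

from .config import AnalysisParams

__all__ = [
    "ColocInput",
    "RwcResult",
    "auto_threshold",
    "rwc",
    "percent_colocalized_per_condition",
]


@dataclass
class ColocInput:
    """Intensities of one cell (any shape; flattened) plus the two cutoffs.

    Pixels count as "above threshold" when strictly greater than the cutoff,
    so a constant channel thresholded at its own value contributes nothing.
    """

    ch_np: np.ndarray
    ch_marker: np.ndarray
    threshold_np: float = 0.0
    threshold_marker: float = 0.0

    def __post_init__(self) -> None:
        self.ch_np = np.asarray(self.ch_np, float).ravel()
        self.ch_marker = np.asarray(self.ch_marker, float).ravel()
        if self.ch_np.shape != self.ch_marker.shape:
            raise ValueError("channel arrays must have the same size")
        if self.threshold_np < 0 or self.threshold_marker < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class RwcResult:
    rwc: float
    n_pixels_evaluated: int
    n_coloc_pixels: int

    @property
    def percent(self) -> float:
        return 100.0 * self.rwc


def auto_threshold(channel: np.ndarray, mask: np.ndarray | None = None,
                   method: str = "otsu", percentile: float = 75.0) -> float:
    """Intensity cutoff for one channel within a cell mask.

    Default is Otsu on the in-mask histogram; a fixed-percentile alternative
    is selectable.  A constant channel returns the constant itself, so no
    pixel lies strictly above it.
    """
    values = np.asarray(channel, float)
    if mask is not None:
        values = values[np.asarray(mask, bool)]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("empty mask: no pixels to threshold")
    if np.all(values == values[0]):
        return float(values[0])
    if method == "otsu":
        return float(threshold_otsu(values))
    if method == "percentile":
        return float(np.percentile(values, percentile))
    raise ValueError(f"unknown threshold method {method!r}")


def rwc(inp: ColocInput) -> RwcResult:
    """Rank Weighted Colocalization coefficient for one cell."""
    x, y = inp.ch_np, inp.ch_marker
    n = x.size
    above_np = x > inp.threshold_np
    if n == 0 or not above_np.any():
        return RwcResult(0.0, int(n), 0)
    coloc = above_np & (y > inp.threshold_marker)
    denom = float(x[above_np].sum())
    if denom <= 0 or not coloc.any():
        return RwcResult(0.0, int(n), int(coloc.sum()))
    rank_x = rankdata(-x, method="average")
    rank_y = rankdata(-y, method="average")
    weight = (n - np.abs(rank_x - rank_y)) / n
    value = float((x[coloc] * weight[coloc]).sum() / denom)
    return RwcResult(value, int(n), int(coloc.sum()))


def rwc_for_cell(ch_np: np.ndarray, ch_marker: np.ndarray, mask: np.ndarray,
                 params: AnalysisParams | None = None) -> RwcResult:
    """RWC of one cell from full-field channels and a boolean cell mask,
    with per-cell automatic thresholds."""
    params = params or AnalysisParams()
    mask = np.asarray(mask, bool)
    t_np = auto_threshold(ch_np, mask, params.coloc_threshold_method,
                          params.coloc_threshold_percentile)
    t_mk = auto_threshold(ch_marker, mask, params.coloc_threshold_method,
                          params.coloc_threshold_percentile)
    return rwc(ColocInput(np.asarray(ch_np, float)[mask],
                          np.asarray(ch_marker, float)[mask], t_np, t_mk))


def percent_colocalized_per_condition(
    cell_inputs: "pd.DataFrame | list[dict]",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell RWC percentages and per-condition mean ± s.e.m.

    ``cell_inputs`` rows need: condition, cell_id, ch_np, ch_marker, mask
    (or pre-masked arrays with mask=None) — typically built from analyzed
    fields.  Returns (per-cell table, condition summary); the summary s.e.m.
    is NaN for single-cell conditions.
    """
    if isinstance(cell_inputs, pd.DataFrame):
        cell_inputs = cell_inputs.to_dict("records")
    rows = []
    for rec in cell_inputs:
        mask = rec.get("mask")
        if mask is not None:
            res = rwc_for_cell(rec["ch_np"], rec["ch_marker"], mask,
                               rec.get("params"))
        else:
            t_np = rec.get("threshold_np")
            t_mk = rec.get("threshold_marker")
            if t_np is None:
                t_np = auto_threshold(rec["ch_np"])
            if t_mk is None:
                t_mk = auto_threshold(rec["ch_marker"])
            res = rwc(ColocInput(rec["ch_np"], rec["ch_marker"], t_np, t_mk))
        rows.append({
            "condition": rec["condition"], "cell_id": rec.get("cell_id", 0),
            "rwc": res.rwc, "percent": res.percent,
        })
    per_cell = pd.DataFrame(rows)
    if per_cell.empty:
        return per_cell, pd.DataFrame(
            columns=["condition", "mean_percent", "sem_percent", "n_cells"])
    summary = per_cell.groupby("condition")["percent"].agg(
        mean_percent="mean",
        sem_percent=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1
        else float("nan"),
        n_cells="size",
    ).reset_index()
    return per_cell, summary
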