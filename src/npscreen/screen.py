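"""Screen statistics: viability, NEG normalization, phenotype calling,
multi-siRNA validation and significance tests.

The fitted-model surface is :class:`ScreenModel` / :class:`ScreenResults`:
build the model from per-well records (image-derived or simulated) plus a
plate layout, call :meth:`ScreenModel.fit`, and read the per-treatment
estimates, phenotype classes, gene-level validation and control readouts
off the results object.  The individual steps are also exposed as plain
functions for composition and testing.

Phenotype classes are defined against the negative-control (NEG)
distribution of normalized ratios: with mean mu and standard deviation
sigma over NEG wells, a treatment's cross-replicate normalized mean r is

    strong_decrease  if r <= mu - 3 sigma
    mild_decrease    if mu - 3 sigma < r <= mu - 2 sigma
    mild_increase    if mu + 2 sigma <= r < mu + 3 sigma
    strong_increase  if r >= mu + 3 sigma
    none             otherwise

(ties go to the more extreme class).  A gene is validated when at least k
of its n independent siRNAs show a phenotype in the screened direction
(default 2 of 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsParams

__all__ = [
    "ControlStats",
    "ScreenModel",
    "ScreenResults",
    "viability_filter",
    "normalize_to_neg",
    "call_phenotype",
    "validate_gene",
    "one_tailed_ttest",
    "control_readouts",
    "PHENOTYPES",
]

PHENOTYPES = ("strong_decrease", "mild_decrease", "none",
              "mild_increase", "strong_increase", "not_viable")

DECREASE_CLASSES = {"strong_decrease", "mild_decrease"}
INCREASE_CLASSES = {"strong_increase", "mild_increase"}


@dataclass
class ControlStats:
    """Mean/sd of the normalized negative-control distribution."""

    neg_mean: float
    neg_sd: float
    n_neg_wells: int
    scope: str = "pooled"

    def __post_init__(self) -> None:
        if self.n_neg_wells >= 2 and self.neg_sd < 0:
            raise ValueError("neg_sd must be >= 0")


def viability_filter(wells: pd.DataFrame,
                     params: StatsParams | None = None) -> pd.Series:
    """Viability flag per treatment.

    A treatment is discarded if any of its wells analyzed fewer than
    ``min_cells_per_well`` cells, or the total across its replicates is
    below ``min_cells_total`` ("less than" is strict: 50 per well and a
    150 total pass).
    """
    params = params or StatsParams()
    grp = wells.groupby("treatment_id")["n_cells_analyzed"]
    ok_per_well = grp.min() >= params.min_cells_per_well
    ok_total = grp.sum() >= params.min_cells_total
    has_ratio = wells.groupby("treatment_id")["lamp1_np_ratio"] \
        .apply(lambda v: np.isfinite(v).any())
    return (ok_per_well & ok_total & has_ratio).rename("viable")


def normalize_to_neg(wells: pd.DataFrame,
                     params: StatsParams | None = None
                     ) -> tuple[pd.DataFrame, ControlStats]:
    """Divide well ratios by the mean NEG ratio of their scope.

    Scope defaults to per-plate-per-replicate; NEG wells therefore have
    normalized mean 1.0 by construction.  Control statistics (mu, sigma)
    are computed over the normalized NEG wells pooled across scopes.
    """
    params = params or StatsParams()
    wells = wells.copy()
    if params.norm_scope == "plate_replicate":
        keys = ["plate_id", "replicate_id"]
    elif params.norm_scope == "plate":
        keys = ["plate_id"]
    elif params.norm_scope == "screen":
        keys = []
    else:
        raise ValueError(f"unknown norm_scope {params.norm_scope!r}")

    finite_neg = wells[wells["is_negative_control"]
                       & np.isfinite(wells["lamp1_np_ratio"])]
    if keys:
        scale = finite_neg.groupby(keys)["lamp1_np_ratio"].mean()
        scopes = wells[keys].drop_duplicates()
        idx = pd.MultiIndex.from_frame(scopes) if len(keys) > 1 \
            else pd.Index(scopes[keys[0]])
        missing = idx.difference(scale.index)
        if len(missing):
            raise ValueError(
                f"no negative-control wells in scope {tuple(missing[0]) if len(keys) > 1 else missing[0]!r}")
        well_idx = pd.MultiIndex.from_frame(wells[keys]) if len(keys) > 1 \
            else pd.Index(wells[keys[0]])
        wells["normalized_ratio"] = wells["lamp1_np_ratio"].to_numpy() / \
            scale.reindex(well_idx).to_numpy()
    else:
        if finite_neg.empty:
            raise ValueError("no negative-control wells in scope 'screen'")
        wells["normalized_ratio"] = wells["lamp1_np_ratio"] / \
            float(finite_neg["lamp1_np_ratio"].mean())

    neg = wells.loc[wells["is_negative_control"], "normalized_ratio"]
    neg = neg[np.isfinite(neg)]
    sd = float(neg.std(ddof=1)) if len(neg) >= 2 else float("nan")
    controls = ControlStats(
        neg_mean=float(neg.mean()), neg_sd=sd, n_neg_wells=int(len(neg)),
        scope=params.norm_scope,
    )
    return wells, controls


def call_phenotype(normalized_ratio_mean: float,
                   controls: ControlStats,
                   params: StatsParams | None = None) -> str:
    """Classify one viable treatment against the NEG distribution."""
    params = params or StatsParams()
    mu, sd = controls.neg_mean, controls.neg_sd
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("degenerate control distribution: sigma is 0 or undefined")
    r = normalized_ratio_mean
    if r <= mu - params.strong_sd * sd:
        return "strong_decrease"
    if r <= mu - params.mild_sd * sd:
        return "mild_decrease"
    if r >= mu + params.strong_sd * sd:
        return "strong_increase"
    if r >= mu + params.mild_sd * sd:
        return "mild_increase"
    return "none"


def validate_gene(phenotypes: list[str], k: int = 2,
                  direction: str = "decrease") -> dict:
    """k-of-n validation of one gene from its per-siRNA phenotypes.

    A siRNA confirms when its phenotype is a (mild or strong) change in the
    screened direction; the gene is validated when at least ``k`` confirm.
    """
    confirming_set = DECREASE_CLASSES if direction == "decrease" \
        else INCREASE_CLASSES
    n_confirming = sum(p in confirming_set for p in phenotypes)
    return {
        "n_sirnas": len(phenotypes),
        "n_confirming": int(n_confirming),
        "validated": bool(n_confirming >= k),
        "rule": f"{k} of {len(phenotypes)}",
    }


def one_tailed_ttest(treatment_values, control_values,
                     direction: str = "decrease", welch: bool = False) -> float:
    """One-tailed two-sample t-test of treatment vs control.

    ``direction="decrease"`` tests H1: treatment < control.  Degenerate
    inputs (zero variance in both groups): p = 0.5 when the means are equal,
    0 or 1 otherwise according to the observed direction.
    """
    t_vals = np.asarray(treatment_values, float)
    c_vals = np.asarray(control_values, float)
    if t_vals.size < 2 or c_vals.size < 2:
        raise ValueError("need at least two values per group")
    alternative = "less" if direction == "decrease" else "greater"
    if t_vals.std() == 0 and c_vals.std() == 0:
        diff = t_vals.mean() - c_vals.mean()
        if diff == 0:
            return 0.5
        observed_less = diff < 0
        return 0.0 if observed_less == (alternative == "less") else 1.0
    res = sps.ttest_ind(t_vals, c_vals, equal_var=not welch,
                        alternative=alternative)
    return float(res.pvalue)


def control_readouts(wells: pd.DataFrame,
                     params: StatsParams | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-treatment organelle-control summaries with one-tailed tests vs NEG.

    Covers the screen's control measurements guarding against hits that are
    mere consequences of altered lysosome organization: mean LAMP1 intensity
    per cell and, when present, LysoTracker spot count and intensity.  Each
    readout is tested one-tailed (increase) against the NEG wells.
    """
    params = params or StatsParams()
    candidates = ["mean_lamp1_intensity_per_cell",
                  "mean_lyso_spot_count", "mean_lyso_intensity"]
    readouts = [c for c in candidates
                if c in wells.columns and wells[c].notna().any()]
    neg = wells[wells["is_negative_control"]]
    rows = []
    for tid, grp in wells[~wells["is_negative_control"]].groupby("treatment_id"):
        row: dict = {"treatment_id": tid}
        for col in readouts:
            vals = grp[col].dropna().to_numpy()
            ctrl = neg[col].dropna().to_numpy()
            row[f"{col}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{col}_sem"] = float(vals.std(ddof=1) / np.sqrt(vals.size)) \
                if vals.size > 1 else float("nan")
            if vals.size >= 2 and ctrl.size >= 2:
                p = one_tailed_ttest(vals, ctrl, direction="increase",
                                     welch=params.welch)
            else:
                p = float("nan")
            row[f"{col}_p"] = p
            row[f"{col}_flagged"] = bool(np.isfinite(p) and p < alpha)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results


class ScreenModel:
    """Screen-statistics model over per-well records.

    Parameters
    ----------
    wells:
        Per-well records with at least plate_id, well_id, replicate_id,
        treatment_id, is_negative_control, n_cells_analyzed, lamp1_np_ratio
        (gene / sirna_id columns enable gene-level validation; control
        readout columns are summarized when present).
    layout:
        Optional layout table merged in when ``wells`` lacks the treatment
        annotation columns.
    params:
        :class:`~npscreen.config.StatsParams`.
    """

    def __init__(self, wells: pd.DataFrame, layout: pd.DataFrame | None = None,
                 params: StatsParams | None = None):
        self.params = params or StatsParams()
        wells = wells.copy()
        if layout is not None:
            ann_cols = ["treatment_id", "gene", "sirna_id", "is_negative_control"]
            missing = [c for c in ann_cols if c not in wells.columns]
            if missing:
                wells = wells.merge(
                    layout[["plate_id", "well_id", "replicate_id"] + missing],
                    on=["plate_id", "well_id", "replicate_id"], how="left",
                    validate="many_to_one",
                )
                if wells["treatment_id"].isna().any():
                    bad = wells.loc[wells["treatment_id"].isna(), "well_id"].iloc[0]
                    raise ValueError(f"well {bad!r} not present in layout")
        required = ["treatment_id", "is_negative_control",
                    "n_cells_analyzed", "lamp1_np_ratio"]
        missing = [c for c in required if c not in wells.columns]
        if missing:
            raise ValueError(f"well table is missing columns: {missing}")
        self.wells = wells

    @classmethod
    def from_csv(cls, wells_csv, layout_csv=None,
                 params: StatsParams | None = None) -> "ScreenModel":
        wells = pd.read_csv(wells_csv)
        layout = pd.read_csv(layout_csv) if layout_csv is not None else None
        return cls(wells, layout, params)

    def fit(self) -> "ScreenResults":
        params = self.params
        normalized, controls = normalize_to_neg(self.wells, params)
        viable = viability_filter(normalized, params)

        neg_norm = normalized.loc[
            normalized["is_negative_control"], "normalized_ratio"]
        neg_norm = neg_norm[np.isfinite(neg_norm)].to_numpy()

        rows = []
        for tid, grp in normalized[~normalized["is_negative_control"]] \
                .groupby("treatment_id"):
            vals = grp["normalized_ratio"].to_numpy()
            vals = vals[np.isfinite(vals)]
            mean = float(vals.mean()) if vals.size else float("nan")
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) \
                if vals.size > 1 else float("nan")
            is_viable = bool(viable.get(tid, False))
            if is_viable:
                phenotype = call_phenotype(mean, controls, params)
            else:
                phenotype = "not_viable"
            if vals.size >= 2 and neg_norm.size >= 2:
                p = one_tailed_ttest(vals, neg_norm,
                                     direction=params.direction,
                                     welch=params.welch)
            else:
                p = float("nan")
            rows.append({
                "treatment_id": tid,
                "gene": grp["gene"].iloc[0] if "gene" in grp else tid,
                "sirna_id": grp["sirna_id"].iloc[0] if "sirna_id" in grp else tid,
                "normalized_ratio_mean": mean,
                "normalized_ratio_sem": sem,
                "n_replicates": int(vals.size),
                "total_cells": int(grp["n_cells_analyzed"].sum()),
                "viable": is_viable,
                "phenotype": phenotype,
                "p_value": p,
            })
        treatment_results = pd.DataFrame(rows).sort_values(
            "treatment_id").reset_index(drop=True)

        validation_rows = []
        if "gene" in treatment_results.columns and len(treatment_results):
            for gene, grp in treatment_results.groupby("gene"):
                v = validate_gene(grp["phenotype"].tolist(),
                                  k=params.validation_k,
                                  direction=params.direction)
                validation_rows.append({
                    "gene": gene,
                    "phenotypes": ";".join(grp["phenotype"]),
                    **v,
                })
        validation = pd.DataFrame(validation_rows)
        controls_table = control_readouts(normalized, params)
        return ScreenResults(self, normalized, controls, treatment_results,
                             validation, controls_table)


class ScreenResults:
    """Fit results: normalized wells, control stats and per-treatment calls."""

    def __init__(self, model, normalized_wells, control_stats,
                 treatment_results, validation, controls_table):
        self.model = model
        self.normalized_wells = normalized_wells
        self.control_stats: ControlStats = control_stats
        self.treatment_results: pd.DataFrame = treatment_results
        self.validation: pd.DataFrame = validation
        self.controls_table: pd.DataFrame = controls_table

    @property
    def hits(self) -> pd.DataFrame:
        """Viable treatments with a decrease phenotype, strongest first."""
        t = self.treatment_results
        hit = t[t["phenotype"].isin(DECREASE_CLASSES)]
        return hit.sort_values("normalized_ratio_mean").reset_index(drop=True)

    def summary(self) -> str:
        c = self.control_stats
        t = self.treatment_results
        counts = t["phenotype"].value_counts()
        lines = [
            "LAMP1-associated NP ratio screen",
            "=" * 48,
            f"wells: {len(self.normalized_wells)}   "
            f"treatments: {len(t)}   NEG wells: {c.n_neg_wells}",
            f"NEG normalized ratio: mean={c.neg_mean:.4f} sd={c.neg_sd:.4f} "
            f"(scope={c.scope})",
            f"viable treatments: {int(t['viable'].sum())} / {len(t)}",
            "phenotype counts: " + ", ".join(
                f"{k}={int(counts.get(k, 0))}" for k in PHENOTYPES
                if counts.get(k, 0)),
        ]
        if len(self.validation):
            lines.append(
                f"validated genes: {int(self.validation['validated'].sum())}"
                f" / {len(self.validation)}")
        if len(self.hits):
            lines.append("")
            lines.append("top decreases (normalized mean +/- sem):")
            for _, row in self.hits.head(10).iterrows():
                lines.append(
                    f"  {row['treatment_id']:<16s}"
                    f" {row['normalized_ratio_mean']:.3f}"
                    f" +/- {row['normalized_ratio_sem']:.3f}"
                    f"  {row['phenotype']}")
        return "\n".join(lines)

    def plot_ratios(self, path=None):
        """Bar chart of normalized ratios ± sem per treatment, NEG line at 1
        and the mild/strong decrease cutoffs marked. Returns the axes."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.treatment_results.sort_values("normalized_ratio_mean")
        c = self.control_stats
        fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(t)), 4))
        ax.bar(t["treatment_id"], t["normalized_ratio_mean"],
               yerr=t["normalized_ratio_sem"].fillna(0.0), color="0.6")
        ax.axhline(c.neg_mean, color="k", lw=1, label="NEG mean")
        if np.isfinite(c.neg_sd):
            p = self.model.params
            ax.axhline(c.neg_mean - p.mild_sd * c.neg_sd, color="orange",
                       ls="--", lw=1, label=f"-{p.mild_sd:g} sd")
            ax.axhline(c.neg_mean - p.strong_sd * c.neg_sd, color="red",
                       ls="--", lw=1, label=f"-{p.strong_sd:g} sd")
        ax.set_ylabel("normalized LAMP1-associated NP ratio")
        ax.tick_params(axis="x", rotation=90)
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return ax

    def to_csv(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.treatment_results.to_csv(outdir / "treatment_results.csv",
                                      index=False)
        if len(self.validation):
            self.validation.to_csv(outdir / "validation.csv", index=False)
        if len(self.controls_table):
            self.controls_table.to_csv(outdir / "controls.csv", index=False)
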