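"""Screen statistics: viability, normalization, phenotype calls, validation,
significance tests and the fitted-model surface."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from npscreen import (ControlStats, ScreenModel, StatsParams, call_phenotype,
                      control_readouts, make_layout, normalize_to_neg,
                      one_tailed_ttest, simulate_well_table, validate_gene,
                      viability_filter)


def _wells(counts_by_treatment, ratios=None, neg="NEG"):
    rows = []
    for tid, counts in counts_by_treatment.items():
        for rep, n in enumerate(counts, start=1):
            rows.append({
                "plate_id": "P1", "well_id": f"{tid}-w", "replicate_id": rep,
                "treatment_id": tid, "gene": tid, "sirna_id": tid,
                "is_negative_control": tid == neg,
                "n_cells_analyzed": n,
                "lamp1_np_ratio": (ratios or {}).get(tid, 0.5),
                "mean_lamp1_intensity_per_cell": 100.0,
            })
    return pd.DataFrame(rows)


@pytest.mark.parametrize("counts,expected", [
    ((49, 80, 80), False),   # one well below 50
    ((50, 50, 49), False),   # fails both sub-rules
    ((50, 50, 50), True),    # boundary: "less than" is strict
    ((120, 120, 120), True),
])
def test_viability_rule_boundaries(counts, expected):
    wells = _wells({"A": counts, "NEG": (200, 200, 200)})
    assert viability_filter(wells)["A"] == expected


def test_viability_thresholds_configurable():
    wells = _wells({"A": (30, 30, 30), "NEG": (200, 200, 200)})
    params = StatsParams(min_cells_per_well=20, min_cells_total=80)
    assert viability_filter(wells, params)["A"]


# ---------------------------------------------------------------------------
# normalization


def _screen_wells(neg_ratios, treatment_ratios):
    rows = []
    for rep in (1, 2, 3):
        for i, r in enumerate(neg_ratios.get(rep, [])):
            rows.append(dict(plate_id="P1", well_id=f"N{i}", replicate_id=rep,
                             treatment_id="NEG", gene="NEG", sirna_id="NEG",
                             is_negative_control=True, n_cells_analyzed=100,
                             lamp1_np_ratio=r,
                             mean_lamp1_intensity_per_cell=100.0))
        for tid, r in treatment_ratios.get(rep, {}).items():
            rows.append(dict(plate_id="P1", well_id=f"{tid}", replicate_id=rep,
                             treatment_id=tid, gene=tid, sirna_id=tid,
                             is_negative_control=False, n_cells_analyzed=100,
                             lamp1_np_ratio=r,
                             mean_lamp1_intensity_per_cell=100.0))
    return pd.DataFrame(rows)


def test_normalization_divides_by_scope_neg_mean():
    wells = _screen_wells({1: [0.8, 0.8, 0.8]}, {1: {"A": 0.4}})
    out, controls = normalize_to_neg(wells)
    a = out.loc[out["treatment_id"] == "A", "normalized_ratio"].iloc[0]
    assert a == pytest.approx(0.5)
    assert controls.neg_mean == pytest.approx(1.0)


def test_normalized_neg_mean_is_one_by_construction(rng):
    neg = {rep: list(rng.uniform(0.3, 0.9, 6)) for rep in (1, 2, 3)}
    wells = _screen_wells(neg, {rep: {"A": 0.5} for rep in (1, 2, 3)})
    out, controls = normalize_to_neg(wells)
    assert controls.neg_mean == pytest.approx(1.0)


def test_missing_neg_in_scope_raises():
    wells = _screen_wells({1: [0.8]}, {1: {"A": 0.4}, 2: {"A": 0.5}})
    with pytest.raises(ValueError, match="negative-control"):
        normalize_to_neg(wells)


def test_simulated_screen_effect_recovered():
    layout = make_layout(["geneA"], n_replicates=3, n_neg_wells=8)
    wells = simulate_well_table(layout, {"geneA": 0.5}, neg_cv=0.05, seed=4)
    out, _ = normalize_to_neg(wells)
    mean = out.loc[out["treatment_id"] == "geneA", "normalized_ratio"].mean()
    assert mean == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# phenotype classification


CTRL = ControlStats(neg_mean=1.0, neg_sd=0.1, n_neg_wells=24)


@pytest.mark.parametrize("ratio,expected", [
    (0.65, "strong_decrease"),
    (0.70, "strong_decrease"),   # tie goes to the extreme class
    (0.75, "mild_decrease"),
    (0.80, "mild_decrease"),
    (0.95, "none"),
    (1.20, "mild_increase"),
    (1.30, "strong_increase"),
    (1.35, "strong_increase"),
])
def test_phenotype_thresholds(ratio, expected):
    assert call_phenotype(ratio, CTRL) == expected


def test_degenerate_sigma_rejected():
    with pytest.raises(ValueError, match="sigma|degenerate"):
        call_phenotype(0.5, ControlStats(1.0, 0.0, 10))


def test_classification_scale_invariant(rng):
    ratios = rng.uniform(0.4, 1.6, 50)
    for c in (0.37, 2.0, 11.0):
        calls_base = [call_phenotype(r, CTRL) for r in ratios]
        scaled_ctrl = ControlStats(CTRL.neg_mean * c, CTRL.neg_sd * c, 24)
        calls_scaled = [call_phenotype(r * c, scaled_ctrl) for r in ratios]
        assert calls_base == calls_scaled


# ---------------------------------------------------------------------------
# validation


@pytest.mark.parametrize("phenos,expected_valid,expected_n", [
    (["strong_decrease", "mild_decrease", "none"], True, 2),
    (["strong_decrease", "none", "none"], False, 1),
    (["strong_decrease", "strong_decrease", "strong_decrease"], True, 3),
    (["mild_increase", "mild_increase", "none"], False, 0),
])
def test_two_of_three_validation(phenos, expected_valid, expected_n):
    out = validate_gene(phenos, k=2, direction="decrease")
    assert out["validated"] is expected_valid
    assert out["n_confirming"] == expected_n


def test_validation_monotone_in_confirming_sirnas():
    base = ["strong_decrease", "none", "none"]
    assert not validate_gene(base)["validated"]
    assert validate_gene(base + ["mild_decrease"])["validated"]
    # adding a confirming siRNA can never un-validate
    v1 = validate_gene(["strong_decrease", "mild_decrease"])
    v2 = validate_gene(["strong_decrease", "mild_decrease", "strong_decrease"])
    assert v1["validated"] and v2["validated"]


# ---------------------------------------------------------------------------
# t-tests


def test_identical_groups_give_half():
    assert one_tailed_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5


def test_wrong_direction_extreme_shift():
    p = one_tailed_ttest([101.0, 102.0, 103.0], [1.0, 2.0, 3.0],
                         direction="decrease")
    assert p > 0.999


def test_matches_t_distribution_cdf():
    a = np.array([0.42, 0.48, 0.51])
    b = np.array([0.61, 0.66, 0.58, 0.63])
    p = one_tailed_ttest(a, b, direction="decrease")
    # pooled-variance t statistic and one-tailed CDF, evaluated directly
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    assert p == pytest.approx(sps.t.cdf(t, na + nb - 2), rel=1e-12)


def test_too_few_values_rejected():
    with pytest.raises(ValueError):
        one_tailed_ttest([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# control readouts


def test_null_lamp1_readouts_rarely_flagged():
    genes = [f"G{i}" for i in range(60)]
    layout = make_layout(genes, n_replicates=3, n_neg_wells=8)
    wells = simulate_well_table(layout, {g: 1.0 for g in genes}, seed=3)
    out = control_readouts(wells)
    frac = out["mean_lamp1_intensity_per_cell_flagged"].mean()
    # binomial(60, 0.05): >= 8 flags has probability < 1e-2
    assert frac <= 7 / 60


def test_planted_lamp1_increase_flagged():
    genes = ["G0", "G1", "G2"]
    layout = make_layout(genes, n_replicates=3, n_neg_wells=8)
    wells = simulate_well_table(layout, {g: 1.0 for g in genes},
                                lamp1_effects={"G1": 2.0}, seed=5)
    out = control_readouts(wells).set_index("treatment_id")
    assert out.loc["G1", "mean_lamp1_intensity_per_cell_flagged"]


def test_absent_lyso_columns_are_omitted():
    layout = make_layout(["A"], n_replicates=3, n_neg_wells=4)
    wells = simulate_well_table(layout, {"A": 1.0}, seed=0, with_lyso=False)
    out = control_readouts(wells)
    assert not any("lyso" in c for c in out.columns)
    wells2 = simulate_well_table(layout, {"A": 1.0}, seed=0, with_lyso=True)
    out2 = control_readouts(wells2)
    assert any("lyso" in c for c in out2.columns)


# ---------------------------------------------------------------------------
# model surface


def test_model_fit_end_to_end_imageless():
    genes = {f"G{i}": f"GENE{i // 3}" for i in range(9)}  # 3 siRNAs per gene
    layout = make_layout(genes, n_replicates=3, n_neg_wells=8,
                         sirna_ids={g: f"si{g}" for g in genes})
    effects = {"G0": 0.5, "G1": 0.5, "G2": 1.0,   # GENE0: 2 strong -> valid
               "G3": 0.5, "G4": 1.0, "G5": 1.0,   # GENE1: 1 strong -> not
               "G6": 1.0, "G7": 1.0, "G8": 1.0}   # GENE2: null
    wells = simulate_well_table(layout, effects, neg_cv=0.05, seed=8)
    res = ScreenModel(wells, params=StatsParams()).fit()
    t = res.treatment_results.set_index("treatment_id")
    assert (t.loc[["G0", "G1", "G3"], "phenotype"] == "strong_decrease").all()
    assert t["viable"].all()
    v = res.validation.set_index("gene")
    assert bool(v.loc["GENE0", "validated"])
    assert not bool(v.loc["GENE1", "validated"])
    assert not bool(v.loc["GENE2", "validated"])
    s = res.summary()
    assert "strong_decrease" in s and "validated genes: 1 / 3" in s
    assert len(res.hits) == 3


def test_model_merges_layout_and_rejects_unknown_wells():
    layout = make_layout(["A"], n_replicates=2, n_neg_wells=2)
    wells = simulate_well_table(layout, {"A": 1.0}, seed=0)
    bare = wells[["plate_id", "well_id", "replicate_id", "n_cells_analyzed",
                  "lamp1_np_ratio", "mean_lamp1_intensity_per_cell"]]
    res = ScreenModel(bare, layout=layout).fit()
    assert len(res.treatment_results) == 1
    rogue = bare.copy()
    rogue.loc[rogue.index[0], "well_id"] = "Z99"
    with pytest.raises(ValueError, match="Z99"):
        ScreenModel(rogue, layout=layout)


def test_plot_ratios_writes_figure(tmp_path):
    layout = make_layout(["A", "B"], n_replicates=3, n_neg_wells=4)
    wells = simulate_well_table(layout, {"A": 0.5, "B": 1.0}, seed=1)
    res = ScreenModel(wells).fit()
    out = tmp_path / "ratios.png"
    res.plot_ratios(out)
    assert out.stat().st_size > 0
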