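"""Generator ground truth: determinism, exact planted fractions, geometry."""

import numpy as np
import pandas as pd
import pytest

from npscreen import (DegenerateGeometryError, SimulationConfig, make_layout,
                      simulate_field, simulate_screen, simulate_well_table,
                      validate_layout)


def test_same_seed_bit_identical(small_clean_config):
    a, _ = simulate_field(small_clean_config, 1.0, seed=5)
    b, _ = simulate_field(small_clean_config, 1.0, seed=5)
    for name in a.channels:
        assert np.array_equal(a[name], b[name])
    c, _ = simulate_field(small_clean_config, 1.0, seed=6)
    assert any(not np.array_equal(a[n], c[n]) for n in a.channels)


def test_cell_count_and_flags_forced_by_config(clean_config):
    cfg = SimulationConfig(**{**clean_config.__dict__, "n_cells_per_field": 30,
                              "field_shape": (384, 384)})
    _, truth = simulate_field(cfg, 1.0, seed=1)
    t = truth.cells
    assert len(t) == 30
    assert not t["is_border"].any()
    assert not t["is_apoptotic"].any()
    assert not t["is_mitotic"].any()


def test_planted_in_spot_fraction_exact(clean_config):
    cfg = SimulationConfig(**{**clean_config.__dict__,
                              "base_in_spot_fraction": 0.6})
    img, truth = simulate_field(cfg, effect=1.0, seed=42)
    spots = truth.spot_labels > 0
    cells = truth.cell_labels > 0
    ratio = img["np"][spots].sum() / img["np"][cells].sum()
    assert ratio == pytest.approx(0.600, abs=1e-9)


def test_np_mass_conserved_per_cell(clean_config):
    img, truth = simulate_field(clean_config, effect=0.7, seed=3)
    for _, row in truth.cells.iterrows():
        mask = truth.cell_labels == row["cell_id"]
        assert img["np"][mask].sum() == pytest.approx(row["np_total"], rel=1e-9)


@pytest.mark.parametrize("effects", [(0.2, 0.8), (0.5, 1.0), (1.0, 1.9)])
def test_effect_monotone_in_planted_fraction(clean_config, effects):
    lo, hi = effects
    _, t_lo = simulate_field(clean_config, effect=lo, seed=9)
    _, t_hi = simulate_field(clean_config, effect=hi, seed=9)
    assert t_lo.true_field_ratio() < t_hi.true_field_ratio()


def test_effect_clamped_at_one(clean_config):
    _, truth = simulate_field(clean_config, effect=5.0, seed=2)
    healthy = truth.cells
    assert (healthy["f_cell"] <= 1.0).all()
    assert truth.true_field_ratio() == pytest.approx(1.0)


def test_mask_containment_and_label_consistency(clean_config):
    cfg = SimulationConfig(**{**clean_config.__dict__,
                              "apoptotic_fraction": 0.1,
                              "border_cell_fraction": 0.1})
    _, truth = simulate_field(cfg, 1.0, seed=11)
    nuc, cell, spot = truth.nucleus_labels, truth.cell_labels, truth.spot_labels
    assert np.all(cell[nuc > 0] == nuc[nuc > 0])
    for sid, cid in truth.spot_to_cell.items():
        assert np.all(cell[spot == sid] == cid)
    assert set(np.unique(cell)) - {0} == set(truth.cells["cell_id"])


def test_negative_effect_rejected(small_clean_config):
    with pytest.raises(ValueError, match="effect"):
        simulate_field(small_clean_config, effect=-0.1, seed=0)


def test_degenerate_geometry_raises():
    cfg = SimulationConfig(field_shape=(32, 32), n_cells_per_field=50)
    with pytest.raises(DegenerateGeometryError):
        simulate_field(cfg, 1.0, seed=0)


def test_invalid_config_fractions():
    with pytest.raises(ValueError):
        SimulationConfig(apoptotic_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(base_in_spot_fraction=-0.1)


# ---------------------------------------------------------------------------
# screen-level simulation


def test_screen_emits_one_image_set_per_well_field(small_clean_config):
    layout = make_layout(["A", "B", "C"], n_replicates=3, n_neg_wells=1)
    assert len(layout) == 12  # 4 wells x 3 replicates
    fields, truth = simulate_screen(layout, {"A": 1.0, "B": 0.5, "C": 1.0},
                                    small_clean_config, fields_per_well=2,
                                    seed=0)
    assert len(fields) == 24
    assert len(truth.well_table) == 12


def test_screen_missing_effect_names_treatment(small_clean_config):
    layout = make_layout(["A", "B"], n_replicates=1, n_neg_wells=1)
    with pytest.raises(KeyError, match="B"):
        simulate_screen(layout, {"A": 1.0}, small_clean_config, seed=0)


def test_screen_planted_effect_ratio_recovered_from_truth(small_clean_config):
    layout = make_layout(["geneA"], n_replicates=3, n_neg_wells=2)
    fields, truth = simulate_screen(
        layout, {"geneA": 0.5}, small_clean_config, fields_per_well=1,
        seed=7, well_jitter_cv=0.0, replicate_cv=0.0)
    t = truth.well_table
    r_a = t.loc[t["treatment_id"] == "geneA", "f_planted"].mean()
    r_neg = t.loc[t["is_negative_control"], "f_planted"].mean()
    assert r_a / r_neg == pytest.approx(0.5, abs=1e-9)


def test_screen_negative_controls_forced_to_unit_effect(small_clean_config):
    layout = make_layout(["A"], n_replicates=2, n_neg_wells=2)
    _, truth = simulate_screen(layout, {"A": 0.3, "NEG": 99.0},
                               small_clean_config, fields_per_well=1, seed=1,
                               well_jitter_cv=0.0, replicate_cv=0.0)
    neg = truth.well_table[truth.well_table["is_negative_control"]]
    assert (neg["effect_realized"] == 1.0).all()


# ---------------------------------------------------------------------------
# imageless well table


def test_well_table_row_count_at_screen_scale():
    genes = [f"G{i:03d}" for i in range(348)]
    layout = make_layout(genes, n_replicates=3, n_neg_wells=16)
    wells = simulate_well_table(layout, {g: 1.0 for g in genes}, seed=0)
    assert len(wells[~wells["is_negative_control"]]) == 1044


def test_well_table_zero_noise_is_exact_baseline():
    layout = make_layout(["A"], n_replicates=3, n_neg_wells=4)
    wells = simulate_well_table(layout, {"A": 0.5}, neg_cv=0.0,
                                baseline_ratio=0.4, seed=0)
    neg = wells[wells["is_negative_control"]]
    assert (neg["lamp1_np_ratio"] == 0.4).all()
    assert (wells.loc[wells["treatment_id"] == "A", "lamp1_np_ratio"] == 0.2).all()


def test_well_table_deterministic():
    layout = make_layout(["A", "B"], n_replicates=3, n_neg_wells=2)
    kw = dict(effects={"A": 0.5, "B": 1.2}, neg_cv=0.1, seed=99)
    pd.testing.assert_frame_equal(simulate_well_table(layout, **kw),
                                  simulate_well_table(layout, **kw))


def test_layout_validation():
    layout = make_layout(["A"], n_replicates=2, n_neg_wells=1)
    validate_layout(layout)
    dup = pd.concat([layout, layout.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        validate_layout(dup)
    no_neg = layout[~layout["is_negative_control"]]
    with pytest.raises(ValueError, match="negative-control"):
        validate_layout(no_neg)
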