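"""Hold-out and leave-one-out experiment orchestration."""

import numpy as np
import pytest

from pdcrec import (
    ExperimentConfig,
    ResponseMatrix,
    get_scheme,
    make_rx_like,
    run_holdout,
    run_leave_one_out,
    simulate_preset,
    split_dataset,
)
from pdcrec.protocols import summarise_loo


def small_config(**kw):
    defaults = dict(
        n_repeats=1,
        n_historical_cells=25,
        panel_size=10,
        panel_method="random",
        imputation="zero",
        top_ns=(10,),
        hit_ks=(10,),
        seed_base=0,
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


# -- splitting ---------------------------------------------------------------

def test_split_sizes_largest_remainder():
    ids10 = [f"c{i}" for i in range(10)]
    train, val, test = split_dataset(ids10, (0.8, 0.1, 0.1), seed=0)
    assert (len(train), len(val), len(test)) == (8, 1, 1)
    ids809 = [f"c{i}" for i in range(809)]
    train, val, test = split_dataset(ids809, (0.8, 0.1, 0.1), seed=0)
    assert (len(train), len(val), len(test)) == (647, 81, 81)


def test_split_is_disjoint_exhaustive_and_reproducible():
    ids = [f"c{i}" for i in range(57)]
    a = split_dataset(ids, seed=3)
    b = split_dataset(ids, seed=3)
    assert a == b
    flat = [c for part in a for c in part]
    assert sorted(flat) == sorted(ids)
    assert len(set(flat)) == len(ids)
    c = split_dataset(ids, seed=4)
    assert c != a


def test_split_empty_part_raises():
    with pytest.raises(ValueError, match="empty split"):
        split_dataset([f"c{i}" for i in range(5)], (0.8, 0.1, 0.1), seed=0)


# -- hold-out ----------------------------------------------------------------

@pytest.fixture(scope="module")
def small_screen():
    matrix, truth = simulate_preset(
        "gdsc1_like", seed=7, n_cells=60, n_drugs=50, missing_fraction=0.05
    )
    return matrix, truth


def test_holdout_deterministic_and_zero_std(small_screen):
    matrix, _ = small_screen
    cfg = small_config()
    rep1 = run_holdout(matrix, cfg)
    rep2 = run_holdout(matrix, cfg)
    assert rep1.repeats[0].predictions == rep2.repeats[0].predictions
    assert rep1.aggregate == rep2.aggregate
    for metric in rep1.aggregate["all_drugs"].values():
        assert metric["std"] == 0.0


def test_holdout_high_signal_recovers_ranking():
    matrix, _ = simulate_preset(
        "gdsc1_like",
        seed=9,
        n_cells=150,
        n_drugs=100,
        noise_sd=0.0,
        missing_fraction=0.0,
    )
    cfg = small_config(panel_size=30, n_historical_cells=60)
    report = run_holdout(matrix, cfg)
    assert report.aggregate["all_drugs"]["r_spearman"]["mean"] >= 0.9


def test_holdout_never_reads_heldout_or_nonpanel_measurements(small_screen):
    """Poisoning validation cells and the test cells' non-panel entries
    changes no prediction bit."""
    matrix, _ = small_screen
    cfg = small_config()
    base = run_holdout(matrix, cfg)
    repeat = base.repeats[0]
    panel_cols = {matrix.drug_index(d) for d in repeat.panel.panel_drugs}

    poisoned = matrix.copy()
    for cell in repeat.validation_cells:
        i = poisoned.cell_index(cell)
        row = ~poisoned.missing_mask[i]
        poisoned.values[i, row] += 1e6
    for cell in repeat.test_cells:
        i = poisoned.cell_index(cell)
        for j in range(poisoned.n_drugs):
            if j not in panel_cols and not poisoned.missing_mask[i, j]:
                poisoned.values[i, j] += 1e6

    again = run_holdout(poisoned, cfg)
    assert again.repeats[0].panel.panel_drugs == repeat.panel.panel_drugs
    assert again.repeats[0].predictions == repeat.predictions


def test_holdout_summary_tracks_per_cell_values(small_screen):
    matrix, _ = small_screen
    report = run_holdout(matrix, small_config())
    repeat = report.repeats[0]
    per_cell = [
        ev["all_drugs"].r_spearman
        for ev in repeat.evaluations.values()
        if ev["all_drugs"] is not None
    ]
    assert repeat.summary["all_drugs"]["r_spearman"] == pytest.approx(
        np.nanmean(per_cell)
    )


# -- leave-one-out -----------------------------------------------------------

def library_mean_predictor(historical, panel, new_profile, seed, scheme, cell):
    """Cheap stand-in predictor: each drug predicted by its cohort mean."""
    panel_set = set(panel.panel_drugs)
    means = historical.values.mean(axis=0)
    return {
        d: float(means[j])
        for j, d in enumerate(historical.drug_ids)
        if d not in panel_set
    }


def test_loo_report_covers_every_cell():
    matrix, _ = make_rx_like(seed=3)
    cfg = small_config(imputation="zero", n_repeats=1)
    report = run_leave_one_out(matrix, cfg, predictor=library_mean_predictor)
    rows = report.repeats[0]
    assert len(rows) == 24
    assert sorted(r.cell_id for r in rows) == sorted(matrix.cell_ids)
    for row in rows:
        assert row.n_hits_identified <= min(row.n_hits_available, row.n_hits_predicted)
        assert set(row.predicted) == {
            d for d in matrix.drug_ids if not np.isnan(
                matrix.values[matrix.cell_index(row.cell_id),
                              matrix.drug_index(d)]
            )
        }


def test_loo_perfect_oracle_reaches_theoretical_top5():
    matrix, _ = make_rx_like(seed=5)

    def oracle(historical, panel, new_profile, seed, scheme, cell):
        i = matrix.cell_index(cell)
        panel_set = set(panel.panel_drugs)
        return {
            d: float(matrix.values[i, j]) if not matrix.missing_mask[i, j] else 100.0
            for j, d in enumerate(matrix.drug_ids)
            if d not in panel_set
        }

    cfg = small_config(imputation="zero", n_repeats=1)
    report = run_leave_one_out(matrix, cfg, predictor=oracle)
    for row in report.repeats[0]:
        i = matrix.cell_index(row.cell_id)
        measured = np.sort(matrix.values[i][~matrix.missing_mask[i]])
        assert row.top5_mean_activity == pytest.approx(measured[:5].mean())
        assert row.n_hits_identified == row.n_hits_available


def test_loo_skips_cells_with_too_few_drugs():
    scheme = get_scheme("viability_percent")
    values = np.full((4, 6), 80.0)
    missing = np.zeros((4, 6), bool)
    missing[0, 2:] = True  # c0 has only 2 measured drugs
    matrix = ResponseMatrix(
        [f"c{i}" for i in range(4)], [f"d{j}" for j in range(6)],
        values, missing, scheme,
    )
    cfg = small_config(imputation="zero", n_repeats=1)
    report = run_leave_one_out(matrix, cfg, predictor=library_mean_predictor)
    assert len(report.repeats[0]) == 3
    assert "c0" not in {r.cell_id for r in report.repeats[0]}


def test_loo_summary_hit_statistics():
    matrix, _ = make_rx_like(seed=6)
    cfg = small_config(imputation="zero", n_repeats=1)
    report = run_leave_one_out(matrix, cfg, predictor=library_mean_predictor)
    rows = report.repeats[0]
    summary = summarise_loo(rows)
    assert summary["n_cells"] == len(rows)
    evaluable = [r for r in rows if r.n_hits_available > 0]
    assert summary["n_hit_evaluable_cells"] == len(evaluable)
    recalls = [r.n_hits_identified / r.n_hits_available for r in evaluable]
    assert summary["hit_recall"] == pytest.approx(np.mean(recalls))
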