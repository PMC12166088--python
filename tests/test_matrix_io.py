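"""Matrix loading, pruning, target transforms, hit calls."""

import numpy as np
import pytest

from pdcrec import (
    MatrixFormatError,
    EmptyMatrixError,
    PruneParams,
    call_hits,
    drug_hit_prevalence,
    get_scheme,
    inverse_transform_targets,
    load_response_matrix,
    prune_matrix,
    rank_drug_ids,
    save_response_matrix,
    selective_drug_mask,
    transform_targets,
)

from conftest import make_matrix


# -- I/O ---------------------------------------------------------------------

def test_load_counts_missing_entries(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("id,d1,d2\nc1,0.5,\nc2,1.0,2.0\nc3,3.0,4.0\n")
    m = load_response_matrix(path, "gdsc_pIC50")
    assert m.shape == (3, 2)
    assert m.missing_mask.sum() == 1
    assert m.missing_mask[0, 1]
    assert m.values[1, 0] == 1.0


@pytest.mark.parametrize("sentinel", ["NA", "nan", "NULL", "NaN", ""])
def test_missing_sentinels(tmp_path, sentinel):
    path = tmp_path / "m.csv"
    path.write_text(f"id,d1\nc1,{sentinel}\nc2,2\n")
    m = load_response_matrix(path, "gdsc_pIC50")
    assert m.missing_mask[0, 0] and not m.missing_mask[1, 0]


def test_transposed_load_matches_untransposed(tmp_path):
    a = tmp_path / "a.csv"
    a.write_text("id,d1,d2\nc1,1,2\nc2,3,\n")
    b = tmp_path / "b.csv"
    b.write_text("id,c1,c2\nd1,1,3\nd2,2,\n")
    ma = load_response_matrix(a, "gdsc_pIC50")
    mb = load_response_matrix(b, "gdsc_pIC50", orientation="drugs_by_rows")
    assert ma.cell_ids == mb.cell_ids and ma.drug_ids == mb.drug_ids
    np.testing.assert_array_equal(ma.missing_mask, mb.missing_mask)
    np.testing.assert_array_equal(
        ma.values[~ma.missing_mask], mb.values[~mb.missing_mask]
    )


def test_duplicate_identifiers_rejected(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("id,d1,d2\nc1,1,2\nc1,3,4\n")
    with pytest.raises(MatrixFormatError, match="duplicate"):
        load_response_matrix(path, "gdsc_pIC50")


def test_non_numeric_cell_rejected_with_location(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("id,d1,d2\nc1,1,2\nc2,oops,4\n")
    with pytest.raises(MatrixFormatError, match=r"'c2'.*'d1'"):
        load_response_matrix(path, "gdsc_pIC50")


def test_save_load_roundtrip_with_sidecar(tmp_path):
    m = make_matrix([[1.0, np.nan], [3.0, 4.0]], scheme="viability_percent")
    path = tmp_path / "m.csv"
    save_response_matrix(m, path)
    again = load_response_matrix(path)  # scheme from sidecar
    assert again.scheme.name == "viability_percent"
    np.testing.assert_array_equal(m.missing_mask, again.missing_mask)
    np.testing.assert_array_equal(
        m.values[~m.missing_mask], again.values[~again.missing_mask]
    )


# -- pruning -----------------------------------------------------------------

def test_prune_cells_first_then_drugs(mk):
    # 5 cells × 5 drugs; c0 misses 2/5 drugs (40% > 20%) and is removed
    # first; c1 at exactly 20% stays. Afterwards d0 is missing in 1 of the
    # 4 remaining cells (25% > 20%) and is removed, while d1's only gap was
    # on the already-removed cell, so it survives.
    values = [
        [np.nan, np.nan, 1.0, 1.0, 1.0],
        [np.nan, 1.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, 1.0, 1.0, 1.0],
    ]
    pruned = prune_matrix(mk(values), PruneParams(0.2, 0.2))
    assert pruned.cell_ids == ["c1", "c2", "c3", "c4"]
    assert pruned.drug_ids == ["d1", "d2", "d3", "d4"]
    assert not pruned.missing_mask.any()


def test_prune_complete_matrix_is_identity(mk):
    m = mk(np.ones((4, 3)))
    pruned = prune_matrix(m, PruneParams(0.0, 0.0))
    assert pruned.cell_ids == m.cell_ids and pruned.drug_ids == m.drug_ids
    np.testing.assert_array_equal(pruned.values, m.values)


def test_prune_absolute_mode(mk):
    # cell missing 6 > 5 entries removed; drugs missing in >5 of the rest kept/dropped
    values = np.ones((8, 7))
    values[0, :6] = np.nan        # cell c0: 6 missing -> dropped
    values[1:8, 6] = np.nan       # drug d6: missing in 7 remaining cells -> dropped
    pruned = prune_matrix(mk(values), PruneParams(5, 5, "absolute"))
    assert "c0" not in pruned.cell_ids
    assert "d6" not in pruned.drug_ids
    assert pruned.shape == (7, 6)


def test_prune_idempotent(rmk):
    rng = np.random.default_rng(0)
    for _ in range(20):
        m = rmk(rng, 8, 6, missing_fraction=0.25)
        params = PruneParams(0.3, 0.3)
        try:
            once = prune_matrix(m, params)
        except EmptyMatrixError:
            continue
        twice = prune_matrix(once, params)
        assert once.cell_ids == twice.cell_ids
        assert once.drug_ids == twice.drug_ids


def test_prune_emptying_raises(mk):
    m = mk([[np.nan, 1.0], [np.nan, np.nan]])
    with pytest.raises(EmptyMatrixError):
        prune_matrix(m, PruneParams(0.0, 0.0))


def test_prune_does_not_mutate_input(mk):
    values = np.ones((4, 3))
    values[0, 0] = np.nan
    m = mk(values)
    before = m.values.copy()
    prune_matrix(m, PruneParams(0.0, 0.0))
    np.testing.assert_array_equal(
        m.values[~m.missing_mask], before[~m.missing_mask]
    )


# -- transforms --------------------------------------------------------------

@pytest.mark.parametrize(
    "scheme,raw,expected",
    [
        ("gdsc_pIC50", 1e-6, 6.0),       # 1 µM sits exactly on the hit boundary
        ("gdsc_pIC50", 1.0, 0.0),
        ("prism_neglog2fc", 0.25, 2.0),  # 4-fold depletion, active (2.0 > 1.7)
        ("viability_percent", 55.0, 55.0),
    ],
)
def test_transform_values(mk, scheme, raw, expected):
    m = transform_targets(mk([[raw]], scheme=scheme))
    assert m.values[0, 0] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("scheme,bad", [("gdsc_pIC50", -1.0), ("gdsc_pIC50", 0.0),
                                        ("prism_neglog2fc", 0.0),
                                        ("viability_percent", -5.0)])
def test_transform_rejects_invalid_values(mk, scheme, bad):
    m = mk([[1.0, bad]], scheme=scheme, drugs=["ok", "bad"])
    with pytest.raises(MatrixFormatError, match="'bad'"):
        transform_targets(m)


@pytest.mark.parametrize("scheme", ["gdsc_pIC50", "prism_neglog2fc", "viability_percent"])
def test_transform_inverse_roundtrip(rmk, scheme):
    rng = np.random.default_rng(1)
    raw = rng.uniform(0.1, 10.0, size=(6, 5))
    raw[rng.random((6, 5)) < 0.2] = np.nan
    m = make_matrix(raw, scheme=scheme)
    back = inverse_transform_targets(transform_targets(m))
    np.testing.assert_allclose(
        back.values[~m.missing_mask], raw[~np.isnan(raw)], rtol=1e-12
    )
    np.testing.assert_array_equal(back.missing_mask, m.missing_mask)


# -- hit calls ---------------------------------------------------------------

@pytest.mark.parametrize(
    "scheme,value,is_hit",
    [
        ("viability_percent", 30.0, True),    # ≤ 30 rule is inclusive
        ("viability_percent", 30.01, False),
        ("gdsc_pIC50", 6.0, False),           # "above 6" is strict
        ("gdsc_pIC50", 6.0001, True),
        ("prism_neglog2fc", 1.7, False),
        ("prism_neglog2fc", 1.71, True),
    ],
)
def test_hit_boundaries(mk, scheme, value, is_hit):
    hits = call_hits(mk([[value]], scheme=scheme))
    assert bool(hits[0, 0] == 1.0) is is_hit


def test_all_missing_column_non_evaluable(mk):
    m = mk([[np.nan, 7.0], [np.nan, 5.0]])
    hits = call_hits(m)
    prevalence = drug_hit_prevalence(hits)
    assert np.isnan(prevalence[0])
    assert prevalence[1] == 0.5
    assert not selective_drug_mask(hits)[0]  # cannot be assessed


def test_hit_counts_invariant_under_permutation(rmk):
    rng = np.random.default_rng(2)
    m = rmk(rng, 7, 6, missing_fraction=0.2)
    base = np.nansum(call_hits(m))
    perm = m.subset(
        cells=list(rng.permutation(m.cell_ids)),
        drugs=list(rng.permutation(m.drug_ids)),
    )
    assert np.nansum(call_hits(perm)) == base


# -- selective drugs ---------------------------------------------------------

def test_selective_is_strictly_below_limit(mk):
    # d0 active in 3/20 cells (15%) -> selective; d1 in 4/20 (20%) -> not
    values = np.full((20, 2), 5.0)
    values[:3, 0] = 7.0
    values[:4, 1] = 7.0
    mask = selective_drug_mask(call_hits(mk(values)))
    assert mask[0] and not mask[1]


def test_zero_hit_drug_is_selective(mk):
    mask = selective_drug_mask(call_hits(mk(np.full((5, 1), 2.0))))
    assert mask[0]


def test_selective_prevalence_matches_bruteforce(rmk):
    rng = np.random.default_rng(3)
    for _ in range(10):
        m = rmk(rng, 10, 8, missing_fraction=0.3)
        m.values[~m.missing_mask] = rng.uniform(4, 8, size=int((~m.missing_mask).sum()))
        hits = call_hits(m)
        mask = selective_drug_mask(hits, 0.4)
        for j in range(m.n_drugs):
            observed = [
                m.values[i, j] for i in range(m.n_cells) if not m.missing_mask[i, j]
            ]
            n_hits = sum(v > 6.0 for v in observed)
            expected = bool(observed) and n_hits / len(observed) < 0.4
            assert mask[j] == expected


def test_rank_drug_ids_directions():
    values = {"a": 1.0, "b": 3.0, "c": 2.0}
    assert rank_drug_ids(values, get_scheme("gdsc_pIC50")) == ["b", "c", "a"]
    assert rank_drug_ids(values, get_scheme("viability_percent")) == ["a", "c", "b"]
    ties = {"x": 1.0, "y": 1.0}
    assert rank_drug_ids(ties, get_scheme("gdsc_pIC50")) == ["x", "y"]
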