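"""Pearson correlation, significance marking and table construction."""

import numpy as np
import pytest

from mrnalang import (
    build_tables,
    compute_parameter_table,
    pearson_with_p,
    stars,
)
from mrnalang.association import (
    GROUP_ROWS,
    NOT_COMPUTABLE,
    TABLE_KEYS,
    associate,
    benjamini_hochberg,
)
from mrnalang.errors import DegenerateInputError, EmptyDatasetError, ShapeError
from mrnalang.sequence_io import (
    KineticClass,
    MrnaRecord,
    PARAMETER_COLUMNS,
    StructuralClass,
    StudyDataset,
)

from oracles import brute_pearson, permutation_p


@pytest.mark.parametrize(
    "x, y, r",
    [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3, 4), (4, 3, 2, 1), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
    ],
)
def test_pearson_exact_cases(x, y, r):
    rhat, p = pearson_with_p(x, y)
    assert rhat == pytest.approx(r, abs=1e-12)
    assert 0.0 <= p <= 1.0


def test_pearson_matches_brute_force_formula(rng):
    for _ in range(20):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rhat, _ = pearson_with_p(x, y)
        assert rhat == pytest.approx(brute_pearson(list(x), list(y)), abs=1e-12)


def test_pearson_p_close_to_exhaustive_permutation_null(rng):
    """The t-based p tracks the exact permutation p for small samples."""
    diffs = []
    for _ in range(6):
        x = list(rng.normal(size=7))
        y = list(rng.normal(size=7))
        _, p_t = pearson_with_p(x, y)
        p_perm = permutation_p(x, y)
        diffs.append(abs(p_t - p_perm))
    assert max(diffs) < 0.06


def test_pearson_invalid_inputs():
    with pytest.raises(DegenerateInputError):
        pearson_with_p((1.0, 1.0, 1.0), (1.0, 2.0, 3.0))
    with pytest.raises(DegenerateInputError):
        pearson_with_p((1.0, 2.0), (1.0, 2.0))
    with pytest.raises(ShapeError):
        pearson_with_p((1.0, 2.0, 3.0), (1.0, 2.0))


def test_pearson_affine_invariance(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r0, p0 = pearson_with_p(x, y)
    r1, p1 = pearson_with_p(5.0 * x - 3.0, y)
    r2, p2 = pearson_with_p(x, 0.1 * y + 100.0)
    assert r1 == pytest.approx(r0, abs=1e-12)
    assert r2 == pytest.approx(r0, abs=1e-12)
    assert p1 == pytest.approx(p0, rel=1e-9)
    assert p2 == pytest.approx(p0, rel=1e-9)


@pytest.mark.parametrize(
    "p, expected",
    [
        (0.0005, "***"),
        (0.005, "**"),
        (0.03, "*"),
        (0.05, ""),
        (0.5, ""),
        (0.001, "**"),  # boundaries are strict
        (0.01, "*"),
    ],
)
def test_star_thresholds(p, expected):
    assert stars(p) == expected


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    # adjusted values keep the significance ordering
    assert list(np.argsort(adj)) == list(np.argsort(p))


def _dataset_with_target(n, rng, target="D12", beta=2.0, noise_sd=0.0):
    """Random framed sequences, ln_kf built directly from the target parameter."""
    from mrnalang import parameter_set

    structural = [list(StructuralClass)[i % 3] for i in range(n)]
    kinetic = [list(KineticClass)[i % 2] for i in range(n)]
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGU"), size=60))
        x = parameter_set(seq).to_dict()[target]
        y = beta * x + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        records.append(
            MrnaRecord(id=f"R{i}", sequence=seq, structural_class=structural[i],
                       kinetic_class=kinetic[i], ln_kf=float(y))
        )
    return StudyDataset(records=tuple(records))


def test_build_tables_shape_and_noise_free_recovery(rng):
    ds = _dataset_with_target(30, rng, beta=2.0, noise_sd=0.0)
    params = compute_parameter_table(ds)
    tables = build_tables(ds, params)
    assert set(tables) == set(TABLE_KEYS)
    for table in tables.values():
        assert table.rows == GROUP_ROWS
        assert table.columns == PARAMETER_COLUMNS
    cell = tables["all_proteins"].cell("all", "D12")
    assert cell.r == pytest.approx(1.0, abs=1e-12)
    assert cell.stars == "***"
    assert cell.slope == pytest.approx(2.0, abs=1e-9)


def test_small_group_cells_flagged_not_computable(rng):
    # 4 records: only 1 multistate -> that row is NC, "all" row computable
    records = []
    for i in range(4):
        seq = "".join(rng.choice(list("ACGU"), size=30))
        records.append(
            MrnaRecord(
                id=f"S{i}", sequence=seq,
                structural_class=StructuralClass.ALL_ALPHA,
                kinetic_class=KineticClass.MULTI_STATE if i == 0 else KineticClass.TWO_STATE,
                ln_kf=float(i),
            )
        )
    ds = StudyDataset(records=tuple(records))
    tables = build_tables(ds, compute_parameter_table(ds))
    t = tables["all_proteins"]
    assert not t.cell("multi_state", "D1").computable
    assert t.cell("multi_state", "D1").formatted() == NOT_COMPUTABLE
    assert t.cell("all", "D1").computable
    # structural classes with zero members give all-NC rows, never KeyErrors
    assert not tables["all_beta"].cell("all", "CGC").computable


def test_constant_parameter_flagged_not_computable():
    records = tuple(
        MrnaRecord(id=f"C{i}", sequence="AAAAAA",
                   structural_class=StructuralClass.ALPHA_BETA,
                   kinetic_class=KineticClass.TWO_STATE, ln_kf=float(i))
        for i in range(5)
    )
    ds = StudyDataset(records=records)
    tables = build_tables(ds, compute_parameter_table(ds))
    cell = tables["all_proteins"].cell("all", "D1")
    assert not cell.computable and "constant" in cell.reason


def test_table_cells_equal_direct_pearson_recalculation(rng):
    """No cross-contamination: each cell equals a from-scratch subgroup call."""
    ds = _dataset_with_target(36, rng, beta=1.0, noise_sd=0.5)
    params = compute_parameter_table(ds).set_index("id")
    tables = build_tables(ds, compute_parameter_table(ds))
    for sc in StructuralClass:
        recs = [r for r in ds if r.structural_class is sc]
        two = [r for r in recs if r.kinetic_class is KineticClass.TWO_STATE]
        for row, group in (("all", recs), ("two_state", two)):
            for col in ("CGC", "D12", "D23"):
                x = [params.loc[r.id, col] for r in group]
                y = [r.ln_kf for r in group]
                expected_r, expected_p = pearson_with_p(x, y)
                cell = tables[sc.value].cell(row, col)
                assert cell.n == len(group)
                assert cell.r == pytest.approx(expected_r, abs=1e-12)
                assert cell.p_value == pytest.approx(expected_p, rel=1e-9)


def test_empty_dataset_rejected():
    with pytest.raises(EmptyDatasetError):
        build_tables(StudyDataset(records=()), None)


def test_associate_result_formatting(rng):
    x = rng.normal(size=20)
    y = 3.0 * x + rng.normal(size=20)
    res = associate(x, y, "all", "D1")
    assert res.formatted() == f"{res.r:.2f}{res.stars}"
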