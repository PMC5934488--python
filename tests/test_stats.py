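"""Permutation inference and FDR correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from restnet.stats import (
    GLOBAL_INDICES,
    MetricsTable,
    compare_global,
    compare_nodal,
    fdr_bh,
    gated_families,
    permutation_test,
)

BANDS = ("theta", "alpha", "beta1", "beta2")


def make_table(rng, n_case=19, n_ctrl=52, shift=None):
    """Metrics table of standard normals; `shift` = {(index, band): delta}."""
    subjects = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_ctrl)]
    cols = pd.MultiIndex.from_product([GLOBAL_INDICES, BANDS])
    values = pd.DataFrame(
        rng.standard_normal((n_case + n_ctrl, len(cols))),
        index=subjects, columns=cols,
    )
    for (idx, band), delta in (shift or {}).items():
        values.loc[subjects[:n_case], (idx, band)] += delta
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_ctrl, index=subjects
    )
    return MetricsTable(values=values, groups=groups)


def test_constant_samples_give_p_one():
    with pytest.warns(UserWarning, match="zero pooled variance"):
        res = permutation_test([1.0, 1.0, 1.0], [1.0, 1.0], n_perm=100, seed=0)
    assert res.p == 1.0


def test_fully_separated_samples_hit_add_one_floor():
    x = np.zeros(19)
    y = np.full(52, 100.0)
    res = permutation_test(x, y, n_perm=5000, seed=1)
    assert res.p == pytest.approx(1 / 5001)


def test_p_value_invariant_under_group_exchange():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 20)
    a = permutation_test(x, y, n_perm=2000, seed=3)
    b = permutation_test(y, x, n_perm=2000, seed=3)
    assert a.p == b.p
    assert a.t_obs == pytest.approx(-b.t_obs)


def test_permutation_p_uniform_under_null():
    """Null calibration: p-values uniform (two-sided KS at alpha 0.01)."""
    rng = np.random.default_rng(4)
    ps = []
    for rep in range(300):
        x = rng.standard_normal(10)
        y = rng.standard_normal(15)
        ps.append(permutation_test(x, y, n_perm=500, seed=rep).p)
    assert sp_stats.kstest(ps, "uniform").pvalue > 0.01


def test_fdr_bh_worked_example_and_edge_cases():
    q = fdr_bh([0.005, 0.009, 0.05, 0.5])
    assert np.allclose(q, [0.018, 0.018, 0.05 * 4 / 3, 0.5])
    assert fdr_bh([0.03])[0] == pytest.approx(0.03)
    assert np.allclose(fdr_bh([0.05] * 4), 0.05)
    with pytest.raises(ValueError):
        fdr_bh([0.5, 1.2])


def test_fdr_bh_monotone_in_p():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=30)
    q = fdr_bh(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


def test_compare_global_runs_all_28_cells_with_joint_fdr():
    rng = np.random.default_rng(6)
    table = make_table(rng)
    results = compare_global(table, n_perm=200, seed=0)
    assert len(results) == 28
    assert {(r.index, r.band) for r in results} == {
        (i, b) for i in GLOBAL_INDICES for b in BANDS
    }
    # joint FDR: q recomputable from the 28 p-values
    q = fdr_bh([r.p for r in results])
    assert np.allclose([r.q for r in results], q)
    assert all(r.p >= 1 / 201 for r in results)


def test_compare_global_detects_injected_shift():
    rng = np.random.default_rng(7)
    table = make_table(rng, shift={("clustering", "theta"): -2.0})
    results = compare_global(table, n_perm=1000, seed=1)
    hit = [r for r in results if (r.index, r.band) == ("clustering", "theta")]
    assert hit[0].q < 0.05


def test_compare_global_is_seed_reproducible():
    rng = np.random.default_rng(8)
    table = make_table(rng)
    a = compare_global(table, n_perm=300, seed=9)
    b = compare_global(table, n_perm=300, seed=9)
    assert a == b


def test_metrics_table_rejects_missing_cells_and_bad_groups():
    rng = np.random.default_rng(9)
    table = make_table(rng, n_case=3, n_ctrl=4)
    values = table.values.copy()
    values.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing metric cells"):
        MetricsTable(values=values, groups=table.groups)
    with pytest.raises(ValueError, match="two groups"):
        MetricsTable(
            values=table.values,
            groups=pd.Series("case", index=table.values.index),
        )


def _nodal_tables(rng, n_roi=10, shift_roi=None):
    subjects = [f"c{i}" for i in range(8)] + [f"n{i}" for i in range(12)]
    groups = pd.Series(["case"] * 8 + ["control"] * 12, index=subjects)
    tables = {}
    for band in ("theta", "beta2"):
        df = pd.DataFrame(
            rng.standard_normal((20, n_roi)),
            index=subjects,
            columns=[f"roi{r}" for r in range(n_roi)],
        )
        if shift_roi and band == "beta2":
            df.loc[subjects[:8], shift_roi] += 3.0
        tables[band] = df
    return tables, groups


def test_compare_nodal_gating_and_family_fdr():
    rng = np.random.default_rng(10)
    tables, groups = _nodal_tables(rng, shift_roi="roi3")
    # n_perm must exceed ~560: with 28 joint tests a lone effect can reach
    # q < 0.05 only if the attainable p floor 1/(n_perm+1) is below 0.05/28
    fake_global = compare_global(
        make_table(rng, shift={("max_bc", "beta2"): 3.0}), n_perm=1000, seed=0
    )
    flagged = gated_families(fake_global)
    assert ("bc", "beta2") in flagged
    results = compare_nodal(
        tables, tables, groups, [("bc", "beta2")],
        n_perm=500, seed=1, global_results=fake_global,
    )
    assert len(results) == 10
    top = max(results, key=lambda r: abs(r.t_obs))
    assert top.index == "bc:roi3" and top.q < 0.05
    # non-flagged band refused without override
    with pytest.raises(ValueError, match="not licensed"):
        compare_nodal(
            tables, tables, groups, [("bc", "theta")],
            n_perm=100, seed=1, global_results=fake_global,
        )
    override = compare_nodal(
        tables, tables, groups, [("bc", "theta")],
        n_perm=100, seed=1, global_results=fake_global, override_gating=True,
    )
    assert len(override) == 10
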