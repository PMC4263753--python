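"""ΔCq quantification chain: RQ, normalization factors, fold changes."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refstab import (
    EfficiencyMap,
    fold_change_report,
    normalization_factor,
    normalize_targets,
    relative_quantities,
)


def rq_of(cq_builder, values, eff):
    table = cq_builder(values)
    return relative_quantities(table, EfficiencyMap.constant(table.gene_ids, eff))


def test_rq_is_one_at_minimum_cq_and_halves_per_cycle(cq_builder):
    rq = rq_of(cq_builder, [[20.0, 25.0], [21.0, 25.0], [23.0, 26.0]], 2.0)
    assert rq["G0"].tolist() == pytest.approx([1.0, 0.5, 0.125])
    assert rq["G0"].max() == 1.0 and rq["G1"].max() == 1.0


def test_rq_with_realistic_efficiency(cq_builder):
    # E = 2.038, three cycles above the minimum: 2.038^-3
    rq = rq_of(cq_builder, [[20.0, 20.0], [23.0, 20.0]], 2.038)
    assert rq.at["s1", "G0"] == pytest.approx(0.11813741426284669, rel=1e-12)


def test_rq_strictly_decreasing_in_cq(cq_builder):
    cq = np.linspace(18, 30, 13)
    rq = rq_of(cq_builder, np.column_stack([cq, np.full(13, 20.0)]), 1.95)
    assert (np.diff(rq["G0"].to_numpy()) < 0).all()
    assert (rq["G0"] > 0).all() and (rq["G0"] <= 1).all()


def test_rq_requires_every_efficiency(cq_builder):
    table = cq_builder([[20.0, 21.0], [21.0, 22.0]])
    with pytest.raises(KeyError, match="G1"):
        relative_quantities(table, EfficiencyMap({"G0": 2.0}))


def test_normalization_factor_examples():
    rq = pd.DataFrame({"a": [0.25, 0.2], "b": [1.0, 0.5], "c": [0.3, 0.9]},
                      index=["s1", "s2"])
    nf1 = normalization_factor(rq, ["a"])
    pd.testing.assert_series_equal(nf1, rq["a"], check_names=False)
    assert normalization_factor(rq, ["a", "b"])["s1"] == pytest.approx(0.5)
    # cube root of 0.2 * 0.5 * 0.9 = 0.09
    assert normalization_factor(rq, ["a", "b", "c"])["s2"] == pytest.approx(
        0.4481404746557165
    )
    with pytest.raises(ValueError, match="at least one"):
        normalization_factor(rq, [])
    with pytest.raises(ValueError, match="positive"):
        normalization_factor(rq.assign(a=[0.0, 0.2]), ["a"])


def test_normalize_targets_is_a_ratio():
    rq = pd.DataFrame({"t": [0.4, 0.8]}, index=["s1", "s2"])
    nf = pd.Series([0.5, 0.8], index=["s1", "s2"])
    out = normalize_targets(rq, nf)
    assert out["t"].tolist() == pytest.approx([0.8, 1.0])


def test_loading_artifact_cancels(cq_builder):
    """Adding a constant to every gene's Cq in one sample (pipetting error)
    leaves normalized expression unchanged."""
    base = np.array([[20.0, 22.0, 25.0], [20.5, 22.5, 25.5], [20.2, 22.1, 25.3]])
    shifted = base.copy()
    shifted[1, :] += 0.7  # common per-sample offset
    eff = EfficiencyMap.constant(["G0", "G1", "G2"], 2.0)

    def normalized(vals):
        rq = relative_quantities(cq_builder(vals), eff)
        nf = normalization_factor(rq, ["G0", "G1"])
        return normalize_targets(rq[["G2"]], nf)

    pd.testing.assert_frame_equal(normalized(base), normalized(shifted))


def _report(control, treated, **kw):
    vals = np.concatenate([control, treated])
    norm = pd.DataFrame({"t": vals})
    meta = pd.DataFrame({"time_h": [0.0] * len(control) + [24.0] * len(treated)})
    return fold_change_report(norm, meta, genes=["t"], **kw).table


def test_fold_change_control_row_is_exactly_one():
    table = _report([0.9, 1.0, 1.1], [1.8, 2.0, 2.2])
    row0 = table[table.time_h == 0].iloc[0]
    assert row0.fold_change == 1.0 and row0.significance == "ns"


def test_identical_groups_are_not_significant():
    table = _report([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
    row = table[table.time_h == 24].iloc[0]
    assert row.fold_change == pytest.approx(1.0)
    assert row.significance == "ns"


def test_zero_variance_separation_reports_p_zero():
    table = _report([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    row = table[table.time_h == 24].iloc[0]
    assert row.fold_change == pytest.approx(2.0)
    assert row.p_value == 0.0 and row.significance == "**"


def test_single_replicate_gives_missing_p():
    norm = pd.DataFrame({"t": [1.0, 1.1, 2.0]})
    meta = pd.DataFrame({"time_h": [0.0, 0.0, 24.0]})
    table = fold_change_report(norm, meta, genes=["t"]).table
    row = table[table.time_h == 24].iloc[0]
    assert np.isnan(row.p_value)
    assert row.fold_change == pytest.approx(2.0 / 1.05)


def _permutation_p(a, b):
    """Exhaustive two-sided permutation p using the pooled-variance t
    statistic over all C(6,3)=20 assignments."""
    pooled = np.concatenate([a, b])
    t_obs = abs(stats.ttest_ind(b, a).statistic)
    count = 0
    for idx in combinations(range(6), 3):
        g1 = pooled[list(idx)]
        g2 = pooled[[i for i in range(6) if i not in idx]]
        if abs(stats.ttest_ind(g2, g1).statistic) >= t_obs - 1e-12:
            count += 1
    return count / 20


def test_p_value_against_exhaustive_permutation_oracle():
    """Student t p-values track the exhaustive 3+3 permutation test: rank
    agreement across seeded cases, bounded disagreement, and the
    complete-separation case where the permutation p sits at its 2/20
    floor while the t-test p falls below it."""
    a = np.array([0.9, 1.0, 1.1])
    b = np.array([1.8, 2.0, 2.2])
    table = _report(a, b)
    row = table[table.time_h == 24].iloc[0]
    assert row.fold_change == pytest.approx(2.0)
    assert _permutation_p(a, b) == 0.1
    assert row.p_value < 0.1  # beats the permutation floor

    rng = np.random.default_rng(42)
    p_t, p_perm = [], []
    for _ in range(60):
        x = rng.normal(1.0, 0.3, 3)
        y = rng.normal(1.0 + rng.uniform(0, 0.5), 0.3, 3)
        row = _report(x, y)[lambda d: d.time_h == 24].iloc[0]
        p_t.append(row.p_value)
        p_perm.append(_permutation_p(x, y))
    rho = stats.spearmanr(p_t, p_perm).statistic
    assert rho >= 0.90
    assert np.median(np.abs(np.array(p_t) - np.array(p_perm))) <= 0.15


def test_welch_option_differs_under_unequal_variance():
    a = [1.0, 1.01, 0.99]
    b = [1.5, 2.5, 3.5]
    p_student = _report(a, b, test="student")[lambda d: d.time_h == 24].iloc[0].p_value
    p_welch = _report(a, b, test="welch")[lambda d: d.time_h == 24].iloc[0].p_value
    assert p_student != p_welch


def test_missing_control_time_is_an_error():
    norm = pd.DataFrame({"t": [1.0, 1.1]})
    meta = pd.DataFrame({"time_h": [4.0, 4.0]})
    with pytest.raises(ValueError, match="control time"):
        fold_change_report(norm, meta, genes=["t"])


def test_bh_correction_raises_p_values():
    rng = np.random.default_rng(7)
    times = np.repeat([0.0, 4.0, 8.0, 24.0], 3)
    norm = pd.DataFrame({"t": rng.normal(1.0, 0.2, 12) + (times == 24) * 1.5})
    meta = pd.DataFrame({"time_h": times})
    raw = fold_change_report(norm, meta, genes=["t"]).table
    adj = fold_change_report(norm, meta, genes=["t"], bh_correction=True).table
    assert (adj.p_value.to_numpy() >= raw.p_value.to_numpy() - 1e-12).all()
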