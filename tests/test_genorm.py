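"""geNorm stability measure, stepwise ranking, and the V series."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refstab import (
    genorm_rank,
    m_values,
    optimal_rg_count,
    pairwise_ratio_sd,
    pairwise_variation_series,
)


def random_rq(seed, n_samples=8, n_genes=8):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        2.0 ** rng.normal(0, 1, size=(n_samples, n_genes)),
        columns=[f"G{j}" for j in range(n_genes)],
    )


# -- pairwise ratio SD -------------------------------------------------

def test_proportional_columns_have_zero_variation():
    q = np.array([0.2, 0.7, 1.0])
    assert pairwise_ratio_sd(q, 3.5 * q) == pytest.approx(0.0, abs=1e-12)


def test_hand_computed_ratio_sd():
    # log2 ratios are (0, 1, 2) whose n-1 SD is exactly 1
    assert pairwise_ratio_sd([1, 2, 4], [1, 1, 1]) == pytest.approx(1.0)


def test_ratio_sd_scale_invariant_and_symmetric():
    rng = np.random.default_rng(0)
    qj, qk = rng.lognormal(size=10), rng.lognormal(size=10)
    v = pairwise_ratio_sd(qj, qk)
    assert pairwise_ratio_sd(17.3 * qj, qk) == pytest.approx(v, rel=1e-12)
    assert pairwise_ratio_sd(qk, qj) == pytest.approx(v, rel=1e-12)
    with pytest.raises(ValueError, match="2 samples"):
        pairwise_ratio_sd([1.0], [1.0])


# -- M values ----------------------------------------------------------

def test_two_genes_share_their_pair_sd():
    rq = random_rq(1, n_genes=2)
    m = m_values(rq)
    v = pairwise_ratio_sd(rq["G0"], rq["G1"])
    assert m["G0"] == pytest.approx(v) and m["G1"] == pytest.approx(v)


def test_m_from_constructed_pairwise_sds():
    """Three genes built so V12=0.1, V13=0.3, V23=0.2 exactly; M must be
    their averages (0.2, 0.15, 0.25)."""
    u = np.array([-1.0, 0.0, 1.0])  # SD exactly 1
    y1, y2, y3 = np.zeros(3), -0.1 * u, -0.3 * u
    rq = pd.DataFrame({"A": 2.0**y1, "B": 2.0**y2, "C": 2.0**y3})
    m = m_values(rq)
    assert m.tolist() == pytest.approx([0.2, 0.15, 0.25])


def test_m_matches_brute_force_pairwise_oracle():
    """Vectorized M equals the definition computed by a double loop over
    pairs, to 1e-12, on random 8x8 tables."""
    for seed in range(5):
        rq = random_rq(seed)
        m = m_values(rq)
        for j, gj in enumerate(rq.columns):
            acc = [
                pairwise_ratio_sd(rq[gj], rq[gk])
                for gk in rq.columns
                if gk != gj
            ]
            assert m[gj] == pytest.approx(np.mean(acc), abs=1e-12)


def test_coregulated_copy_lowers_m():
    rq = random_rq(3, n_genes=4)
    m_before = m_values(rq)["G0"]
    rq["copy"] = rq["G0"] * 2.0  # perfectly co-regulated duplicate
    assert m_values(rq)["G0"] < m_before


def test_m_monotone_in_injected_noise():
    rng = np.random.default_rng(11)
    base = 2.0 ** rng.normal(0, 0.1, size=(40, 5))
    prev = -1.0
    for sd in [0.0, 0.2, 0.4, 0.8]:
        noisy = base.copy()
        noisy[:, 0] *= 2.0 ** np.random.default_rng(5).normal(0, sd, 40)
        m = m_values(pd.DataFrame(noisy, columns=list("ABCDE")))["A"]
        assert m > prev
        prev = m


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_m_invariant_under_rescaling(seed):
    """Per-gene positive rescaling (additive Cq offsets) and per-sample
    common rescaling leave M unchanged."""
    rng = np.random.default_rng(seed)
    rq = random_rq(seed, n_samples=6, n_genes=4)
    gene_scale = rng.lognormal(size=4)
    sample_scale = rng.lognormal(size=(6, 1))
    rescaled = pd.DataFrame(
        rq.to_numpy() * gene_scale * sample_scale, columns=rq.columns
    )
    pd.testing.assert_series_equal(
        m_values(rq), m_values(rescaled), rtol=1e-9
    )


# -- stepwise ranking --------------------------------------------------

def test_noisiest_gene_excluded_first():
    rng = np.random.default_rng(21)
    n = 1000
    a = 2.0 ** rng.normal(0, 0.1, n)
    b = 2.0 ** rng.normal(0, 0.1, n)
    c = 2.0 ** rng.normal(0, 0.2, n)  # double noise SD
    res = genorm_rank(pd.DataFrame({"A": a, "B": b, "C": c}))
    assert res.exclusion_order == ["C"]
    assert res.ranking == {"A": 1, "B": 1, "C": 3}


def test_ranking_structure_is_permutation_with_one_tied_pair():
    for seed in range(4):
        rq = random_rq(seed, n_samples=10, n_genes=7)
        res = genorm_rank(rq)
        positions = sorted(res.ranking.values())
        assert positions == [1, 1] + list(range(3, 8))
        assert set(res.rank_order) == set(rq.columns)
        # reported stepwise M is each gene's M at its exclusion round
        assert (res.m_stepwise >= 0).all()
        assert len(res.m_first_round) == 7


def test_genorm_needs_three_genes():
    with pytest.raises(ValueError, match="at least 3"):
        genorm_rank(random_rq(0, n_genes=2))


def test_rank_invariant_under_rescaling():
    rq = random_rq(9, n_samples=12, n_genes=6)
    rng = np.random.default_rng(1)
    rescaled = rq * rng.lognormal(size=6)
    assert genorm_rank(rq).ranking == genorm_rank(rescaled).ranking


# -- V series and gene count -------------------------------------------

def test_v_zero_when_next_gene_proportional_to_nf():
    q = 2.0 ** np.random.default_rng(0).normal(0, 0.5, 12)
    rq = pd.DataFrame({"A": q, "B": 2 * q, "C": 0.5 * q})
    v = pairwise_variation_series(rq, ["A", "B", "C"])
    assert v["V2/3"] == pytest.approx(0.0, abs=1e-12)


def test_identical_columns_give_all_zero_v():
    q = 2.0 ** np.random.default_rng(3).normal(0, 0.5, 9)
    rq = pd.DataFrame({g: q for g in "ABCD"})
    v = pairwise_variation_series(rq, list("ABCD"))
    assert np.allclose(v.to_numpy(), 0.0)


def test_unstable_third_gene_raises_v23():
    rng = np.random.default_rng(17)
    n = 200
    stable = [2.0 ** rng.normal(0, 0.05, n) for _ in range(3)]
    unstable = 2.0 ** rng.normal(0, 0.8, n)
    even = pd.DataFrame({"A": stable[0], "B": stable[1], "C": stable[2]})
    uneven = pd.DataFrame({"A": stable[0], "B": stable[1], "C": unstable})
    v_even = pairwise_variation_series(even, ["A", "B", "C"])["V2/3"]
    v_uneven = pairwise_variation_series(uneven, ["A", "B", "C"])["V2/3"]
    assert v_uneven > v_even


@pytest.mark.parametrize(
    "series, expected, warned",
    [
        ({"V2/3": 0.054, "V3/4": 0.2}, 2, False),   # published cold V2/3
        ({"V2/3": 0.136, "V3/4": 0.2}, 2, False),   # published heat V2/3
        ({"V2/3": 0.2, "V3/4": 0.18, "V4/5": 0.16}, 5, True),
        ({"V2/3": 0.16, "V3/4": 0.12}, 3, False),
    ],
)
def test_optimal_rg_count(series, expected, warned):
    count, flag = optimal_rg_count(pd.Series(series))
    assert count == expected and flag == warned


def test_optimal_rg_count_empty_series_errors():
    with pytest.raises(ValueError, match="empty"):
        optimal_rg_count(pd.Series(dtype=float))
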