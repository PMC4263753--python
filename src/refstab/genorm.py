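"""geNorm: pairwise-variation stability measure M and gene-count selection.

For genes j and k, V_jk is the sample standard deviation over samples of
log2(q_j/q_k); the stability measure M_j is the mean of V_jk over all other
candidates. Genes are ranked by stepwise exclusion of the highest-M gene
until two remain, which are reported tied at position 1 (M cannot
distinguish the last pair). The pairwise-variation series
V_{n/n+1} = SD(log2(NF_n/NF_{n+1})) between normalization factors built
from the top n and n+1 genes decides how many reference genes are needed;
the conventional cutoff is 0.15.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("refstab")

#: below this V_{n/n+1}, adding the (n+1)-th reference gene is not required
V_CUTOFF = 0.15


def _as_log2(rq: pd.DataFrame, log_base: float = 2.0) -> pd.DataFrame:
    arr = rq.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("relative quantities must be positive")
    return pd.DataFrame(
        np.log(arr) / np.log(log_base), index=rq.index, columns=rq.columns
    )


def pairwise_ratio_sd(q_j, q_k, log_base: float = 2.0) -> float:
    """SD (n−1 denominator) over samples of log(q_j/q_k); symmetric in j, k."""
    q_j = np.asarray(q_j, dtype=float)
    q_k = np.asarray(q_k, dtype=float)
    if q_j.shape != q_k.shape:
        raise ValueError("quantity vectors must have equal length")
    if q_j.size < 2:
        raise ValueError("need at least 2 samples")
    if (q_j <= 0).any() or (q_k <= 0).any():
        raise ValueError("quantities must be positive")
    ratios = np.log(q_j / q_k) / np.log(log_base)
    return float(np.std(ratios, ddof=1))


def m_values(rq: pd.DataFrame, log_base: float = 2.0) -> pd.Series:
    """Stability measure M_j = mean over k≠j of V_jk for every gene."""
    if rq.shape[1] < 2:
        raise ValueError("M requires at least 2 genes")
    y = _as_log2(rq, log_base).to_numpy()
    n = y.shape[1]
    # V_jk = SD of (y_j - y_k); vectorized over all pairs
    m = np.zeros(n)
    for j in range(n):
        diffs = y[:, [j]] - y  # samples × genes
        sds = np.std(diffs, axis=0, ddof=1)
        m[j] = (sds.sum() - sds[j]) / (n - 1)  # sds[j] = 0 (self)
    return pd.Series(m, index=rq.columns, name="M")


@dataclass
class GeNormResult:
    """Stepwise-exclusion ranking with per-gene M and the V series.

    ``ranking`` maps gene → position with the terminal pair tied at 1;
    ``m_stepwise`` is each gene's M at the round of its exclusion (the final
    pair share their common two-gene M); ``m_first_round`` is M computed
    once on the full panel. ``v_series`` maps n → V_{n/n+1}.
    """

    ranking: dict[str, int]
    exclusion_order: list[str]
    m_stepwise: pd.Series
    m_first_round: pd.Series
    rank_order: list[str]
    v_series: pd.Series = field(default=None)  # type: ignore[assignment]
    recommended_count: int | None = None
    cutoff_warning: bool = False

    def to_frame(self, stepwise: bool = True) -> pd.DataFrame:
        m = self.m_stepwise if stepwise else self.m_first_round
        df = pd.DataFrame(
            {
                "rank": pd.Series(self.ranking),
                "M": m,
            }
        ).loc[self.rank_order]
        df.index.name = "gene"
        return df


def genorm_rank(rq: pd.DataFrame, log_base: float = 2.0) -> GeNormResult:
    """Rank genes by stepwise exclusion of the least stable (highest M) gene.

    Ties in the argmax are broken by input column order: the first-listed
    gene is retained longer (the later-listed tied gene is excluded), and
    the tie is logged. Excluded genes take positions N, N−1, …, 3; the two
    survivors share position 1.
    """
    if rq.shape[1] < 3:
        raise ValueError("stepwise ranking requires at least 3 genes")
    genes = list(rq.columns)
    first_round = m_values(rq, log_base)

    survivors = genes[:]
    exclusion_order: list[str] = []
    m_at_exclusion: dict[str, float] = {}
    while len(survivors) > 2:
        m = m_values(rq[survivors], log_base)
        worst_m = m.max()
        tied = [g for g in survivors if m[g] == worst_m]
        if len(tied) > 1:
            logger.info(
                "geNorm tie at M=%.6g between %s; excluding last-listed %s",
                worst_m, tied, tied[-1],
            )
        worst = tied[-1]
        m_at_exclusion[worst] = float(worst_m)
        exclusion_order.append(worst)
        survivors.remove(worst)

    final_m = m_values(rq[survivors], log_base)
    for g in survivors:
        m_at_exclusion[g] = float(final_m[g])

    ranking = {g: 1 for g in survivors}
    for pos, g in zip(range(len(genes), 2, -1), exclusion_order):
        ranking[g] = pos
    rank_order = survivors + exclusion_order[::-1]

    result = GeNormResult(
        ranking=ranking,
        exclusion_order=exclusion_order,
        m_stepwise=pd.Series(m_at_exclusion, name="M").reindex(genes),
        m_first_round=first_round,
        rank_order=rank_order,
    )
    result.v_series = pairwise_variation_series(rq, rank_order, log_base)
    result.recommended_count, result.cutoff_warning = optimal_rg_count(
        result.v_series, warn=False
    )
    return result


def pairwise_variation_series(
    rq: pd.DataFrame, rank_order: list[str], log_base: float = 2.0
) -> pd.Series:
    """V_{n/n+1} for n = 2 .. N−1 along the stability ranking.

    NF_n[s] is the geometric mean over the top-n genes of their quantities
    in sample s; V_n is the SD over samples of log(NF_n/NF_{n+1})."""
    n_genes = len(rank_order)
    if n_genes < 3:
        raise ValueError("V series requires at least 3 ranked genes")
    y = _as_log2(rq[rank_order], log_base).to_numpy()
    out = {}
    for n in range(2, n_genes):
        nf_n = y[:, :n].mean(axis=1)  # log of geometric mean
        nf_n1 = y[:, : n + 1].mean(axis=1)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(out, name="V")


def optimal_rg_count(
    v_series: pd.Series, cutoff: float = V_CUTOFF, warn: bool = True
) -> tuple[int, bool]:
    """Smallest n with V_{n/n+1} below the cutoff.

    Returns (count, no_value_under_cutoff). If no V falls below the cutoff
    the full panel size N is returned with the warning flag set."""
    if len(v_series) == 0:
        raise ValueError("empty V series")
    for label, v in v_series.items():
        n = int(str(label).split("/")[0].lstrip("V"))
        if v < cutoff:
            return n, False
    n_full = int(str(v_series.index[-1]).split("/")[1])
    if warn:
        logger.warning(
            "no V_{n/n+1} below cutoff %.3g; recommending the full panel (%d)",
            cutoff, n_full,
        )
    return n_full, True
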