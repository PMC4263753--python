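"""Consensus ranking: geometric mean of per-algorithm competition ranks.

Each algorithm contributes a position per gene (most stable = 1; tied genes
share the minimal position and the next distinct score skips the tied
count). The consensus score is the geometric mean of the three positions;
the final ordering is ascending in that score. With three algorithms each
ranking N genes the score lies in [1, N] and equals N only for a gene
ranked last by all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("refstab")


@dataclass
class AlgorithmRanking:
    """Named per-gene positions from one stability algorithm.

    Positions are competition ranks: integers in 1..N where tied genes share
    the minimal position and the following positions are skipped.
    """

    algorithm: str
    positions: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.positions)
        vals = sorted(self.positions.values())
        expected = list(rankdata(vals, method="min").astype(int))
        if vals != expected:
            raise ValueError(
                f"{self.algorithm}: positions {vals} are not valid competition "
                f"ranks over {n} genes"
            )


def competition_ranks(
    scores: pd.Series | dict, direction: str = "ascending_is_best"
) -> dict[str, int]:
    """Competition (minimum) ranks from stability scores.

    ``ascending_is_best``: the lowest score gets position 1 (the convention
    for M, ρ and dispersion, where lower means more stable).
    """
    s = pd.Series(scores, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    if direction == "descending_is_best":
        s = -s
    elif direction != "ascending_is_best":
        raise ValueError(f"unknown direction: {direction!r}")
    pos = rankdata(s.to_numpy(), method="min").astype(int)
    return dict(zip(s.index, pos))


@dataclass
class ConsensusRanking:
    """Per-gene positions from each algorithm, their geometric mean, and the
    final ordering (ascending geometric mean)."""

    table: pd.DataFrame  # columns: one per algorithm, geometric_mean, rank
    algorithms: list[str]

    @property
    def rank_order(self) -> list[str]:
        return list(self.table.index)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def consensus_geomean(rankings: list[AlgorithmRanking]) -> ConsensusRanking:
    """Aggregate per-algorithm positions by their geometric mean.

    All rankings must cover the same gene set. Output is sorted by
    ascending geometric mean (ties keep the first ranking's gene order).
    """
    if len(rankings) < 2:
        raise ValueError("consensus needs at least 2 rankings")
    gene_sets = [set(r.positions) for r in rankings]
    base = gene_sets[0]
    for r, gs in zip(rankings[1:], gene_sets[1:]):
        if gs != base:
            raise ValueError(
                f"gene sets differ between {rankings[0].algorithm!r} and "
                f"{r.algorithm!r}: only in first {sorted(base - gs)}, "
                f"only in second {sorted(gs - base)}"
            )
    genes = list(rankings[0].positions)
    cols = {r.algorithm: [r.positions[g] for g in genes] for r in rankings}
    df = pd.DataFrame(cols, index=genes)
    df["geometric_mean"] = np.exp(np.log(df.to_numpy(dtype=float)).mean(axis=1))
    df = df.sort_values("geometric_mean", kind="stable")
    df["rank"] = rankdata(df["geometric_mean"].to_numpy(), method="min").astype(int)
    df.index.name = "gene"
    return ConsensusRanking(df, [r.algorithm for r in rankings])


def format_geomean(value: float) -> str:
    """Render a consensus score the way stability tables print it: 3
    decimals, trimmed to 4 significant figures for values ≥ 10 (10.00)."""
    return f"{value:.2f}" if value >= 10 else f"{value:.3f}"


def top_k(consensus: ConsensusRanking, k: int = 3) -> list[str]:
    """The k best consensus genes; ties spanning the boundary are all
    included (with a warning), so the list may exceed k."""
    order = consensus.rank_order
    if k >= len(order):
        return order
    gm = consensus.table["geometric_mean"]
    cut = gm.iloc[k - 1]
    selected = [g for g in order if gm[g] <= cut]
    if len(selected) > k:
        logger.warning(
            "consensus tie at geometric mean %.3f: returning %d genes for k=%d",
            cut, len(selected), k,
        )
    return selected
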