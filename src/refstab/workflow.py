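"""End-to-end stability workflow: Cq → RQ → three algorithms → consensus."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bestkeeper import BestKeeperResult, bestkeeper_analysis
from .consensus import (
    AlgorithmRanking,
    ConsensusRanking,
    competition_ranks,
    consensus_geomean,
    format_geomean,
    top_k,
)
from .core import CqTable, EfficiencyMap, GroupDesign
from .genorm import GeNormResult, genorm_rank
from .normfinder import NormFinderResult, log_quantities, normfinder_stability
from .quantify import relative_quantities


@dataclass
class StabilityReport:
    """Per-algorithm results plus the consensus over competition ranks."""

    genorm: GeNormResult
    normfinder: NormFinderResult
    bestkeeper: BestKeeperResult
    consensus: ConsensusRanking
    recommended_count: int | None

    def top_reference_genes(self, k: int = 3) -> list[str]:
        return top_k(self.consensus, k)

    def to_frame(self) -> pd.DataFrame:
        """Stability-table layout: one row per consensus rank, per-algorithm
        score and position, consensus geometric mean."""
        c = self.consensus.table
        df = pd.DataFrame(index=c.index)
        df["genorm_rank"] = c["geNorm"]
        df["genorm_M"] = self.genorm.m_stepwise
        df["normfinder_rank"] = c["NormFinder"]
        df["normfinder_rho"] = self.normfinder.rho
        df["bestkeeper_rank"] = c["BestKeeper"]
        df["bestkeeper_sd"] = self.bestkeeper.descriptives["dispersion"]
        df["bestkeeper_r"] = self.bestkeeper.correlations["r"]
        df["geometric_mean"] = c["geometric_mean"]
        df["rank"] = c["rank"]
        df.index.name = "gene"
        return df


def stability_analysis(
    cq: CqTable,
    efficiencies: EfficiencyMap | None = None,
    genes: list[str] | None = None,
    groups: GroupDesign | None = None,
    use_classic_sd: bool = False,
) -> StabilityReport:
    """Run geNorm, the model-based analysis and BestKeeper on the candidate
    reference genes and aggregate their rankings by geometric mean.

    geNorm and the model-based analysis work on efficiency-corrected
    relative quantities (assumed perfect doubling, E = 2, when no
    efficiencies are supplied); BestKeeper works on raw Cq.
    """
    candidates = genes if genes is not None else cq.reference_candidates
    if len(candidates) < 3:
        raise ValueError("stability analysis requires at least 3 candidate genes")
    sub = cq.subset_genes(candidates)
    if efficiencies is None:
        efficiencies = EfficiencyMap.constant(candidates)

    rq = relative_quantities(sub, efficiencies)
    gn = genorm_rank(rq)
    nf = normfinder_stability(log_quantities(rq), groups)
    bk = bestkeeper_analysis(sub, use_classic_sd=use_classic_sd)

    rankings = [
        AlgorithmRanking("geNorm", gn.ranking),
        AlgorithmRanking("NormFinder", nf.ranking),
        AlgorithmRanking("BestKeeper", bk.ranking),
    ]
    cons = consensus_geomean(rankings)
    return StabilityReport(gn, nf, bk, cons, gn.recommended_count)


__all__ = [
    "StabilityReport",
    "stability_analysis",
    "competition_ranks",
    "format_geomean",
]
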