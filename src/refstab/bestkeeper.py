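"""BestKeeper: descriptive Cq dispersion, the per-sample index, and
gene-vs-index correlation.

Unlike geNorm and the model-based analysis, BestKeeper works on raw Cq.
Each candidate gene is summarised by its Cq spread — by convention the
"SD (± Cq)" it reports is the mean absolute deviation around the arithmetic
mean, not the n−1 standard deviation (both are computed here) — and by the
Pearson correlation of its Cq column with the BestKeeper index, the
per-sample geometric mean of all candidate genes' Cq. Genes with dispersion
above 1 cycle are conventionally considered unacceptable as references.
Ranking is by ascending dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CqTable

logger = logging.getLogger("refstab")

#: dispersion (cycles) above which a candidate is conventionally rejected
ACCEPTABLE_SD = 1.0


def cq_descriptives(cq: CqTable | pd.DataFrame, use_classic_sd: bool = False) -> pd.DataFrame:
    """Per-gene descriptive statistics of raw Cq.

    Columns: geo_mean, mean, min, max, sd_mad (mean absolute deviation from
    the arithmetic mean — the published "SD [± Cq]" convention), sd_classic
    (n−1 SD), cv_percent (100·dispersion/mean) and the acceptability flag.
    ``use_classic_sd`` switches which dispersion feeds CV and the flag.
    """
    values = cq.values if isinstance(cq, CqTable) else cq
    if values.shape[0] < 2:
        raise ValueError("descriptives need at least 2 samples")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    mad = np.abs(arr - mean).mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    disp = sd if use_classic_sd else mad
    df = pd.DataFrame(
        {
            "geo_mean": stats.gmean(arr, axis=0),
            "mean": mean,
            "min": arr.min(axis=0),
            "max": arr.max(axis=0),
            "sd_mad": mad,
            "sd_classic": sd,
            "dispersion": disp,
            "cv_percent": 100.0 * disp / mean,
            "acceptable": disp <= ACCEPTABLE_SD,
        },
        index=values.columns,
    )
    df.index.name = "gene"
    return df


def bestkeeper_index(cq: CqTable | pd.DataFrame, genes: list[str] | None = None) -> pd.Series:
    """Per-sample BestKeeper index: geometric mean of the candidates' Cq."""
    values = cq.values if isinstance(cq, CqTable) else cq
    if genes is None:
        genes = list(values.columns)
    if not genes:
        raise ValueError("need at least one gene for the index")
    arr = values[genes].to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("Cq values must be positive for the geometric mean")
    return pd.Series(stats.gmean(arr, axis=1), index=values.index, name="index")


def index_correlations(
    cq: CqTable | pd.DataFrame, index: pd.Series
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each gene's Cq against the index.

    p comes from the exact t transform t = r·sqrt((N−2)/(1−r²)) on N−2
    degrees of freedom. Zero-variance genes (or a constant index) have no
    defined correlation and are reported as NaN with a warning.
    """
    values = cq.values if isinstance(cq, CqTable) else cq
    idx = index.reindex(values.index).to_numpy(dtype=float)
    n = len(idx)
    rows = {}
    for g in values.columns:
        col = values[g].to_numpy(dtype=float)
        if np.std(col) == 0 or np.std(idx) == 0:
            logger.warning("zero variance for gene %s or index; r undefined", g)
            rows[g] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(col, idx)
        if n < 3:
            p = float("nan")
        rows[g] = (float(r), float(p))
    df = pd.DataFrame(rows, index=["r", "p_value"]).T
    df.index.name = "gene"
    return df


@dataclass
class BestKeeperResult:
    """Descriptives, index, correlations and the dispersion-based ranking."""

    descriptives: pd.DataFrame
    index: pd.Series
    correlations: pd.DataFrame
    ranking: dict[str, int]
    rank_order: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = self.descriptives.join(self.correlations)
        df["rank"] = pd.Series(self.ranking)
        return df.loc[self.rank_order]


def bestkeeper_rank(
    descriptives: pd.DataFrame, correlations: pd.DataFrame
) -> tuple[dict[str, int], list[str]]:
    """Order genes by ascending dispersion; exact ties broken by larger |r|,
    then by input order (logged). Positions are competition ranks on the
    dispersion values."""
    disp = descriptives["dispersion"]
    absr = correlations["r"].abs().reindex(disp.index).fillna(-1.0)
    order = sorted(
        range(len(disp)),
        key=lambda i: (disp.iloc[i], -absr.iloc[i], i),
    )
    rank_order = [disp.index[i] for i in order]
    positions = stats.rankdata(disp.to_numpy(), method="min").astype(int)
    ranking = dict(zip(disp.index, positions))
    tied = disp[disp.duplicated(keep=False)]
    if len(tied):
        logger.info("dispersion ties broken by |r| then input order: %s",
                    sorted(tied.index))
    return ranking, rank_order


def bestkeeper_analysis(
    cq: CqTable | pd.DataFrame,
    genes: list[str] | None = None,
    use_classic_sd: bool = False,
) -> BestKeeperResult:
    """Full BestKeeper pass: descriptives, index over all candidates (no
    pre-filtering), correlations and ranking."""
    values = cq.values if isinstance(cq, CqTable) else cq
    if genes is not None:
        values = values[genes]
    desc = cq_descriptives(values, use_classic_sd=use_classic_sd)
    idx = bestkeeper_index(values)
    corr = index_correlations(values, idx)
    ranking, rank_order = bestkeeper_rank(desc, corr)
    return BestKeeperResult(desc, idx, corr, ranking, rank_order)
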