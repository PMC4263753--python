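"""Efficiency-corrected ΔCq relative quantification and fold-change reports.

The chain is: Cq → relative quantities RQ = E^(ΔCq) with ΔCq measured from
each gene's lowest Cq (so the most-expressing sample has RQ = 1) → a
per-sample normalization factor NF, the geometric mean of the selected
reference genes' RQ → normalized expression N = RQ/NF → per-time-point fold
change against the t = 0 control group with a two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CqTable, EfficiencyMap

logger = logging.getLogger("refstab")


def relative_quantities(cq: CqTable, eff: EfficiencyMap) -> pd.DataFrame:
    """ΔCq relative quantities: RQ[s, g] = E_g ** (min_s' Cq[s', g] − Cq[s, g]).

    Each gene is rescaled so its minimum-Cq (most expressing) sample has
    RQ exactly 1; all other samples fall in (0, 1].
    """
    missing = [g for g in cq.gene_ids if g not in eff]
    if missing:
        raise KeyError(f"genes without amplification efficiency: {missing}")
    out = {}
    for g in cq.gene_ids:
        col = cq.values[g].astype(float)
        out[g] = eff[g] ** (col.min() - col)
    rq = pd.DataFrame(out, index=cq.values.index)
    return rq


def normalization_factor(rq: pd.DataFrame, reference_genes: list[str]) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the selected
    reference genes' relative quantities."""
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    missing = [g for g in reference_genes if g not in rq.columns]
    if missing:
        raise KeyError(f"reference genes absent from RQ table: {missing}")
    sub = rq[reference_genes].to_numpy(dtype=float)
    if (sub <= 0).any():
        raise ValueError("relative quantities must be positive")
    nf = np.exp(np.log(sub).mean(axis=1))
    return pd.Series(nf, index=rq.index, name="NF")


def normalize_targets(rq: pd.DataFrame, nf: pd.Series) -> pd.DataFrame:
    """Normalized expression N[s, g] = RQ[s, g] / NF[s]."""
    missing = [s for s in rq.index if s not in nf.index]
    if missing:
        raise KeyError(f"samples without a normalization factor: {missing}")
    nf = nf.reindex(rq.index)
    if (nf == 0).any():
        raise ValueError("normalization factor of zero")
    return rq.div(nf, axis=0)


@dataclass
class ExpressionReport:
    """Per (target gene, time point) fold change vs the control group with
    replicate mean ± SD, a t-test p-value and a significance flag
    (ns, ``*`` for p ≤ 0.05, ``**`` for p ≤ 0.01)."""

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _flag(p: float) -> str:
    if pd.isna(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _ttest(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sided two-sample t-test p-value with degenerate-variance handling."""
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 1.0
        logger.warning(
            "zero within-group variance with unequal means; p reported as 0"
        )
        return 0.0
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return float(res.pvalue)


def fold_change_report(
    normalized: pd.DataFrame,
    sample_meta: pd.DataFrame,
    genes: list[str] | None = None,
    control_time: float = 0.0,
    test: str = "student",
    per_timepoint_control: bool = False,
    bh_correction: bool = False,
    time_column: str = "time_h",
) -> ExpressionReport:
    """Fold change of each gene at each time point relative to the control.

    By default the control is the ``control_time`` group and every time
    point's replicate mean is divided by the control replicate mean (the
    control row is exactly 1). With ``per_timepoint_control`` the control
    values are matched by replicate at each time point instead (for paired
    treated/untreated designs). p-values are two-sided two-sample t-tests
    (Student by default, Welch with ``test='welch'``) of the replicate
    values; optional Benjamini–Hochberg correction across time points per
    gene.
    """
    if test not in {"student", "welch"}:
        raise ValueError(f"unknown test: {test!r}")
    if time_column not in sample_meta.columns:
        raise KeyError(f"sample metadata lacks column {time_column!r}")
    times = sample_meta[time_column].astype(float)
    if not (times == control_time).any():
        raise ValueError(f"control time {control_time} not present in design")
    genes = list(genes) if genes is not None else list(normalized.columns)

    rows = []
    for g in genes:
        vals = normalized[g]
        control = vals[times == control_time].to_numpy(dtype=float)
        pvals, keys = [], []
        for t in sorted(times.unique()):
            grp = vals[times == t].to_numpy(dtype=float)
            if per_timepoint_control and t != control_time:
                ref = control[: len(grp)]
            else:
                ref = control
            fc = grp.mean() / control.mean()
            if t == control_time:
                fc = 1.0  # exact by construction
            p = 1.0 if t == control_time else _ttest(grp, ref, test)
            if len(grp) < 2 or len(ref) < 2:
                logger.warning(
                    "gene %s, t=%g: fewer than 2 replicates; p undefined", g, t
                )
            rows.append(
                {
                    "gene": g,
                    "time_h": t,
                    "fold_change": fc,
                    "mean": grp.mean(),
                    "sd": grp.std(ddof=1) if len(grp) > 1 else float("nan"),
                    "n": len(grp),
                    "p_value": p,
                }
            )
            pvals.append(p)
            keys.append(len(rows) - 1)
        if bh_correction:
            adj = _benjamini_hochberg(np.array(pvals, dtype=float))
            for k, p in zip(keys, adj):
                rows[k]["p_value"] = p

    table = pd.DataFrame(rows)
    table["significance"] = table["p_value"].map(_flag)
    table.loc[table["time_h"] == control_time, "significance"] = "ns"
    return ExpressionReport(table)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj
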