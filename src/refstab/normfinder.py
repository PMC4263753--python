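"""Model-based stability estimation (NormFinder-style analysis of variance).

Works on log2 relative quantities. Each sample is centred by its across-gene
mean, which absorbs sample-loading effects; the model then attributes the
remaining spread of each gene to intra-group variance σ²_ig and, when a
grouping of samples is supplied, a systematic inter-group difference d_ig.
Because centring mixes every gene's noise into every other gene's residuals,
the naive per-gene residual variance is biased; the unbiased estimate solves
the induced linear system:

    σ̂²_ig = max(0, n/(n−2) · (v_ig − V_g / (n(n−1))))

with n genes, v_ig the residual variance of gene i in group g and
V_g = Σ_i v_ig. Inter-group differences are shrunk toward zero in proportion
to their sampling noise before entering the stability value

    ρ_i = (1/G) Σ_g ( |d̃_ig| + sqrt(σ̂²_ig / n_g) )       (grouped)
    ρ_i = sqrt(σ̂²_i)                                      (ungrouped)

Lower ρ means more stable. Rankings use competition (minimum) ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import GroupDesign


def log_quantities(rq: pd.DataFrame) -> pd.DataFrame:
    """log2 of relative quantities; errors on nonpositive values."""
    arr = rq.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("relative quantities must be positive for log transform")
    return pd.DataFrame(np.log2(arr), index=rq.index, columns=rq.columns)


def _group_matrix(y: pd.DataFrame, groups: GroupDesign | None) -> dict[str, list]:
    if groups is None:
        return {"all": list(y.index)}
    groups.validate(y.index, min_group_size=2)
    return {label: groups.members(label) for label in groups.labels}


def variance_decomposition(
    y: pd.DataFrame, groups: GroupDesign | None = None
) -> pd.DataFrame:
    """Unbiased per-gene, per-group intra-group variances σ̂²_ig.

    Negative estimates (small-sample artifacts) are truncated at 0.
    Requires at least 3 genes (the bias-correction factor n/(n−2) is
    undefined below that) and ≥2 samples per group.
    """
    n = y.shape[1]
    if n < 3:
        raise ValueError("variance decomposition requires at least 3 genes")
    members = _group_matrix(y, groups)
    out = {}
    for label, samples in members.items():
        block = y.loc[samples].to_numpy(dtype=float)
        if block.shape[0] < 2:
            raise ValueError(f"group {label!r} needs at least 2 samples")
        z = block - block.mean(axis=1, keepdims=True)  # centre each sample
        v = np.var(z, axis=0, ddof=1)
        V = v.sum()
        sigma2 = np.maximum(0.0, (n / (n - 2)) * (v - V / (n * (n - 1))))
        out[label] = sigma2
    return pd.DataFrame(out, index=y.columns)


def group_differences(
    y: pd.DataFrame, groups: GroupDesign, sigma2: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-group expression differences d_ig and their shrunk versions d̃_ig.

    d_ig is the centred group mean of gene i in group g relative to the mean
    over groups. Shrinkage multiplies by γ̂²/(γ̂² + σ̂²_ig/n_g) with
    γ̂² = max(0, mean(d²) − mean(σ̂²/n_g)), pulling noisy differences toward
    zero (and to exactly zero when the observed spread of d is fully
    explained by sampling noise).
    """
    members = _group_matrix(y, groups)
    if len(members) < 2:
        raise ValueError("group differences require at least 2 groups")
    if sigma2 is None:
        sigma2 = variance_decomposition(y, groups)

    zbar = {}
    n_g = {}
    for label, samples in members.items():
        block = y.loc[samples].to_numpy(dtype=float)
        z = block - block.mean(axis=1, keepdims=True)
        zbar[label] = z.mean(axis=0)
        n_g[label] = block.shape[0]
    zbar_df = pd.DataFrame(zbar, index=y.columns)
    d = zbar_df.sub(zbar_df.mean(axis=1), axis=0)

    noise = sigma2.div(pd.Series(n_g), axis=1)
    gamma2 = max(0.0, float(np.mean(d.to_numpy() ** 2) - np.mean(noise.to_numpy())))
    if gamma2 == 0.0:
        d_shrunk = d * 0.0
    else:
        d_shrunk = d * (gamma2 / (gamma2 + noise))
    return d, d_shrunk


@dataclass
class NormFinderResult:
    """Stability values ρ with the variance components behind them."""

    rho: pd.Series
    sigma2: pd.DataFrame          # genes × groups
    d: pd.DataFrame | None        # inter-group differences (grouped mode)
    d_shrunk: pd.DataFrame | None
    ranking: dict[str, int]
    rank_order: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rank": pd.Series(self.ranking), "rho": self.rho})
        df = df.loc[self.rank_order]
        df.index.name = "gene"
        return df


def normfinder_stability(
    y: pd.DataFrame, groups: GroupDesign | None = None
) -> NormFinderResult:
    """Stability value ρ per gene, ranked ascending (lower = more stable)."""
    sigma2 = variance_decomposition(y, groups)
    if groups is not None and groups.n_groups >= 2:
        d, d_shrunk = group_differences(y, groups, sigma2)
        n_g = pd.Series({label: len(groups.members(label)) for label in groups.labels})
        per_group = d_shrunk.abs() + np.sqrt(sigma2.div(n_g, axis=1))
        rho = per_group.mean(axis=1)
    else:
        d = d_shrunk = None
        rho = np.sqrt(sigma2.iloc[:, 0])
    rho = pd.Series(rho, index=y.columns, name="rho")

    positions = rankdata(rho.to_numpy(), method="min").astype(int)
    ranking = dict(zip(y.columns, positions))
    rank_order = list(rho.sort_values(kind="stable").index)
    return NormFinderResult(
        rho=rho, sigma2=sigma2, d=d, d_shrunk=d_shrunk,
        ranking=ranking, rank_order=rank_order,
    )
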