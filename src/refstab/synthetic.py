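"""Synthetic Cq data with known ground truth.

The generator emulates a temperature-stress RT-qPCR time course on a
medicinal plant: a panel of candidate reference genes spanning very
abundant ribosomal transcripts (Cq ≈ 8) to rare ones (Cq ≈ 28), plus target
genes that respond to the stress. The Cq model inverts the quantification
equations downstream code must solve:

    Cq[g, sample(t, rep)] = b_g + s_sample − f_g(t)/log2(E_g) + ε

where b_g is the gene's baseline Cq, s_sample ~ N(0, τ²) is a loading
effect shared by every gene within a sample (exactly the nuisance that
reference-gene normalization removes), f_g(t) is the true log2 fold change
of expression versus t = 0, E_g the amplification factor (so the same fold
change moves Cq differently for different efficiencies), and
ε ~ N(0, σ_g²) is independent per-reaction noise. A gene's true
instability on the log2 scale combines its biological response and its
noise: v_g = Var_t(−f_g(t)) + (σ_g · log2 E_g)².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CqTable, EfficiencyMap, ROLE_REFERENCE, ROLE_TARGET
from .standard_curve import DilutionSeries, FIVEFOLD_STEP, slope_from_efficiency


@dataclass
class GeneSpec:
    """Generator parameters for one gene."""

    gene_id: str
    baseline_cq: float          # cycles, at t = 0 with zero loading/noise
    efficiency: float           # amplification factor E in (1, 2.2]
    sigma: float                # per-reaction Cq noise SD, cycles
    role: str = ROLE_REFERENCE
    profile: dict[float, float] = field(default_factory=dict)  # t(h) -> log2 FC

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.gene_id}: sigma must be ≥ 0")
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError(f"{self.gene_id}: efficiency must be in (1, 2.2]")
        if self.profile.get(0.0, 0.0) != 0.0:
            raise ValueError(f"{self.gene_id}: profile must satisfy f(0) = 0")

    def log2_fc(self, t: float) -> float:
        """Piecewise-linear interpolation of the response profile."""
        if not self.profile:
            return 0.0
        pts = sorted({0.0: 0.0, **self.profile}.items())
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        return float(np.interp(t, xs, ys))


@dataclass
class SyntheticSpec:
    """Full design: condition label, time points × replicates, genes, and
    the sample-loading SD τ (cycles)."""

    seed: int
    condition: str
    time_points_h: list[float]
    replicates: int
    genes: list[GeneSpec]
    loading_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be ≥ 0")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate per time point")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in spec")

    def efficiency_map(self) -> EfficiencyMap:
        return EfficiencyMap({g.gene_id: g.efficiency for g in self.genes})


@dataclass
class GroundTruth:
    """True stability per gene for recovery tests.

    variability is v_g = Var_t(−f_g(t)) + (σ_g·log2 E_g)² on the log2
    scale (population variance over the design's time points); ordering is
    ascending v among candidate reference genes; most_stable is the set of
    candidates within a factor 2 of the minimal v — the clearly-separated
    stable class, since candidates of equal noise σ differ slightly in v
    through their efficiencies."""

    variability: pd.Series
    ordering: list[str]
    most_stable: set[str]


def _ground_truth(spec: SyntheticSpec) -> GroundTruth:
    t = np.array(spec.time_points_h, dtype=float)
    v = {}
    for g in spec.genes:
        f = np.array([g.log2_fc(tp) for tp in t])
        v[g.gene_id] = float(np.var(-f) + (g.sigma * np.log2(g.efficiency)) ** 2)
    candidates = [g.gene_id for g in spec.genes if g.role == ROLE_REFERENCE]
    vs = pd.Series(v, name="variability")
    ordering = sorted(candidates, key=lambda gid: vs[gid])
    vmin = vs[candidates].min()
    most_stable = {gid for gid in candidates if vs[gid] <= 2.0 * vmin}
    return GroundTruth(vs, ordering, most_stable)


def generate_cq(spec: SyntheticSpec) -> tuple[CqTable, GroundTruth]:
    """Draw a Cq table from the generative model; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    sample_ids, cond, times, reps = [], [], [], []
    for t in spec.time_points_h:
        for r in range(1, spec.replicates + 1):
            sample_ids.append(f"{spec.condition}_t{t:g}_r{r}")
            cond.append(spec.condition)
            times.append(t)
            reps.append(r)
    n_samples = len(sample_ids)

    loading = rng.normal(0.0, spec.loading_sd, size=n_samples)
    cols = {}
    for g in spec.genes:
        shift = np.array([g.log2_fc(t) for t in times]) / np.log2(g.efficiency)
        noise = rng.normal(0.0, g.sigma, size=n_samples) if g.sigma > 0 else 0.0
        cols[g.gene_id] = g.baseline_cq + loading - shift + noise

    values = pd.DataFrame(cols, index=sample_ids)
    sample_meta = pd.DataFrame(
        {"condition": cond, "time_h": times, "replicate": reps}, index=sample_ids
    )
    gene_meta = pd.DataFrame(
        {"role": [g.role for g in spec.genes]},
        index=[g.gene_id for g in spec.genes],
    )
    table = CqTable(values, sample_meta, gene_meta).validate()
    return table, _ground_truth(spec)


# ---------------------------------------------------------------------
# Default study designs
# ---------------------------------------------------------------------

COLD_TIME_POINTS_H = [0.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0]
HEAT_TIME_POINTS_H = [0.0, 12.0, 24.0, 72.0, 168.0]  # 7 days = 168 h
REPLICATES = 3

#: default per-reaction noise for stable and unstable candidates (cycles)
STABLE_SIGMA = 0.1
UNSTABLE_SIGMA = 0.6

# Candidate panel: (gene, baseline Cq, E). Baselines span the abundant
# ribosomal genes (~8 cycles) down to rare transcripts (~28 cycles);
# efficiencies span the realistic 1.87-2.04 range. The last two candidates
# are generated unstable.
_CANDIDATES = [
    ("18SrRNA", 8.0, 1.93),
    ("26SrRNA", 9.5, 1.97),
    ("RBCL", 14.0, 1.94),
    ("HYP1", 20.0, 1.97),
    ("GAPDH", 21.0, 1.91),
    ("GSA", 22.0, 2.01),
    ("H2A", 23.0, 1.99),
    ("TUB", 24.0, 1.99),
    ("SDR", 28.0, 1.94),
    ("PKS1", 25.0, 2.02),
    ("PKS2", 26.0, 1.87),
]

# Target responses (log2 fold change vs t = 0): an induced flavonoid-pathway
# gene peaking mid-course, a repressed catalase, a stress-induced oxidase
# with recovery, and a mildly repressed oxidase isoform.
_TARGETS = {
    "cold": [
        ("CHS", 22.0, 2.04, {24.0: 1.2, 48.0: 1.85, 72.0: 1.3}),
        ("CAT1", 23.0, 2.02, {24.0: -1.0, 72.0: -1.0}),
        ("AOX1", 24.0, 1.93, {24.0: 1.5, 72.0: 0.3}),
        ("AOX2", 24.5, 2.02, {24.0: -0.9, 72.0: -0.5}),
    ],
    "heat": [
        ("CHS", 22.0, 2.03, {12.0: -1.9, 72.0: -0.2}),
        ("CAT1", 23.0, 1.98, {24.0: -1.0, 168.0: -1.0}),
        ("AOX1", 24.0, 1.93, {24.0: 0.85, 168.0: 0.85}),
        ("AOX2", 24.5, 1.94, {12.0: -0.4, 168.0: -0.2}),
    ],
}


def study_design(condition: str, seed: int = 0) -> SyntheticSpec:
    """Default synthetic design for the cold (7 time points × 3 replicates)
    or heat (5 × 3) stress time course: 11 candidate reference genes (9
    stable at σ = 0.1 cycles, 2 unstable at σ = 0.6) and 4 responsive
    target genes."""
    if condition == "cold":
        time_points = COLD_TIME_POINTS_H
    elif condition == "heat":
        time_points = HEAT_TIME_POINTS_H
    else:
        raise ValueError(f"unknown condition: {condition!r}")
    genes = [
        GeneSpec(
            gene_id=gid,
            baseline_cq=b,
            efficiency=e,
            sigma=UNSTABLE_SIGMA if gid in ("PKS1", "PKS2") else STABLE_SIGMA,
        )
        for gid, b, e in _CANDIDATES
    ]
    genes += [
        GeneSpec(gid, b, e, STABLE_SIGMA, role=ROLE_TARGET, profile=dict(prof))
        for gid, b, e, prof in _TARGETS[condition]
    ]
    return SyntheticSpec(
        seed=seed,
        condition=condition,
        time_points_h=list(time_points),
        replicates=REPLICATES,
        genes=genes,
    )


def generate_dilution_series(
    efficiency: float,
    intercept: float = 22.0,
    noise_sd: float = 0.0,
    n_points: int = 4,
    step_log10: float = FIVEFOLD_STEP,
    seed: int = 0,
    gene_id: str = "",
) -> DilutionSeries:
    """Simulated standard curve: the undiluted pool at log10 amount 0 plus
    (n_points − 1) serial dilutions (five-fold by default), with
    Cq = intercept + slope·log10(amount) + N(0, noise_sd²) and
    slope = −1/log10(E)."""
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    if n_points < 3:
        raise ValueError("need at least 3 dilution points")
    rng = np.random.default_rng(seed)
    amounts = step_log10 * np.arange(n_points)
    slope = slope_from_efficiency(efficiency)
    cq = intercept + slope * amounts
    if noise_sd > 0:
        cq = cq + rng.normal(0.0, noise_sd, size=n_points)
    return DilutionSeries(amounts, cq, gene_id=gene_id)
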