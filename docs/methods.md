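# Methods

## Scope and data model

The package operates on a complete samples × genes matrix of
quantification cycles (Cq), annotated with a per-sample design (condition,
time in hours, replicate) and per-gene roles (candidate reference gene or
target). Cq values must be finite and in (0, 45); values outside 5–40 are
accepted with a warning. Missing cells are an error under the default
`strict` policy and remove the affected sample under `drop-sample`.
Technical-replicate averaging on read is opt-in (arithmetic mean of
duplicate (sample, gene) pairs); the default assumes one pre-averaged Cq
per biological sample. Time values are normalized to hours internally
(e.g. 7 days → 168 h), so mixed hour/day designs compare cleanly.

## Standard curves and efficiency

A dilution series is encoded as log10 relative template amount with the
undiluted pool at 0 (five-fold steps are −0.699 apart). The fit is
ordinary least squares of Cq on log10 amount; r² is the squared Pearson
correlation of fitted versus observed values, the convention instrument
software prints. Conversions: E = 10^(−1/slope), slope = −1/log10 E,
percent efficiency (E−1)·100. These round-trip to 1e−12 over the realistic
slope range [−4, −2.5]. Efficiencies are validated to (1, 2.2]; real
assays cluster near 1.87–2.04.

## Relative quantities and normalization

RQ[s, g] = E_g^(min_s′ Cq[s′, g] − Cq[s, g]), so each gene's
most-expressing (minimum-Cq) sample has RQ exactly 1 and all RQ lie in
(0, 1]. The per-gene minimum is taken over the full sample set of the
assay being analyzed; ties in the minimum are harmless (identical RQ
either way). The normalization factor is the geometric mean of the
selected reference genes' RQ per sample; normalized expression is RQ/NF.
Because a per-sample loading error multiplies every gene's quantity by a
common factor, it cancels exactly in RQ/NF — the property reference-gene
normalization exists for, and an invariant asserted in the tests.

## geNorm

V_jk is the sample standard deviation (n−1 denominator) over samples of
log2(q_j/q_k); M_j is the mean of V_jk over all other candidates. Log
base 2 is the convention throughout (a natural-log option exists). geNorm
runs on efficiency-corrected relative quantities, not raw Cq. Ranking is
by stepwise exclusion: recompute M on the survivors, drop the argmax-M
gene, repeat until two genes remain; those two are reported tied at
position 1 (M cannot separate the final pair). The per-gene reported M is
its M at the round of its exclusion; a flag reports first-round M instead,
since published tables do not always say which convention they print.
Argmax ties are broken by input column order (first-listed retained
longer) and logged.

V_{n/n+1} is the SD over samples of log2(NF_n/NF_{n+1}), where NF_n is
the geometric mean of the top-n genes' quantities. The recommended gene
count is the smallest n with V_{n/n+1} < 0.15 (the conventional cutoff);
if none qualifies the full panel size is returned with a warning flag
rather than silently.

## Model-based analysis (NormFinder-style)

Input is log2 RQ. Each sample is centred by its across-gene mean, which
absorbs loading effects but also mixes every gene's noise into every other
gene's residuals: for gene i among n genes, the naive residual variance
has expectation σ²_i(1−1/n)² + Σ_{k≠i}σ²_k/n². Solving that linear system
gives the unbiased estimator implemented here,

    σ̂²_ig = max(0, n/(n−2) · (v_ig − V_g/(n(n−1)))),

with v_ig the residual variance of gene i in group g and V_g = Σ_i v_ig;
negative estimates (small-sample artifacts) truncate to 0, and n ≥ 3 genes
are required. Inter-group differences d_ig (centred group mean minus the
unweighted mean over groups) are shrunk by the empirical-Bayes factor
γ̂²/(γ̂² + σ̂²_ig/n_g) with γ̂² = max(0, mean d² − mean σ̂²/n_g): when the
spread of observed d is fully explained by sampling noise, d̃ collapses to
zero. The stability value is ρ_i = (1/G) Σ_g (|d̃_ig| + √(σ̂²_ig/n_g)) in
grouped mode and √σ̂²_i ungrouped. Grouped mode needs G ≥ 2 groups of
n_g ≥ 2; ungrouped is the default since time-course studies do not always
treat time points as subgroups. The decomposition is validated by
simulation: Monte-Carlo recovery of known variances, and a 100-run
parameter-recovery check in which a noisy gene and a group-shifted gene
must occupy the two worst ranks. Exact reproduction of the original
software's shrinkage constants is not attempted; the estimator follows
from the stated model and is judged by these recovery oracles.

## BestKeeper

BestKeeper works on raw Cq. The published "SD [± Cq]" is an average
absolute deviation around the arithmetic mean, not the classic n−1
standard deviation; the mean absolute deviation is therefore the default
dispersion here, with the classic SD always reported alongside and
selectable as the ranking dispersion. The index is the per-sample
geometric mean of all candidates' Cq (no pre-filtering); each gene's
Pearson r against the index gets a two-sided p from
t = r√((N−2)/(1−r²)) on N−2 df. Genes with dispersion > 1 cycle are
flagged unacceptable but not excluded. Ranking is ascending dispersion at
full precision; exact ties break by larger |r|, then input order (logged).
Zero-variance genes have undefined r, reported as missing with a warning.

## Consensus

Each algorithm's scores become competition ranks (best = 1; ties share the
minimal position; the next distinct score skips the tied count — so a tied
pair at 1 is followed by position 3). The consensus score is the geometric
mean of the three positions, ordered ascending; printed-score ties between
algorithms' published values are treated as rounding artifacts when
full-precision scores are available. `top_k` returns the k best genes and
includes all genes tied across the boundary, with a warning, rather than
cutting arbitrarily. The ΔΔCt comparative method sometimes aggregated by
web tools is deliberately excluded: the consensus here is exactly the
three-algorithm geometric mean.

## Quantification reports

Fold change at time t is the replicate mean of normalized expression at t
divided by the mean at the control time (default 0 h), so the control row
is exactly 1. p-values are two-sided two-sample t-tests of replicate
values (Student's equal-variance by default, matching the common
statistics-package default; Welch by flag), flagged * at p ≤ 0.05 and **
at p ≤ 0.01. With both groups at zero variance, equal means give p = 1 and
unequal means give p = 0 with a degeneracy warning; groups of fewer than
two replicates give a missing p but still a fold change. No
multiple-testing correction is applied by default (a Benjamini–Hochberg
flag exists). A `--per-timepoint-control` flag matches control replicates
per time point for paired designs. The t-test p-values are cross-checked
against an exhaustive 20-assignment permutation test at n = 3 + 3; because
the permutation p is granular (multiples of 0.05, floor 2/20) and the
t reference has 4 df, the check asserts rank agreement (Spearman ρ ≥ 0.9)
and bounded median disagreement rather than equality.

## Synthetic data generator

The generator emulates a two-condition temperature-stress time course on a
plant: cold (0, 4, 8, 12, 24, 48, 72 h × 3 replicates = 21 samples) and
heat (0, 12, 24, 72, 168 h × 3 = 15 samples), 11 candidate reference genes
and 4 responsive targets. The model is

    Cq[g, sample(t, r)] = b_g + s_sample − f_g(t)/log2(E_g) + ε,

with baseline Cq b_g spanning 8–28 cycles (abundant ribosomal genes at the
low end, a rare dehydrogenase at the high end), loading effect
s_sample ~ N(0, τ²) shared by all genes within a sample (τ = 0.15 cycles —
a realistic pipetting/input spread, and exactly the nuisance normalization
must remove), response profile f_g(t) in log2 fold-change units
interpolated piecewise-linearly between anchor points with f(0) = 0, and
per-reaction noise ε ~ N(0, σ_g²). Dividing f by log2 E_g makes genes with
different efficiencies encode the same fold change differently, so
efficiency correction is actually exercised. Defaults: nine stable
candidates at σ = 0.1 cycles, two unstable at σ = 0.6 (chosen to separate
rankings decisively at 21 samples while leaving recovery genuinely
stochastic), efficiencies 1.87–2.04, target profiles mimicking an induced
flavonoid-pathway gene (~3.6-fold at 48 h, cold), a repressed catalase, a
stress-induced oxidase with recovery, and a mildly repressed oxidase
isoform. Ground truth per gene is v_g = Var_t(−f_g(t)) + (σ_g·log2 E_g)²;
the "most stable" set is the candidates within a factor 2 of the minimal v
(the clearly-separated stable class — equal-σ candidates differ slightly
in v through their efficiencies, so the strict argmin would be noise).

What the generator does **not** model: technical-replicate structure,
plate/batch effects, inhibitor kinetics, co-regulation between candidates,
heteroscedastic noise at high Cq, and non-normal error. Passing recovery
tests therefore shows the algorithms behave correctly under the stated
model, not that any particular real panel is stable.

Reproducibility: every stochastic operation takes an explicit seed and is
bit-identical per seed; the CLI logs it.

## Validation against published values

Per-algorithm stability scores of the motivating kind of study are not
recomputable without raw Cq data, so validation splits in two: (i) exact
reproduction of the consensus arithmetic — feeding published per-algorithm
positions of an 11-gene cold/heat panel reproduces all 22 printed
geometric means to 3 decimals and both top-3 normalization sets, and the
printed assay efficiencies reproduce the published slope-range endpoints —
and (ii) property-based validation of each algorithm against independent
oracles (brute-force pairwise loops, covariance-definition correlation,
Monte-Carlo variance recovery, exhaustive permutation tests) plus
synthetic-recovery rates over 100 seeded replicates. Problem sizes in the
acceptance script (100 replicates of the 21-sample cold design) keep the
full run in a few seconds while giving rate estimates with ~3-percentage-
point standard errors.

## Known limitations

- The geNorm stepwise procedure inherits the method's blindness to
  co-regulated candidate pairs.
- The model-based estimator requires at least 3 genes and prefers many;
  with few genes the centering correction is noisy and truncation at 0
  biases small variances upward.
- BestKeeper's regression diagnostics of each gene on the index and its
  target-gene co-analysis are not implemented; targets are handled in the
  quantification chain.
- No absolute quantification, inter-plate calibration, instrument-native
  file parsing, or melting-curve analysis.
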