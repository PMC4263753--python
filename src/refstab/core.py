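"""Core containers and delimited-text IO for quantification-cycle (Cq) data.

The universal input of every downstream stage is a :class:`CqTable`: a
complete samples × genes matrix of quantification cycles together with a
per-sample design (condition, time, replicate) and a per-gene role
(candidate reference gene or target gene). Amplification efficiencies travel
separately as an :class:`EfficiencyMap` because they come from a different
experiment (the dilution-series standard curve) than the Cq matrix itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("refstab")

# Hard validity bounds on a quantification cycle; values outside the soft
# band are physically possible but almost always indicate an assay problem.
CQ_HARD_MIN, CQ_HARD_MAX = 0.0, 45.0
CQ_SOFT_MIN, CQ_SOFT_MAX = 5.0, 40.0

# Amplification factor per PCR cycle: 2 is perfect doubling; real assays
# occasionally exceed 2 slightly through pipetting/regression error.
EFFICIENCY_MIN, EFFICIENCY_MAX = 1.0, 2.2

ROLE_REFERENCE = "candidate_reference"
ROLE_TARGET = "target"

#: default number of decimals in text reports
REPORT_PRECISION = 3


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger for CLI use."""
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level.upper())


def hours(value: float, unit: str) -> float:
    """Normalize a time value to hours. Units: ``hours``/``h``/``hpi`` or
    ``days``/``d``/``dpi`` (so 7 dpi → 168 h)."""
    u = unit.lower()
    if u in {"hours", "hour", "h", "hpi"}:
        return float(value)
    if u in {"days", "day", "d", "dpi"}:
        return float(value) * 24.0
    raise ValueError(f"unknown time unit: {unit!r}")


class ValidationError(ValueError):
    """A Cq table or efficiency map violated an invariant."""


@dataclass
class CqTable:
    """Samples × genes matrix of quantification cycles plus annotations.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and gene ids as columns; every
        cell a finite Cq in cycles.
    sample_meta
        DataFrame indexed by sample id; recognised columns are
        ``condition``, ``time_h`` (hours) and ``replicate``.
    gene_meta
        DataFrame indexed by gene id with a ``role`` column whose values are
        ``candidate_reference`` or ``target``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.index.copy())
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(
                {"role": ROLE_REFERENCE}, index=self.values.columns.copy()
            )

    # -- accessors -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def genes_with_role(self, role: str) -> list[str]:
        if "role" not in self.gene_meta.columns:
            return self.gene_ids if role == ROLE_REFERENCE else []
        return list(self.gene_meta.index[self.gene_meta["role"] == role])

    @property
    def reference_candidates(self) -> list[str]:
        return self.genes_with_role(ROLE_REFERENCE)

    @property
    def targets(self) -> list[str]:
        return self.genes_with_role(ROLE_TARGET)

    def subset_genes(self, genes: Iterable[str]) -> "CqTable":
        genes = list(genes)
        return CqTable(
            self.values[genes].copy(),
            self.sample_meta.copy(),
            self.gene_meta.loc[self.gene_meta.index.intersection(genes)].copy(),
        )

    # -- validation ----------------------------------------------------
    def validate(self, missing_policy: str = "strict") -> "CqTable":
        """Check invariants; return a (possibly reduced) valid table.

        ``missing_policy``: ``strict`` raises on any missing cell naming the
        sample and gene; ``drop-sample`` removes samples with missing cells.
        """
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")

        if v.isna().any().any():
            if missing_policy == "strict":
                s, g = next(
                    (s, g)
                    for s in v.index
                    for g in v.columns
                    if pd.isna(v.at[s, g])
                )
                raise ValidationError(
                    f"missing Cq for sample {s!r}, gene {g!r} "
                    "(missing-data policy is 'strict')"
                )
            elif missing_policy == "drop-sample":
                keep = ~v.isna().any(axis=1)
                dropped = v.index[~keep].tolist()
                logger.warning("dropping samples with missing Cq: %s", dropped)
                v = v.loc[keep]
            else:
                raise ValueError(f"unknown missing-data policy: {missing_policy!r}")

        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 samples and 2 genes, got {v.shape}"
            )
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite Cq values present")
        if (arr <= CQ_HARD_MIN).any() or (arr >= CQ_HARD_MAX).any():
            raise ValidationError(
                f"Cq values outside ({CQ_HARD_MIN}, {CQ_HARD_MAX}) cycles"
            )
        if (arr < CQ_SOFT_MIN).any() or (arr > CQ_SOFT_MAX).any():
            logger.warning(
                "Cq values outside the usual %g-%g cycle band", CQ_SOFT_MIN, CQ_SOFT_MAX
            )
        meta = self.sample_meta.loc[self.sample_meta.index.intersection(v.index)]
        return CqTable(v, meta, self.gene_meta)


@dataclass
class EfficiencyMap:
    """Per-gene amplification factor E (fold increase per PCR cycle)."""

    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        for gene, e in self.efficiencies.items():
            if not (EFFICIENCY_MIN < e <= EFFICIENCY_MAX):
                raise ValidationError(
                    f"efficiency for {gene!r} is {e}; must be in "
                    f"({EFFICIENCY_MIN}, {EFFICIENCY_MAX}]"
                )

    def __getitem__(self, gene: str) -> float:
        try:
            return self.efficiencies[gene]
        except KeyError:
            raise KeyError(f"no amplification efficiency for gene {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self.efficiencies

    @classmethod
    def constant(cls, genes: Iterable[str], e: float = 2.0) -> "EfficiencyMap":
        return cls({g: e for g in genes})


@dataclass
class GroupDesign:
    """Assignment of samples to subgroups (e.g. time points) for the
    model-based stability analysis."""

    groups: dict[str, str]  # sample_id -> group label

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    def validate(self, sample_ids: Iterable[str], min_group_size: int = 2) -> None:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without a group: {missing}")
        for label in self.labels:
            n = len(self.members(label))
            if n < min_group_size:
                raise ValidationError(
                    f"group {label!r} has {n} samples; need ≥ {min_group_size}"
                )

    @classmethod
    def from_sample_meta(cls, sample_meta: pd.DataFrame, column: str) -> "GroupDesign":
        if column not in sample_meta.columns:
            raise ValidationError(f"design column {column!r} not in sample metadata")
        return cls({s: str(v) for s, v in sample_meta[column].items()})


# ---------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------

_DESIGN_COLUMNS = ("condition", "time_h", "replicate")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cq_table(
    path: str | Path,
    layout: str = "wide",
    sample_column: str = "sample",
    gene_column: str = "gene",
    cq_column: str = "cq",
    average_technical_reps: bool = False,
    missing_policy: str = "strict",
    gene_roles: Mapping[str, str] | None = None,
) -> CqTable:
    """Read a delimited Cq table.

    Wide layout: one row per sample, one column per gene, plus optional
    design columns (``condition``, ``time_h``, ``replicate``). Long layout:
    columns (sample, gene, Cq) plus optional design columns. Duplicate
    (sample, gene) pairs in long layout are an error unless
    ``average_technical_reps`` is set, in which case their arithmetic mean
    is taken.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep)

    if layout == "wide":
        raw = raw.set_index(raw.columns[0])
        design_cols = [c for c in raw.columns if c in _DESIGN_COLUMNS]
        sample_meta = raw[design_cols].copy()
        values = raw.drop(columns=design_cols).astype(float)
    elif layout == "long":
        for col in (sample_column, gene_column, cq_column):
            if col not in raw.columns:
                raise ValidationError(f"long layout requires column {col!r}")
        dup = raw.duplicated(subset=[sample_column, gene_column])
        if dup.any() and not average_technical_reps:
            pair = raw.loc[dup.idxmax(), [sample_column, gene_column]].tolist()
            raise ValidationError(
                f"duplicate (sample, gene) pair {tuple(pair)}; pass "
                "average_technical_reps=True to average technical replicates"
            )
        design_cols = [c for c in raw.columns if c in _DESIGN_COLUMNS]
        if average_technical_reps:
            grouped = raw.groupby([sample_column, gene_column], sort=False)
            raw = grouped.agg(
                {cq_column: "mean", **{c: "first" for c in design_cols}}
            ).reset_index()
        values = raw.pivot(index=sample_column, columns=gene_column, values=cq_column)
        values.index.name = None
        values.columns.name = None
        sample_meta = (
            raw.drop_duplicates(subset=[sample_column])
            .set_index(sample_column)[design_cols]
            .copy()
        )
        sample_meta = sample_meta.reindex(values.index)
    else:
        raise ValueError(f"unknown layout: {layout!r}")

    roles = dict(gene_roles or {})
    gene_meta = pd.DataFrame(
        {"role": [roles.get(g, ROLE_REFERENCE) for g in values.columns]},
        index=values.columns.copy(),
    )
    return CqTable(values, sample_meta, gene_meta).validate(missing_policy)


def read_efficiencies(path: str | Path, gene_column: str = "gene",
                      e_column: str = "E") -> EfficiencyMap:
    """Read a per-gene efficiency table (columns: gene, E)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return EfficiencyMap(dict(zip(df[gene_column].astype(str), df[e_column].astype(float))))


def _to_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if hasattr(results, "to_frame"):
        return results.to_frame()
    if isinstance(results, pd.Series):
        return results.to_frame()
    raise TypeError(f"cannot serialise object of type {type(results).__name__}")


def write_report(
    results,
    path: str | Path,
    format: str = "tsv",
    precision: int | None = REPORT_PRECISION,
) -> Path:
    """Write a result table as TSV (human-readable, rounded) or JSON
    (machine-readable, full precision). Column order is preserved from the
    result object, so output is deterministic."""
    path = Path(path)
    df = _to_frame(results)
    if format == "tsv":
        out = df.copy()
        if precision is not None:
            fmt = f"{{:.{precision}f}}".format
            for col in out.columns:
                if pd.api.types.is_float_dtype(out[col]):
                    out[col] = out[col].map(
                        lambda x: "" if pd.isna(x) else fmt(x)
                    )
        out.to_csv(path, sep="\t", index=True)
    elif format == "json":
        payload = {
            "index": list(map(str, df.index)),
            "columns": list(map(str, df.columns)),
            "data": df.to_numpy().tolist(),
        }
        path.write_text(json.dumps(payload, indent=1, default=str))
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return path


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(
            payload["data"], index=payload["index"], columns=payload["columns"]
        )
    raise ValueError(f"unknown report format: {format!r}")
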