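"""Count normalization: control-gene log2 ratios, probe collapse, Tukey
median polish, replicate collapse, and median centering.

The pipeline converts QC-filtered probe counts to gene-level log2 expression
in five one-way stages:

1. add a pseudocount of 1 and take, per well, the log2 ratio of each probe to
   the geometric mean of the control-gene probes (Ascl3, Psmd4, Sdha, Tbp) —
   this absorbs library size, so the control-probe log ratios of every well
   average to exactly zero;
2. collapse probes to genes by median;
3. run a two-way Tukey median polish on the gene x sample table and keep the
   residuals plus the per-gene (row) effects, removing sample effects and the
   overall level while preserving gene-relative structure;
4. collapse replicate wells of each chemical@concentration@sex condition by
   median;
5. remove the sex markers (Xist, Ddx3y) and median-center each gene row.

Genes or conditions that lose every probe/well are dropped, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    SEX_MARKER_GENES,
    CountMatrix,
    PlateDesign,
    ProbePanel,
    ValidationError,
)

log = logging.getLogger(__name__)

STAGES = ("probe", "well", "condition", "centered")


@dataclass
class NormalizedMatrix:
    """Genes (or probes) x samples log2-scale expression with a stage tag."""

    values: pd.DataFrame
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            arr = self.values.to_numpy()
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at {self.values.index[r]!r}, "
                f"{self.values.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


def log_ratio_normalize(
    counts: CountMatrix, panel: ProbePanel, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Probe-level log2 ratios to the per-well control-probe geometric mean.

    value(probe, well) = log2(count + pc) - mean over control probes of
    log2(count + pc); the geometric mean is computed in log space for
    numerical stability. Requires at least one surviving probe for each of
    the four control genes.
    """
    gene_of = panel.probe_to_gene()
    control_probes = [
        p for p in counts.probes if gene_of.get(p) in set(panel.control_genes)
    ]
    missing = [
        g
        for g in panel.control_genes
        if not any(gene_of.get(p) == g for p in control_probes)
    ]
    if missing:
        raise ValidationError(f"control genes with no surviving probes: {missing}")
    logs = np.log2(counts.counts.to_numpy(dtype=float) + pseudocount)
    logs_df = pd.DataFrame(logs, index=counts.counts.index, columns=counts.counts.columns)
    geo = logs_df[control_probes].mean(axis=1)  # per-well log2 geometric mean
    ratios = logs_df.sub(geo, axis=0)
    # probes x wells orientation
    return NormalizedMatrix(ratios.T, stage="probe")


def collapse_probes(norm: NormalizedMatrix, panel: ProbePanel) -> NormalizedMatrix:
    """Collapse probe rows to one row per gene by median."""
    if norm.stage != "probe":
        raise ValidationError(f"expected probe-level matrix, got {norm.stage!r}")
    gene_of = panel.probe_to_gene()
    unmapped = [p for p in norm.values.index if p not in gene_of.index]
    if unmapped:
        raise ValidationError(f"probes absent from panel: {unmapped}")
    genes = norm.values.index.map(gene_of)
    collapsed = norm.values.groupby(genes).median()
    collapsed.index.name = "gene"
    lost = set(gene_of.unique()) - set(collapsed.index)
    if lost:
        log.info("genes with zero surviving probes: %s", sorted(lost))
    return NormalizedMatrix(collapsed, stage="well")


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    n_iter: int
    converged: bool


def median_polish_decompose(
    table: pd.DataFrame, tol: float = 1e-6, max_iter: int = 20
) -> MedianPolishResult:
    """Tukey's two-way median polish: table = overall + row + col + residual.

    Sweeps rows first, then columns, alternating (the classical ordering),
    until the largest absolute change in the residuals between sweeps falls
    below ``tol`` or ``max_iter`` full sweeps have run.
    """
    arr = table.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("median polish needs at least a 2 x 2 table")
    if not np.isfinite(arr).all():
        r, c = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"non-finite value at row {table.index[r]!r}, column {table.columns[c]!r}"
        )
    resid = arr.copy()
    row_eff = np.zeros(arr.shape[0])
    col_eff = np.zeros(arr.shape[1])
    overall = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prev = resid.copy()
        row_med = np.median(resid, axis=1)
        resid -= row_med[:, None]
        row_eff += row_med
        col_med_of_row = np.median(row_eff)
        overall += col_med_of_row
        row_eff -= col_med_of_row

        col_med = np.median(resid, axis=0)
        resid -= col_med[None, :]
        col_eff += col_med
        row_med_of_col = np.median(col_eff)
        overall += row_med_of_col
        col_eff -= row_med_of_col
        if np.max(np.abs(resid - prev)) < tol:
            converged = True
            break
    return MedianPolishResult(
        overall=overall,
        row_effects=pd.Series(row_eff, index=table.index),
        col_effects=pd.Series(col_eff, index=table.columns),
        residuals=pd.DataFrame(resid, index=table.index, columns=table.columns),
        n_iter=n_iter,
        converged=converged,
    )


def median_polish(
    norm: NormalizedMatrix,
    tol: float = 1e-6,
    max_iter: int = 20,
    output: str = "residual+row",
) -> NormalizedMatrix:
    """Polish the gene x sample table; keep residuals (+ row effects).

    The default ``residual+row`` output removes sample (column) effects and
    the overall level but retains each gene's own level, preserving
    gene-relative structure for display and correlation. ``residual``
    returns the bare residuals.
    """
    if output not in ("residual", "residual+row"):
        raise ValidationError(f"unknown polish output {output!r}")
    res = median_polish_decompose(norm.values, tol=tol, max_iter=max_iter)
    out = res.residuals
    if output == "residual+row":
        out = out.add(res.row_effects, axis=0)
    if not res.converged:
        log.warning("median polish did not converge in %d sweeps", res.n_iter)
    return NormalizedMatrix(out, stage=norm.stage)


def collapse_replicates(
    norm: NormalizedMatrix, design: PlateDesign
) -> NormalizedMatrix:
    """Collapse replicate wells by median into chemical@conc@sex conditions."""
    condition = design.condition_of()
    orphans = [c for c in norm.values.columns if c not in condition.index]
    if orphans:
        raise ValidationError(f"columns absent from the design: {orphans}")
    labels = norm.values.columns.map(condition)
    collapsed = norm.values.T.groupby(labels).median().T
    collapsed.columns.name = "condition"
    n_lost = condition.nunique() - collapsed.shape[1]
    if n_lost:
        log.info("%d conditions have no surviving wells", n_lost)
    return NormalizedMatrix(collapsed, stage="condition")


def drop_sex_markers(norm: NormalizedMatrix) -> NormalizedMatrix:
    present = [g for g in SEX_MARKER_GENES if g in norm.values.index]
    return NormalizedMatrix(norm.values.drop(index=present), stage=norm.stage)


def median_center(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Center each gene row at median 0 across conditions."""
    centered = norm.values.sub(norm.values.median(axis=1), axis=0)
    return NormalizedMatrix(centered, stage="centered")


def average_sexes(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Average the M/F condition columns into chemical@conc columns."""
    if norm.stage not in ("condition", "centered"):
        raise ValidationError("sex averaging needs a condition-level matrix")
    base = ["@".join(c.split("@")[:2]) for c in norm.values.columns]
    out = norm.values.T.groupby(pd.Index(base)).mean().T
    out.columns.name = "condition"
    return NormalizedMatrix(out, stage=norm.stage)


def normalize_pipeline(
    counts: CountMatrix,
    panel: ProbePanel,
    design: PlateDesign,
    pseudocount: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 20,
    polish_output: str = "residual+row",
) -> dict[str, NormalizedMatrix]:
    """Run all normalization stages; returns matrices keyed by stage."""
    probe_level = log_ratio_normalize(counts, panel, pseudocount=pseudocount)
    well_level = collapse_probes(probe_level, panel)
    polished = median_polish(well_level, tol=tol, max_iter=max_iter, output=polish_output)
    condition_level = collapse_replicates(polished, design)
    centered = median_center(drop_sex_markers(condition_level))
    return {
        "well": polished,
        "condition": condition_level,
        "centered": centered,
    }
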