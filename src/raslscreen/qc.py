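"""Read-count quality filters and the spike-in cell-health metric.

The screen's QC discards wells whose total read count does not exceed 500
and probes whose experiment-wide total does not exceed 1000 (both strict
inequalities). Luciferase spike-in probes are separated from the analysis
matrix before either filter runs and never enter normalization; the fraction
of a well's reads landing on spike probes serves as a cell-health proxy
(more spike reads means fewer cellular transcripts, i.e. lower viability).

Filter order is fixed: spikes are separated first, probe totals are computed
on the full unfiltered well set, then the well filter applies. Well totals
include spike reads (the filter addresses total amplification per well).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import CountMatrix, ProbePanel, ValidationError

MIN_WELL_READS = 500
MIN_PROBE_READS = 1000


@dataclass
class QcReport:
    """Per-well and per-probe accounting for one filtering pass."""

    well_table: pd.DataFrame  # total_reads, spike_reads, spike_fraction, passed
    probe_table: pd.DataFrame  # total_reads, passed
    n_wells_dropped: int
    n_probes_dropped: int

    def dropped_wells(self) -> list[str]:
        return self.well_table.index[~self.well_table["passed"]].tolist()

    def dropped_probes(self) -> list[str]:
        return self.probe_table.index[~self.probe_table["passed"]].tolist()


def separate_spikes(
    counts: CountMatrix, panel: ProbePanel
) -> tuple[CountMatrix, CountMatrix]:
    """Split the matrix into (cellular probes, spike probes)."""
    spikes = [p for p in counts.probes if p in set(panel.spike_probes)]
    cellular = [p for p in counts.probes if p not in set(spikes)]
    return (
        CountMatrix(counts.counts[cellular], provenance=counts.provenance),
        CountMatrix(counts.counts[spikes], provenance=counts.provenance),
    )


def luciferase_fraction(counts: CountMatrix, panel: ProbePanel) -> pd.Series:
    """Per-well fraction of reads on luciferase spike-in probes.

    Wells with zero total reads get NaN (0/0 is undefined, reported missing).
    """
    spike_probes = [p for p in counts.probes if p in set(panel.spike_probes)]
    if not panel.spike_probes:
        raise ValidationError("panel defines no spike probes")
    total = counts.counts.sum(axis=1)
    spike = counts.counts[spike_probes].sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = spike / total
    frac.name = "spike_fraction"
    return frac


def filter_wells(
    counts: CountMatrix,
    min_total: int = MIN_WELL_READS,
    strict: bool = True,
    spike_counts: Optional[CountMatrix] = None,
) -> tuple[CountMatrix, QcReport]:
    """Drop wells whose total reads do not exceed ``min_total``.

    ``spike_counts`` (the separated spike columns for the same wells), when
    given, is included in each well's total so the filter sees the full
    amplification of the well. ``strict`` selects > (default) vs >=.
    """
    if counts.shape[0] == 0:
        raise ValidationError("empty count matrix")
    total = counts.well_totals()
    if spike_counts is not None:
        total = total.add(spike_counts.well_totals(), fill_value=0)
    passed = total > min_total if strict else total >= min_total
    kept = CountMatrix(counts.counts.loc[passed], provenance=counts.provenance)
    well_table = pd.DataFrame({"total_reads": total, "passed": passed})
    report = QcReport(
        well_table=well_table,
        probe_table=pd.DataFrame(
            {"total_reads": counts.probe_totals(), "passed": True}
        ),
        n_wells_dropped=int((~passed).sum()),
        n_probes_dropped=0,
    )
    return kept, report


def filter_probes(
    counts: CountMatrix,
    panel: ProbePanel,
    min_total: int = MIN_PROBE_READS,
    strict: bool = True,
) -> tuple[CountMatrix, QcReport]:
    """Drop probes whose totals over all given wells do not exceed ``min_total``.

    Call on the full (well-unfiltered) matrix: probe totals are defined over
    the whole experiment. A control gene losing its last probe is a hard
    error, because normalization becomes impossible downstream.
    """
    if counts.shape[1] == 0:
        raise ValidationError("empty count matrix")
    total = counts.probe_totals()
    passed = total > min_total if strict else total >= min_total
    kept_probes = passed[passed].index.tolist()

    gene_of = panel.probe_to_gene()
    for gene in panel.control_genes:
        gene_probes = [p for p in counts.probes if gene_of.get(p) == gene]
        if gene_probes and not any(p in set(kept_probes) for p in gene_probes):
            raise ValidationError(
                f"control gene {gene!r} lost all probes in the probe filter; "
                "normalization impossible"
            )
    kept = CountMatrix(counts.counts[kept_probes], provenance=counts.provenance)
    report = QcReport(
        well_table=pd.DataFrame(
            {"total_reads": counts.well_totals(), "passed": True}
        ),
        probe_table=pd.DataFrame({"total_reads": total, "passed": passed}),
        n_wells_dropped=0,
        n_probes_dropped=int((~passed).sum()),
    )
    return kept, report


def run_qc(
    counts: CountMatrix,
    panel: ProbePanel,
    min_well_reads: int = MIN_WELL_READS,
    min_probe_reads: int = MIN_PROBE_READS,
    strict: bool = True,
) -> tuple[CountMatrix, QcReport]:
    """Full QC pass: separate spikes, filter probes, then filter wells.

    Returns the filtered cellular matrix plus a combined report whose well
    table carries spike reads and the spike fraction for every input well.
    """
    cellular, spikes = separate_spikes(counts, panel)
    probe_filtered, probe_report = filter_probes(
        cellular, panel, min_total=min_probe_reads, strict=strict
    )
    # the well filter judges the well's full amplification: its totals cover
    # every input probe (spikes and probe-filter casualties included)
    dropped = probe_report.dropped_probes()
    rest = CountMatrix(
        pd.concat([spikes.counts, cellular.counts[dropped]], axis=1),
        provenance=counts.provenance,
    )
    well_filtered, well_report = filter_wells(
        probe_filtered, min_total=min_well_reads, strict=strict, spike_counts=rest
    )
    spike_frac = luciferase_fraction(counts, panel)
    well_table = well_report.well_table.copy()
    well_table["spike_reads"] = spikes.well_totals()
    well_table["spike_fraction"] = spike_frac
    report = QcReport(
        well_table=well_table,
        probe_table=probe_report.probe_table,
        n_wells_dropped=well_report.n_wells_dropped,
        n_probes_dropped=probe_report.n_probes_dropped,
    )
    return well_filtered, report
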