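"""Readers and writers for the screen's plain-text artifacts.

All tables are UTF-8 TSV with a header row. Synthetic FASTQ uses standard
4-line records in which each read is laid out as
``fwd_barcode + junction_seq + rev_barcode``; demultiplexing is exact-match
only. That read layout is this package's own simulation dialect, not a claim
about the structure of reads from the real assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np
import pandas as pd

from .design import CountMatrix, PlateDesign, ProbePanel, ValidationError

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# count matrix


def read_count_matrix(path: PathLike, provenance: str = "loaded") -> CountMatrix:
    """Read a wells x probes TSV (first column well ids, header probe ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "well_id"
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    arr = counts.to_numpy()
    bad = ~(np.isfinite(arr) & (arr == np.floor(arr)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-integer cell at well {counts.index[r]!r}, probe {counts.columns[c]!r}"
        )
    return CountMatrix(counts.astype(np.int64), provenance=provenance)


def write_count_matrix(cm: CountMatrix, path: PathLike) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="well_id")


# ---------------------------------------------------------------------------
# plate map


def read_plate_map(path: PathLike) -> PlateDesign:
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "row": str, "sex": str})
    required = [
        "plate_id", "row", "col", "chemical_id", "concentration_uM",
        "sex", "replicate", "fwd_barcode", "rev_barcode",
    ]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"plate map missing columns: {sorted(missing)}")
    return PlateDesign.from_frame(df[required])


def write_plate_map(design: PlateDesign, path: PathLike) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe panel


def read_panel(path: PathLike) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ProbePanel(df)


def write_panel(panel: ProbePanel, path: PathLike) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ demultiplex/count


@dataclass
class DemuxResult:
    counts: CountMatrix
    n_assigned: int
    n_unassigned: int

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_unassigned


def _iter_fastq(handle: IO[str]) -> Iterator[str]:
    """Yield read sequences from a 4-line-record FASTQ stream."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline()
        if not qual:
            raise ValidationError("truncated FASTQ record")
        yield seq


def count_fastq(
    reads: Union[PathLike, IO[str], Iterable[str]],
    design: PlateDesign,
    panel: ProbePanel,
) -> DemuxResult:
    """Demultiplex synthetic reads into a well x probe CountMatrix.

    Reads whose barcode pair or junction match nothing in the design/panel
    are tallied as unassigned; assigned + unassigned always equals the input
    read count.
    """
    if not panel.has_junctions:
        raise ValidationError(
            "panel has no junction sequences; FASTQ counting unsupported"
        )
    junctions = panel.junction_to_probe()
    jlen = len(next(iter(junctions)))
    if any(len(j) != jlen for j in junctions):
        raise ValidationError("junction sequences must share a common length")
    barcodes = design.barcode_index()
    fwd_len = len(next(iter(barcodes))[0])
    rev_len = len(next(iter(barcodes))[1])

    well_ids = [w.well_id for w in design.wells]
    probe_ids = panel.probe_ids
    well_pos = {w: i for i, w in enumerate(well_ids)}
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    mat = np.zeros((len(well_ids), len(probe_ids)), dtype=np.int64)

    close_after = False
    if isinstance(reads, (str, Path)):
        handle: IO[str] = open(reads, "rt", encoding="utf-8")
        close_after = True
        seq_iter: Iterable[str] = _iter_fastq(handle)
    elif hasattr(reads, "readline"):
        seq_iter = _iter_fastq(reads)  # type: ignore[arg-type]
    else:
        seq_iter = reads

    n_assigned = n_unassigned = 0
    try:
        for seq in seq_iter:
            if len(seq) != fwd_len + jlen + rev_len:
                n_unassigned += 1
                continue
            fwd = seq[:fwd_len]
            junction = seq[fwd_len : fwd_len + jlen]
            rev = seq[fwd_len + jlen :]
            well = barcodes.get((fwd, rev))
            probe = junctions.get(junction)
            if well is None or probe is None:
                n_unassigned += 1
                continue
            mat[well_pos[well], probe_pos[probe]] += 1
            n_assigned += 1
    finally:
        if close_after:
            handle.close()

    counts = pd.DataFrame(mat, index=pd.Index(well_ids, name="well_id"), columns=probe_ids)
    return DemuxResult(
        counts=CountMatrix(counts, provenance="demultiplexed"),
        n_assigned=n_assigned,
        n_unassigned=n_unassigned,
    )


def write_fastq(records: Iterable[tuple[str, str]], path: PathLike) -> int:
    """Write (read_id, sequence) pairs as FASTQ; returns the record count."""
    n = 0
    with open(path, "wt", encoding="utf-8") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
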