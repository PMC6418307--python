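"""Core data model for a RASL-seq screen.

A screen is described by three objects: a :class:`ProbePanel` mapping every
ligation probe to a gene symbol and a functional role, a :class:`PlateDesign`
recording which chemical/concentration/sex/replicate sits in every barcoded
well, and a :class:`CountMatrix` of raw reads per (well, probe).

Well identifiers follow the canonical ``"{plate_id}:{row}{col}"`` convention
(e.g. ``"P01:A1"``); every module joins tables on that string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

PLATE_ROWS_384 = [chr(ord("A") + i) for i in range(16)]  # A..P
PLATE_COLS_384 = list(range(1, 25))

#: probe roles
ROLE_TARGET = "target"
ROLE_CONTROL = "control"
ROLE_SPIKE = "spike"
ROLE_SEX_MARKER = "sex_marker"
VALID_ROLES = {ROLE_TARGET, ROLE_CONTROL, ROLE_SPIKE, ROLE_SEX_MARKER}

#: the four housekeeping genes whose geometric mean sets the per-well scale
CONTROL_GENES = ("Ascl3", "Psmd4", "Sdha", "Tbp")
#: X/Y marker genes used to confirm the sex of each culture
SEX_MARKER_GENES = ("Xist", "Ddx3y")
#: exogenous spike-in; its read fraction proxies cell health
SPIKE_GENE = "Luciferase"

VEHICLE = "VEHICLE"


class ValidationError(ValueError):
    """An input table violates a structural invariant of the screen."""


def well_id(plate_id: str, row: str, col: int) -> str:
    return f"{plate_id}:{row}{col}"


@dataclass(frozen=True)
class ProbePanel:
    """Probe → gene/role annotation for the targeted panel.

    ``table`` has columns ``probe_id, gene, role`` and optionally
    ``junction_seq`` (the ligated junction sequence used when demultiplexing
    synthetic FASTQ).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "gene", "role"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"panel missing columns: {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        bad_roles = set(t["role"]) - VALID_ROLES
        if bad_roles:
            raise ValidationError(f"unknown probe roles: {sorted(bad_roles)}")
        # one gene per probe is structural (long format); check gene/role coherence
        role_per_gene = t.groupby("gene")["role"].nunique()
        if (role_per_gene > 1).any():
            genes = role_per_gene[role_per_gene > 1].index.tolist()
            raise ValidationError(f"genes with conflicting roles: {genes}")
        if "junction_seq" in t.columns:
            seqs = t["junction_seq"].dropna()
            if seqs.duplicated().any():
                raise ValidationError("duplicate junction sequences in panel")

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].unique().tolist()

    def probe_to_gene(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene"]

    def probes_with_role(self, role: str) -> list[str]:
        return self.table.loc[self.table["role"] == role, "probe_id"].tolist()

    @property
    def spike_probes(self) -> list[str]:
        return self.probes_with_role(ROLE_SPIKE)

    @property
    def control_genes(self) -> list[str]:
        return self.table.loc[self.table["role"] == ROLE_CONTROL, "gene"].unique().tolist()

    @property
    def has_junctions(self) -> bool:
        return "junction_seq" in self.table.columns and self.table["junction_seq"].notna().all()

    def junction_to_probe(self) -> Mapping[str, str]:
        if not self.has_junctions:
            raise ValidationError("panel carries no junction sequences")
        return dict(zip(self.table["junction_seq"], self.table["probe_id"]))


@dataclass(frozen=True)
class WellRecord:
    """One well of the screen: position, treatment, and its barcode pair."""

    plate_id: str
    row: str
    col: int
    chemical_id: str
    concentration_uM: float
    sex: str
    replicate: int
    fwd_barcode: str
    rev_barcode: str

    def __post_init__(self) -> None:
        if self.row not in PLATE_ROWS_384:
            raise ValidationError(f"row {self.row!r} outside A-P in plate {self.plate_id}")
        if not (1 <= self.col <= 24):
            raise ValidationError(f"col {self.col} outside 1-24 in plate {self.plate_id}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")
        if self.chemical_id == VEHICLE and self.concentration_uM != 0:
            raise ValidationError(
                f"vehicle well {self.well_id} must have concentration 0, "
                f"got {self.concentration_uM}"
            )
        if self.chemical_id != VEHICLE and self.concentration_uM <= 0:
            raise ValidationError(
                f"treated well {self.well_id} needs a positive concentration"
            )

    @property
    def well_id(self) -> str:
        return well_id(self.plate_id, self.row, self.col)

    @property
    def condition(self) -> str:
        """``chemical@conc_uM@sex`` condition label (replicates collapse onto it)."""
        return f"{self.chemical_id}@{self.concentration_uM:g}@{self.sex}"


@dataclass
class PlateDesign:
    """The well-level experimental design of a whole screen."""

    wells: list[WellRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_bc: dict[tuple[str, str], str] = {}
        seen_id: set[str] = set()
        per_plate: dict[str, int] = {}
        for w in self.wells:
            pair = (w.fwd_barcode, w.rev_barcode)
            if pair in seen_bc:
                raise ValidationError(
                    f"barcode pair {pair} shared by wells {seen_bc[pair]} and {w.well_id}"
                )
            seen_bc[pair] = w.well_id
            if w.well_id in seen_id:
                raise ValidationError(f"duplicate well id {w.well_id}")
            seen_id.add(w.well_id)
            per_plate[w.plate_id] = per_plate.get(w.plate_id, 0) + 1
        over = {p: n for p, n in per_plate.items() if n > 384}
        if over:
            raise ValidationError(f"plates over 384 wells: {over}")

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def n_plates(self) -> int:
        return len({w.plate_id for w in self.wells})

    @property
    def n_replicates(self) -> int:
        return len({w.replicate for w in self.wells})

    @property
    def sexes(self) -> set[str]:
        return {w.sex for w in self.wells}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": w.plate_id,
                "row": w.row,
                "col": w.col,
                "chemical_id": w.chemical_id,
                "concentration_uM": w.concentration_uM,
                "sex": w.sex,
                "replicate": w.replicate,
                "fwd_barcode": w.fwd_barcode,
                "rev_barcode": w.rev_barcode,
            }
            for w in self.wells
        ]
        df = pd.DataFrame(rows)
        df.index = pd.Index([w.well_id for w in self.wells], name="well_id")
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateDesign":
        wells = [
            WellRecord(
                plate_id=str(r.plate_id),
                row=str(r.row),
                col=int(r.col),
                chemical_id=str(r.chemical_id),
                concentration_uM=float(r.concentration_uM),
                sex=str(r.sex),
                replicate=int(r.replicate),
                fwd_barcode=str(r.fwd_barcode),
                rev_barcode=str(r.rev_barcode),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(wells)

    def condition_of(self) -> pd.Series:
        """well_id → ``chemical@conc@sex`` condition label."""
        return pd.Series(
            {w.well_id: w.condition for w in self.wells}, name="condition"
        )

    def barcode_index(self) -> Mapping[tuple[str, str], str]:
        return {(w.fwd_barcode, w.rev_barcode): w.well_id for w in self.wells}


@dataclass
class CountMatrix:
    """Wells x probes matrix of nonnegative integer read counts."""

    counts: pd.DataFrame
    provenance: str = "loaded"

    def __post_init__(self) -> None:
        c = self.counts
        c.index.name = "well_id"
        c.columns.name = None
        if c.index.duplicated().any():
            raise ValidationError(
                f"duplicate well ids: {c.index[c.index.duplicated()].tolist()}"
            )
        if c.columns.duplicated().any():
            raise ValidationError(
                f"duplicate probe ids: {c.columns[c.columns.duplicated()].tolist()}"
            )
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                bad = np.argwhere(~(np.isfinite(arr) & (arr == np.floor(arr))))
                r, col = bad[0]
                raise ValidationError(
                    f"non-integer count at well {c.index[r]!r}, probe {c.columns[col]!r}"
                )
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)
            r, col = bad[0]
            raise ValidationError(
                f"negative count at well {c.index[r]!r}, probe {c.columns[col]!r}"
            )

    @property
    def wells(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def probes(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def well_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def probe_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def check_against_panel(self, panel: ProbePanel) -> None:
        unknown = set(self.probes) - set(panel.probe_ids)
        if unknown:
            raise ValidationError(f"probes absent from panel: {sorted(unknown)}")
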