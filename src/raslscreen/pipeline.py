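"""End-to-end orchestration: simulate -> qc -> normalize -> classify.

A :class:`RunConfig` carries every tunable with its screening default; the
runner executes the stages in order, writes all artifacts as TSV/Newick, and
emits a manifest with SHA-256 checksums so reruns can be verified
byte-for-byte. All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import io as rio
from .classify import (
    CORRELATION_THRESHOLD,
    SignatureSet,
    assign_clusters,
    correlate_to_signatures,
    hierarchical_cluster,
    infer_sex,
)
from .design import ValidationError
from .normalize import average_sexes, normalize_pipeline
from .panel import default_panel, load_templates
from .qc import run_qc
from .simulate import (
    SimulationConfig,
    assign_templates,
    build_profiles,
    default_chemicals,
    make_design,
    simulate_counts,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables, at their screening defaults."""

    outdir: str = "rasl_out"
    seed: int = 0
    simulate: bool = False
    counts_path: Optional[str] = None
    plate_map_path: Optional[str] = None
    panel_path: Optional[str] = None
    signatures_path: Optional[str] = None
    # simulation scale
    n_chemicals: int = 360
    n_replicates: int = 3
    n_per_template: int = 6
    # QC
    min_well_reads: int = 500
    min_probe_reads: int = 1000
    strict_filters: bool = True
    # normalization
    pseudocount: float = 1.0
    polish_tol: float = 1e-6
    polish_max_iter: int = 20
    polish_output: str = "residual+row"
    # classification
    correlation_threshold: float = CORRELATION_THRESHOLD
    average_sexes: bool = True
    linkage_method: str = "average"
    version: str = "raslscreen-0.1.0"

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns {artifact name: sha256}.

    With ``config.simulate`` a synthetic screen is generated at the
    configured scale; otherwise counts/plate map/panel are loaded from the
    configured paths. The manifest (and its checksums) is also written to
    ``outdir/manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        panel = default_panel()
        chemicals = default_chemicals(config.n_chemicals)
        design = make_design(
            chemicals, n_replicates=config.n_replicates, seed=config.seed
        )
        labels = assign_templates(
            chemicals, n_per_template=config.n_per_template, seed=config.seed
        )
        profiles = build_profiles(labels, seed=config.seed)
        counts, truth = simulate_counts(
            design, panel, profiles, SimulationConfig(seed=config.seed)
        )
        rio.write_panel(panel, out / "panel.tsv")
        rio.write_plate_map(design, out / "plate_map.tsv")
        rio.write_count_matrix(counts, out / "counts.tsv")
        truth.chemicals.to_csv(out / "truth_chemicals.tsv", sep="\t")
        truth.wells.to_csv(out / "truth_wells.tsv", sep="\t")
    else:
        if not (config.counts_path and config.plate_map_path and config.panel_path):
            raise ValidationError(
                "need counts, plate map and panel paths (or simulate=True)"
            )
        panel = rio.read_panel(config.panel_path)
        design = rio.read_plate_map(config.plate_map_path)
        counts = rio.read_count_matrix(config.counts_path)

    filtered, qc_report = run_qc(
        counts,
        panel,
        min_well_reads=config.min_well_reads,
        min_probe_reads=config.min_probe_reads,
        strict=config.strict_filters,
    )
    log.info(
        "QC: dropped %d wells and %d probes",
        qc_report.n_wells_dropped,
        qc_report.n_probes_dropped,
    )
    qc_report.well_table.to_csv(out / "qc_wells.tsv", sep="\t")
    qc_report.probe_table.to_csv(out / "qc_probes.tsv", sep="\t")
    rio.write_count_matrix(filtered, out / "counts_filtered.tsv")

    stages = normalize_pipeline(
        filtered,
        panel,
        design,
        pseudocount=config.pseudocount,
        tol=config.polish_tol,
        max_iter=config.polish_max_iter,
        polish_output=config.polish_output,
    )
    for name in ("well", "condition", "centered"):
        stages[name].values.to_csv(out / f"normalized_{name}.tsv", sep="\t")

    sex_calls = infer_sex(stages["condition"])
    sex_calls.to_csv(out / "sex_calls.tsv", sep="\t")

    centered = stages["centered"]
    if config.average_sexes:
        centered = average_sexes(centered)

    if config.signatures_path:
        import pandas as pd

        sig_df = pd.read_csv(config.signatures_path, sep="\t", index_col=0)
        signatures = SignatureSet(sig_df, provenance="user-supplied")
    else:
        signatures = SignatureSet(
            load_templates().drop(columns=["null"]), provenance="packaged fixture"
        )
    corr = correlate_to_signatures(centered, signatures)
    corr.to_csv(out / "correlations.tsv", sep="\t")
    result = assign_clusters(corr, threshold=config.correlation_threshold)
    result.to_frame().to_csv(out / "classification.tsv", sep="\t")

    tree = hierarchical_cluster(centered, method=config.linkage_method)
    (out / "clustering.nwk").write_text(tree.to_newick() + "\n")
    centered.values[tree.leaf_order].to_csv(out / "heatmap_matrix.tsv", sep="\t")

    config.to_yaml(out / "run_config.yaml")
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
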