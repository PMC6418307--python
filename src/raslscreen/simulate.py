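"""Synthetic RASL-seq screen generator.

Generates plate designs and overdispersed probe-level count matrices with the
statistical structure the analysis pipeline assumes, together with the ground
truth needed to score recovery:

* library size per well is log-normal; probe counts are negative-binomial
  around the well's expected partition of reads (a gamma-Poisson mixture with
  a shared dispersion, the simplest overdispersed model for targeted
  sequencing counts);
* a chemical's effect is a per-gene log2 fold-change profile scaled by a dose
  activity (``flat``, ``threshold`` at the top concentration, or ``monotone``
  in log-concentration), applied at the gene level and partitioned equally
  across the gene's probes (the pipeline collapses probes by median, so probe
  heterogeneity is nuisance);
* the luciferase spike-in competes with cellular transcripts for the well's
  fixed read budget, so lower viability (toxic chemicals at active doses)
  yields a higher spike read fraction — mirroring the use of spike fraction
  as a cell-health proxy;
* Xist is elevated in female wells and Ddx3y in male wells by a configurable
  log2 separation;
* sporadic well failure collapses a well's library size; sporadic probe
  failure zeroes a probe everywhere.

Identical (seed, inputs) reproduce identical outputs; all randomness flows
from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    CONTROL_GENES,
    ROLE_SPIKE,
    VEHICLE,
    CountMatrix,
    PlateDesign,
    ProbePanel,
    ValidationError,
    WellRecord,
)
from .panel import barcode_seq, load_templates

CONCENTRATIONS_UM = (0.01, 0.1, 1.0, 10.0)
DOSE_MODELS = ("flat", "threshold", "monotone")

# hallmark chemicals with known cluster membership and dose behaviour
HALLMARK_CHEMICALS: dict[str, tuple[str, str]] = {
    # chemical -> (template label, dose model)
    "pyraclostrobin": ("C2", "flat"),
    "trifloxystrobin": ("C2", "flat"),
    "kresoxim-methyl": ("C2", "flat"),
    "azoxystrobin": ("C2", "threshold"),
    "fenamidone": ("C2", "flat"),
    "fenpyroximate": ("C2", "flat"),
    "rotenone": ("C2", "flat"),
    "bifenthrin": ("C1", "threshold"),
    "fenpropathrin": ("C1", "flat"),
    "esfenvalerate": ("C1", "threshold"),
    "NMDA": ("C1", "flat"),
    "topotecan": ("C5", "flat"),
    "JQ1": ("novel", "flat"),
}


class SizingError(ValueError):
    """The requested conditions do not fit the available plate budget."""


# ---------------------------------------------------------------------------
# design generation


def default_chemicals(n: int = 360) -> list[str]:
    """Chemical id list for a paper-scale screen (hallmarks + filler ids)."""
    names = list(HALLMARK_CHEMICALS)
    fillers = [f"chem{i:03d}" for i in range(1, max(0, n - len(names)) + 1)]
    return (names + fillers)[:n]


def make_design(
    chemicals: Sequence[str],
    n_replicates: int = 3,
    sexes: Sequence[str] = ("M", "F"),
    concentrations: Sequence[float] = CONCENTRATIONS_UM,
    plate_size: int = 384,
    vehicle_per_plate: int = 24,
    max_plates: Optional[int] = None,
    seed: int = 0,
) -> PlateDesign:
    """Lay out a full screen on uniquely barcoded plates.

    Every (chemical, concentration) is placed once per sex per replicate;
    vehicle wells are interspersed at evenly spaced positions on every plate.
    Forward barcodes index plates and reverse barcodes index well positions,
    which makes every (fwd, rev) pair unique across the experiment.
    """
    if plate_size not in (96, 384):
        raise ValidationError(f"plate_size must be 96 or 384, got {plate_size}")
    if not concentrations:
        raise ValidationError("need at least one concentration")
    n_rows, n_cols = (16, 24) if plate_size == 384 else (8, 12)
    rows = [chr(ord("A") + i) for i in range(n_rows)]

    conditions = [(c, conc) for c in chemicals for conc in concentrations]
    capacity = plate_size - vehicle_per_plate
    if capacity <= 0:
        raise ValidationError("vehicle_per_plate leaves no treated capacity")
    plates_per_group = math.ceil(len(conditions) / capacity)
    total_plates = plates_per_group * len(sexes) * n_replicates
    if max_plates is not None and total_plates > max_plates:
        raise SizingError(
            f"design needs {total_plates} plates "
            f"({plates_per_group} per sex per replicate) but only "
            f"{max_plates} allowed"
        )

    # evenly spaced vehicle positions, identical on every plate
    vehicle_pos = {i * plate_size // vehicle_per_plate for i in range(vehicle_per_plate)}
    rng = np.random.default_rng(seed)

    wells: list[WellRecord] = []
    plate_counter = 0
    for rep in range(1, n_replicates + 1):
        for sex in sexes:
            order = rng.permutation(len(conditions))
            queue: Iterator[tuple[str, float]] = iter(
                [conditions[i] for i in order]
            )
            for p in range(plates_per_group):
                plate_id = f"R{rep}{sex}P{p + 1:02d}"
                fwd = barcode_seq(plate_counter)
                plate_counter += 1
                for pos in range(plate_size):
                    row = rows[pos // n_cols]
                    col = pos % n_cols + 1
                    rev = barcode_seq(4096 + pos)
                    if pos in vehicle_pos:
                        chem, conc = VEHICLE, 0.0
                    else:
                        try:
                            chem, conc = next(queue)
                        except StopIteration:
                            chem, conc = VEHICLE, 0.0
                    wells.append(
                        WellRecord(
                            plate_id=plate_id,
                            row=row,
                            col=col,
                            chemical_id=chem,
                            concentration_uM=conc,
                            sex=sex,
                            replicate=rep,
                            fwd_barcode=fwd,
                            rev_barcode=rev,
                        )
                    )
    return PlateDesign(wells)


# ---------------------------------------------------------------------------
# effect profiles


@dataclass
class EffectProfile:
    """A chemical's transcriptional effect at the reference (top) dose.

    ``log2fc`` maps gene symbols to log2 fold-changes applied at full dose
    activity. ``sex_mult`` multiplies the fold-change in female wells (male
    wells use 1.0). ``toxicity`` in [0, 1] scales viability loss at full
    activity. Control genes and the spike gene must carry no effect: they
    define the normalization scale.
    """

    chemical_id: str
    log2fc: dict[str, float] = field(default_factory=dict)
    dose_model: str = "flat"
    sex_mult: dict[str, float] = field(default_factory=dict)
    toxicity: float = 0.0
    template: str = "custom"

    def __post_init__(self) -> None:
        if self.dose_model not in DOSE_MODELS:
            raise ValidationError(f"unknown dose model {self.dose_model!r}")
        if not 0.0 <= self.toxicity <= 1.0:
            raise ValidationError("toxicity must lie in [0, 1]")
        forbidden = [
            g for g in self.log2fc
            if g in CONTROL_GENES and self.log2fc[g] != 0.0
        ]
        if forbidden:
            raise ValidationError(
                f"profile {self.chemical_id!r} perturbs control genes {forbidden}"
            )
        if self.chemical_id == VEHICLE and any(v != 0 for v in self.log2fc.values()):
            raise ValidationError("vehicle profile must be identically zero")

    def activity(self, concentration_uM: float, top: float = 10.0) -> float:
        """Dose activity in [0, 1] at a given concentration."""
        if concentration_uM <= 0:
            return 0.0
        if self.dose_model == "flat":
            return 1.0
        if self.dose_model == "threshold":
            return 1.0 if concentration_uM >= top else 0.0
        # monotone: log-linear from 4 decades below the top concentration,
        # so the lowest screened dose (top/1000) retains quarter activity
        lo, hi = math.log10(top) - 4.0, math.log10(top)
        return float(np.clip((math.log10(concentration_uM) - lo) / (hi - lo), 0.0, 1.0))


def vehicle_profile() -> EffectProfile:
    return EffectProfile(chemical_id=VEHICLE, template="null")


def assign_templates(
    chemicals: Sequence[str],
    n_per_template: int = 6,
    templates: Sequence[str] = ("C1", "C2", "C5", "novel"),
    seed: int = 0,
) -> dict[str, str]:
    """Assign template labels to chemicals; hallmarks keep their known label.

    Non-hallmark chemicals are drawn without replacement to fill each listed
    template up to ``n_per_template`` members; the rest are ``null``.
    """
    labels = {c: "null" for c in chemicals}
    counts = {t: 0 for t in templates}
    for chem in chemicals:
        if chem in HALLMARK_CHEMICALS:
            label = HALLMARK_CHEMICALS[chem][0]
            if label in counts:
                labels[chem] = label
                counts[label] += 1
    rng = np.random.default_rng(seed)
    pool = [c for c in chemicals if c not in HALLMARK_CHEMICALS]
    pool = list(rng.permutation(pool))
    for t in templates:
        while counts[t] < n_per_template and pool:
            labels[pool.pop()] = t
            counts[t] += 1
    return labels


def build_profiles(
    labels: Mapping[str, str],
    templates: Optional[pd.DataFrame] = None,
    amplitude: float = 1.0,
    seed: int = 0,
    dose_model_probs: Mapping[str, float] = {"flat": 0.5, "threshold": 0.25, "monotone": 0.25},
    toxicity_by_template: Optional[Mapping[str, float]] = None,
) -> dict[str, EffectProfile]:
    """Materialize EffectProfiles from template labels.

    Hallmark chemicals get their documented dose behaviour; other
    effect-bearing chemicals draw a dose model at random. ``null`` chemicals
    are inert. ``toxicity_by_template`` defaults to moderate toxicity for
    effect-bearing templates (0.5) and none for null.
    """
    if templates is None:
        templates = load_templates()
    rng = np.random.default_rng(seed)
    models = list(dose_model_probs)
    probs = np.array([dose_model_probs[m] for m in models], dtype=float)
    probs /= probs.sum()
    profiles: dict[str, EffectProfile] = {VEHICLE: vehicle_profile()}
    for chem in labels:
        label = labels[chem]
        if label == "null":
            profiles[chem] = EffectProfile(chemical_id=chem, template="null")
            continue
        if label not in templates.columns:
            raise ValidationError(f"no template column {label!r} for {chem!r}")
        if chem in HALLMARK_CHEMICALS:
            model = HALLMARK_CHEMICALS[chem][1]
        else:
            model = str(rng.choice(models, p=probs))
        tox = 0.5 if toxicity_by_template is None else toxicity_by_template.get(label, 0.0)
        fc = templates[label] * amplitude
        profiles[chem] = EffectProfile(
            chemical_id=chem,
            log2fc={g: float(v) for g, v in fc.items() if v != 0.0},
            dose_model=model,
            toxicity=tox,
            template=label,
        )
    return profiles


# ---------------------------------------------------------------------------
# count simulation


@dataclass
class SimulationConfig:
    """Tunable knobs of the count model. ``seed`` is mandatory: there is no
    implicit randomness anywhere in the generator."""

    seed: int
    library_meanlog: float = math.log(30_000.0)  # ~30k reads/well
    library_sdlog: float = 0.4
    dispersion: float = 10.0  # NB size; var = m + m^2/size
    spike_fraction: float = 0.05  # spike read share at full viability, no effect
    toxicity_coupling: float = 1.0  # exponent linking viability to cellular mass
    well_failure_prob: float = 0.002
    probe_failure_prob: float = 0.004
    well_failure_scale: float = 1e-3  # library-size multiplier for failed wells
    sex_effect_log2: float = 4.0  # Xist - Ddx3y log2 separation
    baseline_sigma: float = 0.8  # log-sd of per-gene baseline weights
    min_viability: float = 0.05

    def __post_init__(self) -> None:
        for name in ("spike_fraction", "well_failure_prob", "probe_failure_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring recovery downstream."""

    chemicals: pd.DataFrame  # index chemical_id; template, dose_model, toxicity
    wells: pd.DataFrame  # index well_id; sex, viability, failed
    failed_probes: list[str]


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and NB size parameter ``size``."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(
    design: PlateDesign,
    panel: ProbePanel,
    profiles: Mapping[str, EffectProfile],
    config: SimulationConfig,
    baselines: Optional[Mapping[str, float]] = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Draw a probe-level count matrix for a designed screen.

    Per well: library size L ~ LogNormal; each gene's cellular mass is its
    baseline weight times 2^effect, split equally over the gene's probes; the
    spike competes with viability-weighted cellular mass for the read budget;
    counts are negative binomial around the expected partition of L.
    """
    missing = {w.chemical_id for w in design.wells} - set(profiles)
    if missing:
        raise ValidationError(f"no effect profile for chemicals: {sorted(missing)}")

    ptab = panel.table
    spike_mask = (ptab["role"] == ROLE_SPIKE).to_numpy()
    probe_ids = ptab["probe_id"].to_numpy()
    probe_genes = ptab["gene"].to_numpy()
    cell_genes = pd.unique(probe_genes[~spike_mask])
    n_probes = len(probe_ids)

    rng = np.random.default_rng(config.seed)

    # per-gene baseline weights (relative expression); controls must be > 0
    if baselines is None:
        weights = pd.Series(
            np.exp(rng.normal(0.0, config.baseline_sigma, size=len(cell_genes))),
            index=cell_genes,
        )
    else:
        weights = pd.Series({g: float(baselines[g]) for g in cell_genes})
    for g in panel.control_genes:
        if g not in weights.index or weights[g] <= 0:
            raise ValidationError(f"control gene {g!r} has zero baseline mean")

    probes_per_gene = pd.Series(probe_genes[~spike_mask]).value_counts()
    # per-probe baseline mass (equal split within gene)
    base_mass = np.zeros(n_probes)
    cell_idx = np.where(~spike_mask)[0]
    for i in cell_idx:
        g = probe_genes[i]
        base_mass[i] = weights[g] / probes_per_gene[g]
    n_spike = int(spike_mask.sum())
    if n_spike == 0:
        raise ValidationError("panel has no spike probes")

    total_base = base_mass.sum()
    # spike input chosen so that with no effect and full viability the
    # expected spike read share equals config.spike_fraction
    spike_input = config.spike_fraction / (1.0 - config.spike_fraction) * total_base

    wells = design.wells
    n_wells = len(wells)
    well_ids = [w.well_id for w in wells]

    lib = np.exp(rng.normal(config.library_meanlog, config.library_sdlog, n_wells))
    well_failed = rng.random(n_wells) < config.well_failure_prob
    lib[well_failed] *= config.well_failure_scale
    probe_failed = rng.random(n_probes) < config.probe_failure_prob

    # group wells by (chemical, conc, sex) to build each expected profile once
    group_key = [(w.chemical_id, w.concentration_uM, w.sex) for w in wells]
    mean_mat = np.zeros((n_wells, n_probes))
    viability = np.ones(n_wells)
    xist_idx = probe_genes == "Xist"
    ddx3y_idx = probe_genes == "Ddx3y"
    cache: dict[tuple[str, float, str], tuple[np.ndarray, float]] = {}
    half_sex = config.sex_effect_log2 / 2.0
    for wi, key in enumerate(group_key):
        if key not in cache:
            chem, conc, sex = key
            prof = profiles[chem]
            act = prof.activity(conc)
            effect = np.zeros(n_probes)
            for gene, fc in prof.log2fc.items():
                mult = prof.sex_mult.get(gene, 1.0) if sex == "F" else 1.0
                effect[probe_genes == gene] = fc * act * mult
            sign = 1.0 if sex == "F" else -1.0
            effect[xist_idx] += sign * half_sex
            effect[ddx3y_idx] -= sign * half_sex
            mass = base_mass * np.exp2(effect)
            mass[spike_mask] = 0.0
            v = max(config.min_viability, 1.0 - prof.toxicity * act)
            cell_mass = mass.sum() * v**config.toxicity_coupling
            f_spike = spike_input / (spike_input + cell_mass)
            expected = np.empty(n_probes)
            expected[~spike_mask] = (1.0 - f_spike) * mass[~spike_mask] / mass.sum()
            expected[spike_mask] = f_spike / n_spike
            cache[key] = (expected, v)
        expected, v = cache[key]
        mean_mat[wi] = expected * lib[wi]
        viability[wi] = v

    counts = _nb_draws(rng, mean_mat, config.dispersion)
    counts[:, probe_failed] = 0

    cm = CountMatrix(
        pd.DataFrame(
            counts, index=pd.Index(well_ids, name="well_id"), columns=probe_ids
        ),
        provenance="simulated",
    )
    chem_rows = {
        c: {
            "template": profiles[c].template,
            "dose_model": profiles[c].dose_model,
            "toxicity": profiles[c].toxicity,
        }
        for c in sorted({w.chemical_id for w in wells})
    }
    truth = GroundTruth(
        chemicals=pd.DataFrame.from_dict(chem_rows, orient="index").rename_axis(
            "chemical_id"
        ),
        wells=pd.DataFrame(
            {
                "sex": [w.sex for w in wells],
                "viability": viability,
                "failed": well_failed,
            },
            index=pd.Index(well_ids, name="well_id"),
        ),
        failed_probes=[probe_ids[i] for i in np.where(probe_failed)[0]],
    )
    return cm, truth


# ---------------------------------------------------------------------------
# FASTQ emission


def simulate_fastq(
    counts: CountMatrix,
    design: PlateDesign,
    panel: ProbePanel,
    seed: int = 0,
) -> Iterator[tuple[str, str]]:
    """Emit one synthetic read per count, shuffled, as (read_id, sequence).

    Reads follow the exact-match dialect ``fwd + junction + rev`` so that
    :func:`raslscreen.io.count_fastq` inverts this function exactly.
    """
    if not panel.has_junctions:
        raise ValidationError("panel has no junction sequences")
    junction_of = dict(zip(panel.table["probe_id"], panel.table["junction_seq"]))
    bc_of = {w.well_id: (w.fwd_barcode, w.rev_barcode) for w in design.wells}
    arr = counts.counts.to_numpy()
    nz = np.argwhere(arr > 0)
    # expand (well, probe) cells into one entry per read, then shuffle
    reps = arr[nz[:, 0], nz[:, 1]]
    expanded = np.repeat(np.arange(len(nz)), reps)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(expanded))
    wells_list = counts.wells
    probes_list = counts.probes
    for k, cell in enumerate(expanded[order]):
        wi, pi = nz[cell]
        well = wells_list[wi]
        probe = probes_list[pi]
        fwd, rev = bc_of[well]
        yield f"read{k}:{well}:{probe}", f"{fwd}{junction_of[probe]}{rev}"
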