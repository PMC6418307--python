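import numpy as np
import pandas as pd
import pytest

import raslscreen as rs
from raslscreen.panel import _seq_from_index
from raslscreen.simulate import SimulationConfig


@pytest.fixture(scope="session")
def panel():
    return rs.default_panel()


@pytest.fixture(scope="session")
def tiny_panel():
    """Minimal panel: 2 targets, 4 controls, 2 sex markers, 1 spike gene."""
    rows = []
    spec = [
        ("GeneA", "target", 3),
        ("GeneB", "target", 1),
        ("Ascl3", "control", 1),
        ("Psmd4", "control", 1),
        ("Sdha", "control", 1),
        ("Tbp", "control", 1),
        ("Xist", "sex_marker", 1),
        ("Ddx3y", "sex_marker", 1),
        ("Luciferase", "spike", 2),
    ]
    i = 0
    for gene, role, n in spec:
        for k in range(n):
            rows.append(
                {
                    "probe_id": f"{gene}_p{k + 1}",
                    "gene": gene,
                    "role": role,
                    "junction_seq": _seq_from_index(i, 20),
                }
            )
            i += 1
    return rs.ProbePanel(pd.DataFrame(rows))


def random_count_matrix(rng, n_wells=8, n_probes=6, scale=200.0):
    counts = rng.poisson(scale, size=(n_wells, n_probes))
    return rs.CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"P:A{i + 1}" for i in range(n_wells)],
            columns=[f"probe{j}" for j in range(n_probes)],
        ),
        provenance="simulated",
    )


@pytest.fixture(scope="session")
def small_screen(panel):
    """A 60-chemical triplicate screen with known ground truth (seeded)."""
    chemicals = rs.default_chemicals(60)
    design = rs.make_design(chemicals, n_replicates=3, seed=11)
    labels = rs.assign_templates(chemicals, n_per_template=6, seed=11)
    profiles = rs.build_profiles(labels, seed=11)
    counts, truth = rs.simulate_counts(
        design, panel, profiles, SimulationConfig(seed=11)
    )
    return {
        "design": design,
        "panel": panel,
        "counts": counts,
        "truth": truth,
        "labels": labels,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def small_screen_normalized(small_screen):
    filtered, report = rs.run_qc(small_screen["counts"], small_screen["panel"])
    stages = rs.normalize_pipeline(
        filtered, small_screen["panel"], small_screen["design"]
    )
    return {**small_screen, "filtered": filtered, "qc_report": report, **stages}
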