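"""Default probe panel and packaged signature templates.

The default panel mirrors the scale of a targeted neuronal RASL-seq screen:
56 genes covered by 261 ligation probes (3-7 probes per gene), four
housekeeping control genes (Ascl3, Psmd4, Sdha, Tbp), the X/Y sex markers
Xist and Ddx3y, and luciferase spike-in probes used as a cell-health proxy.

The packaged signature templates (``data/templates.tsv``) are synthetic,
hand-authored gene x cluster log2 effect profiles. They encode the
qualitative directions of the six previously described chemical-cluster
signatures (e.g. a Cluster-2-like response up-regulates Hmox1/Fos/Cx3cr1/
Gsta4 and down-regulates Rbfox3/Syt1/Nrxn1; a JQ1-like "novel" response
down-regulates microglial/astrocytic markers and up-regulates Fos/Rest/
Nrxn1) but are NOT reconstructions of any measured signature values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import (
    CONTROL_GENES,
    ROLE_CONTROL,
    ROLE_SEX_MARKER,
    ROLE_SPIKE,
    ROLE_TARGET,
    SEX_MARKER_GENES,
    SPIKE_GENE,
    ProbePanel,
)

# 50 target genes spanning neuroinflammation, cytoskeleton, stress response,
# immediate early genes and synaptic function; plus 4 controls + 2 sex markers
# = 56 genes on the panel.
TARGET_GENES = [
    # neuroinflammation / glial markers
    "Cx3cr1", "Aqp4", "Trem2", "Gfap", "Aif1", "C1qa", "Csf1r", "P2ry12",
    "Tmem119", "Il1b", "Tnf", "Ccl2",
    # cytoskeleton
    "Gsn", "Pdlim2", "Tubb3", "Map2", "Mapt", "Nefl", "Gap43",
    # stress response
    "Hmox1", "Gsta4", "Nqo1", "Nfe2l2", "Hspa5", "Ddit3", "Atf4",
    # immediate early / activity-dependent
    "Fos", "Vgf", "Npas4", "Arc", "Egr1", "Junb", "Bdnf", "Homer1",
    # synaptic function / neuronal identity
    "Nrxn1", "Syt1", "Rbfox3", "Snap25", "Syn1", "Dlg4", "Grin1", "Grin2b",
    "Gria1", "Stx1a", "Gabra1", "Gad1", "Slc17a7", "Camk2a", "Shank3",
    # transcriptional regulator
    "Rest",
]

N_SPIKE_PROBES = 3
_JUNCTION_LEN = 20
_BASES = "ACGT"


def _seq_from_index(i: int, length: int) -> str:
    """Deterministic unique nucleotide string encoding ``i`` in base 4."""
    digits = []
    for _ in range(length):
        digits.append(_BASES[i % 4])
        i //= 4
    return "".join(reversed(digits))


def barcode_seq(i: int, length: int = 8) -> str:
    return _seq_from_index(i, length)


def default_panel(with_junctions: bool = True) -> ProbePanel:
    """Build the default 56-gene, 261-probe panel (plus spike probes).

    Probes per gene are fixed deterministically: the first 37 genes of the
    combined list get 5 probes each, the remaining 19 get 4, totalling 261
    gene probes; luciferase spike probes are extra.
    """
    genes = TARGET_GENES + list(CONTROL_GENES) + list(SEX_MARKER_GENES)
    assert len(genes) == 56
    rows = []
    probe_index = 0
    for gi, gene in enumerate(genes):
        n_probes = 5 if gi < 37 else 4
        if gene in CONTROL_GENES:
            role = ROLE_CONTROL
        elif gene in SEX_MARKER_GENES:
            role = ROLE_SEX_MARKER
        else:
            role = ROLE_TARGET
        for k in range(n_probes):
            rows.append(
                {
                    "probe_id": f"{gene}_p{k + 1}",
                    "gene": gene,
                    "role": role,
                    "junction_seq": _seq_from_index(probe_index, _JUNCTION_LEN),
                }
            )
            probe_index += 1
    for k in range(N_SPIKE_PROBES):
        rows.append(
            {
                "probe_id": f"{SPIKE_GENE}_p{k + 1}",
                "gene": SPIKE_GENE,
                "role": ROLE_SPIKE,
                "junction_seq": _seq_from_index(probe_index, _JUNCTION_LEN),
            }
        )
        probe_index += 1
    table = pd.DataFrame(rows)
    if not with_junctions:
        table = table.drop(columns=["junction_seq"])
    return ProbePanel(table)


def load_templates() -> pd.DataFrame:
    """Load the packaged synthetic cluster templates (genes x labels, log2)."""
    with resources.files("raslscreen.data").joinpath("templates.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df
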