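"""Sex inference, signature correlation, cluster assignment, hierarchical
clustering, and cross-platform concordance.

Each chemical-concentration-sex profile is compared, by Pearson correlation
over a shared gene set, against aggregate signatures of previously defined
chemical clusters. A chemical is retained when at least one of its
concentrations correlates with at least one signature above 0.65 (strict);
chemicals exceeding the threshold for more than one signature are flagged
ambiguous and never auto-resolved, and chemicals never exceeding it are
unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .design import SEX_MARKER_GENES, ValidationError
from .normalize import NormalizedMatrix

log = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.65
MIN_SHARED_GENES = 3

STATUS_CLASSIFIED = "classified"
STATUS_AMBIGUOUS = "unclassified_ambiguous"
STATUS_LOW = "unclassified_low"


# ---------------------------------------------------------------------------
# sex inference


def infer_sex(norm: NormalizedMatrix) -> pd.DataFrame:
    """Call the sex of each sample from the Xist - Ddx3y score.

    Positive score means female, negative male, exact zero is left unknown.
    """
    for g in SEX_MARKER_GENES:
        if g not in norm.values.index:
            raise ValidationError(f"sex marker {g!r} absent from the matrix")
    score = norm.values.loc["Xist"] - norm.values.loc["Ddx3y"]
    call = pd.Series(
        np.where(score > 0, "F", np.where(score < 0, "M", "unknown")),
        index=score.index,
    )
    return pd.DataFrame({"score": score, "call": call})


# ---------------------------------------------------------------------------
# signatures


@dataclass
class SignatureSet:
    """Named aggregate signatures: genes x signature log2 expression."""

    values: pd.DataFrame
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate signature names")

    @property
    def names(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()


def aggregate_signatures(
    reference: NormalizedMatrix,
    cluster_membership: Mapping[str, str],
    provenance: str = "aggregated-reference",
) -> SignatureSet:
    """Collapse a reference profile matrix into per-cluster signatures.

    ``reference`` columns are chemicals; each cluster's signature is the
    per-gene median across its member chemicals.
    """
    clusters: dict[str, list[str]] = {}
    for chem, cl in cluster_membership.items():
        clusters.setdefault(cl, []).append(chem)
    cols = {}
    for cl, members in sorted(clusters.items()):
        present = [m for m in members if m in reference.values.columns]
        if not present:
            raise ValidationError(f"cluster {cl!r} has no member in the reference")
        cols[cl] = reference.values[present].median(axis=1)
    return SignatureSet(pd.DataFrame(cols), provenance=provenance)


# ---------------------------------------------------------------------------
# correlation and assignment


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlate_to_signatures(
    norm: NormalizedMatrix,
    signatures: SignatureSet,
    gene_subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pearson r of every sample column against every signature.

    Correlations run over the intersection of matrix genes, signature genes
    and ``gene_subset`` (when given, e.g. the genes commonly assayed by both
    platforms). Zero-variance vectors yield NaN, never 0: a flat (vehicle-
    like) profile carries no signature information.
    """
    shared = [g for g in norm.values.index if g in set(signatures.genes)]
    if gene_subset is not None:
        shared = [g for g in shared if g in set(gene_subset)]
    if len(shared) < MIN_SHARED_GENES:
        log.warning("only %d shared genes; correlations undefined", len(shared))
        return pd.DataFrame(
            np.nan, index=norm.values.columns, columns=signatures.names
        )
    m = norm.values.loc[shared].to_numpy()
    s = signatures.values.loc[shared].to_numpy()
    out = np.full((m.shape[1], s.shape[1]), np.nan)
    for j in range(s.shape[1]):
        for i in range(m.shape[1]):
            out[i, j] = _pearson_or_nan(m[:, i], s[:, j])
    table = pd.DataFrame(out, index=norm.values.columns, columns=signatures.names)
    table.index.name = "condition"
    return table


def parse_condition(label: str) -> tuple[str, float, Optional[str]]:
    """Split ``chemical@conc[@sex]`` labels; sex is optional (sex-averaged)."""
    parts = label.split("@")
    if len(parts) not in (2, 3):
        raise ValidationError(f"malformed condition label {label!r}")
    chem, conc = parts[0], float(parts[1])
    sex = parts[2] if len(parts) == 3 else None
    return chem, conc, sex


@dataclass
class ChemicalCall:
    chemical_id: str
    status: str
    signature: Optional[str]  # set only when classified
    candidates: list[str]  # every signature exceeding the threshold
    supporting: list[tuple[float, Optional[str], float]]  # (conc, sex, r)
    max_r: float
    cell_health: Optional[float] = None


@dataclass
class ClassificationResult:
    calls: dict[str, ChemicalCall] = field(default_factory=dict)
    threshold: float = CORRELATION_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls.values():
            rows.append(
                {
                    "chemical_id": c.chemical_id,
                    "status": c.status,
                    "signature": c.signature if c.signature else "",
                    "candidates": ";".join(c.candidates),
                    "max_r": c.max_r,
                    "n_supporting": len(c.supporting),
                    "cell_health": c.cell_health,
                }
            )
        return pd.DataFrame(rows).set_index("chemical_id")

    def classified(self) -> dict[str, str]:
        return {
            c.chemical_id: c.signature  # type: ignore[misc]
            for c in self.calls.values()
            if c.status == STATUS_CLASSIFIED
        }


def assign_clusters(
    corr: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    cell_health: Optional[Mapping[str, float]] = None,
) -> ClassificationResult:
    """Apply the retention rule to a condition x signature correlation table.

    Per chemical, collect the signatures for which any concentration (and
    sex, when labels carry one) correlates strictly above ``threshold``.
    Exactly one such signature classifies the chemical; several flag it
    ambiguous (candidates are reported, with the cell-health covariate when
    provided, and never auto-resolved); none leaves it unclassified.
    """
    per_chem: dict[str, list[tuple[float, Optional[str], str, float]]] = {}
    max_r: dict[str, float] = {}
    for label in corr.index:
        chem, conc, sex = parse_condition(str(label))
        per_chem.setdefault(chem, [])
        for sig in corr.columns:
            r = corr.loc[label, sig]
            if pd.isna(r):
                continue
            max_r[chem] = max(max_r.get(chem, -np.inf), float(r))
            if r > threshold:
                per_chem[chem].append((conc, sex, str(sig), float(r)))
    result = ClassificationResult(threshold=threshold)
    for chem, hits in per_chem.items():
        candidates = sorted({h[2] for h in hits})
        if len(candidates) == 1:
            status, signature = STATUS_CLASSIFIED, candidates[0]
        elif len(candidates) > 1:
            status, signature = STATUS_AMBIGUOUS, None
        else:
            status, signature = STATUS_LOW, None
        result.calls[chem] = ChemicalCall(
            chemical_id=chem,
            status=status,
            signature=signature,
            candidates=candidates,
            supporting=[(c, s, r) for c, s, _, r in hits],
            max_r=max_r.get(chem, np.nan),
            cell_health=None if cell_health is None else cell_health.get(chem),
        )
    return result


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterTree:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id].replace(" ", "_")
            return (
                f"({walk(node.get_left())},{walk(node.get_right())}):"
                f"{node.dist:.6g}"
            )

        return walk(tree) + ";"


def hierarchical_cluster(
    norm: NormalizedMatrix, method: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of sample columns at 1 - Pearson r distance.

    Columns are sorted lexicographically first so that leaf order is
    deterministic under relabeling/tie conditions.
    """
    if norm.values.shape[1] < 2:
        raise ValidationError("clustering needs at least two columns")
    values = norm.values[sorted(norm.values.columns, key=str)]
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        raise ValidationError("clustering input contains non-finite values")
    corr = np.corrcoef(arr.T)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance columns: no similarity
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = hierarchy.leaves_list(link)
    labels = values.columns.tolist()
    return ClusterTree(
        linkage=link, labels=labels, leaf_order=[labels[i] for i in order]
    )


# ---------------------------------------------------------------------------
# cross-platform concordance


@dataclass
class Concordance:
    r: float
    p_value: float
    pairs: pd.DataFrame  # per-gene paired values, for scatter plots


def cross_platform_concordance(
    profile_a: pd.Series, profile_b: pd.Series
) -> Concordance:
    """Pearson concordance of two per-gene profiles over their shared genes.

    Returns r with a two-sided t-distribution p-value plus the paired table.
    """
    shared = profile_a.index.intersection(profile_b.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} shared genes; need >= {MIN_SHARED_GENES}"
        )
    a = profile_a.loc[shared].astype(float)
    b = profile_b.loc[shared].astype(float)
    res = stats.pearsonr(a, b)
    pairs = pd.DataFrame({"a": a, "b": b})
    pairs.index.name = "gene"
    return Concordance(r=float(res.statistic), p_value=float(res.pvalue), pairs=pairs)
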