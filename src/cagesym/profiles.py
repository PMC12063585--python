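"""Community profiling: rarefaction and phylogeny-guided agglomeration.

Turns a samples x ASVs read matrix plus a phylogeny into a lineage-level
count matrix: reads are rarefied to a fixed depth (without replacement),
ASVs are clustered on their cophenetic (tip-to-tip path length) distances
by hierarchical clustering cut at a height threshold, and counts are
summed within clusters.  At the conventional threshold of 0.1 the clusters
approximate bacterial species ("lineages").
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import LineageMatrix, validate_read_matrix
from .seeds import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy",
    "cophenetic_matrix",
    "agglomerate_tips",
    "group_richness",
    "dominant_lineages",
]

#: Rarefaction depth at which rarefaction curves plateaued in the study
#: this pipeline models; the default depth for the full pipeline.
DEFAULT_RAREFACTION_DEPTH = 9123

#: Cophenetic distance threshold approximating the species level.
DEFAULT_AGGLOMERATION_H = 0.1


def rarefy(
    matrix: pd.DataFrame,
    depth: int,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Rarefy each sample to exactly ``depth`` reads without replacement.

    Each retained sample's counts are a multivariate-hypergeometric draw of
    ``depth`` reads from its observed reads, so row sums equal ``depth``
    exactly and no count ever increases.  Samples with fewer than ``depth``
    total reads are dropped (logged at INFO).
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    validate_read_matrix(matrix)
    if matrix.shape[0] == 0:
        warnings.warn("rarefy: empty read matrix", stacklevel=2)
        return matrix.copy()
    rng = as_rng(seed)
    totals = matrix.sum(axis=1)
    keep = totals >= depth
    dropped = matrix.index[~keep]
    if len(dropped):
        logger.info(
            "rarefy: dropping %d/%d samples below depth %d: %s",
            len(dropped), len(matrix), depth, list(dropped),
        )
    out = np.empty((int(keep.sum()), matrix.shape[1]), dtype=np.int64)
    rows = matrix.loc[keep].to_numpy().astype(np.int64)
    for i in range(rows.shape[0]):
        out[i] = rng.multivariate_hypergeometric(rows[i], depth)
    return pd.DataFrame(out, index=matrix.index[keep], columns=matrix.columns)


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise tip-to-tip path-length (cophenetic) distances of a tree.

    Raises if any non-root edge lacks a branch length, naming the edge by
    its child node.
    """
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            name = node.taxon.label if node.taxon else f"internal node {id(node)}"
            raise ValueError(f"edge above {name!r} has no branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def agglomerate_tips(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    h: float = DEFAULT_AGGLOMERATION_H,
    linkage_method: str = "average",
) -> LineageMatrix:
    """Agglomerate ASVs into lineages by cophenetic distance.

    Hierarchically clusters the ASVs of ``matrix`` on their cophenetic
    distances (average linkage by default; ``complete`` and ``single`` are
    also supported), cuts the dendrogram at height ``h``, and sums counts
    within each cluster.  Each lineage is named after its archetype: the
    member ASV with the largest total count across samples, ties broken by
    the lexicographically smallest ASV id.

    Per-sample totals are conserved exactly under the collapse.
    """
    if h < 0:
        raise ValueError("agglomeration threshold h must be >= 0")
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    validate_read_matrix(matrix)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [a for a in matrix.columns if a not in tips]
    if missing:
        raise ValueError(f"ASVs absent from the tree: {missing}")
    asvs = list(matrix.columns)
    if len(asvs) == 0:
        return LineageMatrix(counts=matrix.copy(), mapping={}, archetypes={})
    if len(asvs) == 1:
        lab = asvs[0]
        return LineageMatrix(
            counts=matrix.copy(), mapping={lab: lab}, archetypes={lab: lab}
        )
    dist = cophenetic_matrix(tree).loc[asvs, asvs]
    z = linkage(squareform(dist.to_numpy(), checks=False), method=linkage_method)
    flat = fcluster(z, t=h, criterion="distance")
    totals = matrix.sum(axis=0)
    mapping: dict[str, str] = {}
    archetypes: dict[str, str] = {}
    for cluster_id in np.unique(flat):
        members = [asvs[i] for i in np.where(flat == cluster_id)[0]]
        archetype = min(members, key=lambda a: (-totals[a], a))
        archetypes_id = archetype  # lineages are named after their archetype ASV
        archetypes[archetypes_id] = archetype
        for a in members:
            mapping[a] = archetypes_id
    lineage_ids = sorted(archetypes)
    collapsed = pd.DataFrame(
        0, index=matrix.index, columns=lineage_ids, dtype=np.int64
    )
    for a in asvs:
        collapsed[mapping[a]] += matrix[a].to_numpy()
    logger.info(
        "agglomerate: %d ASVs -> %d lineages at h=%g (%s linkage)",
        len(asvs), len(lineage_ids), h, linkage_method,
    )
    return LineageMatrix(counts=collapsed, mapping=mapping, archetypes=archetypes)


def _counts_of(matrix: LineageMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.counts if isinstance(matrix, LineageMatrix) else matrix


def group_richness(
    matrix: LineageMatrix | pd.DataFrame, samples: Iterable[str]
) -> int:
    """Number of lineages present (count > 0) in the union of ``samples``."""
    counts = _counts_of(matrix)
    samples = list(samples)
    unknown = [s for s in samples if s not in counts.index]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")
    if not samples:
        return 0
    return int((counts.loc[samples] > 0).any(axis=0).sum())


def dominant_lineages(
    matrix: LineageMatrix | pd.DataFrame, threshold: float
) -> set[str]:
    """Lineages whose share of total reads across all samples >= ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    counts = _counts_of(matrix)
    total = counts.to_numpy().sum()
    if total == 0:
        return set()
    shares = counts.sum(axis=0) / total
    return set(shares.index[shares >= threshold])
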