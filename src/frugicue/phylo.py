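"""Phylogenetic correlation structure for species-level random effects.

The phylogenetic random effect assumes a Brownian-motion-like covariance:
two species covary in proportion to the branch length they share from the
root.  For tips k and l with root-to-tip depths d_k, d_l and shared
root-to-MRCA path length t_shared, the correlation is

    C_kl = t_shared(k, l) / sqrt(d_k * d_l),

which reduces to the familiar scaled variance-covariance matrix on
ultrametric trees (entries in [0, 1], unit diagonal) and remains a valid
correlation on non-ultrametric trees.  The sampler consumes the inverse
of C (the precision parameterization), computed with a small ridge for
numerical stability.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "PhyloCorrelation",
    "read_newick",
    "correlation_from_tree",
    "stable_inverse",
    "write_correlation_csv",
    "read_correlation_csv",
]


@dataclass
class Phylogeny:
    """A rooted tree with unique tip labels and non-negative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
            if not np.isfinite(edge.length) or edge.length < 0:
                raise ValueError("branch lengths must be finite and >= 0")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (or file-like) into a Phylogeny."""
    if hasattr(text, "read"):
        text = text.read()
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(text), schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    if len(tree.leaf_nodes()) < 1:
        raise ValueError("tree has no tips")
    return Phylogeny(tree)


@dataclass
class PhyloCorrelation:
    """Species-ordered correlation matrix from shared branch lengths."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.matrix, float)
        n = len(self.species)
        if C.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        self.matrix = C

    def submatrix(self, species: list[str]) -> "PhyloCorrelation":
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(list(species), self.matrix[np.ix_(idx, idx)])


def correlation_from_tree(phylogeny: Phylogeny,
                          species: list[str] | None = None) -> PhyloCorrelation:
    """Standardized shared-branch-length correlation, pruned to and
    ordered by ``species`` (default: all tips in tree order)."""
    tree = phylogeny.tree
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if species is None:
        species = list(tips)
    missing = [s for s in species if s not in tips]
    if missing:
        raise KeyError(f"species absent from tree: {missing}")

    # root distance of every node
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    d = np.array([depth[tips[s]] for s in species])
    if d.max() <= 0:
        raise ValueError("tree has zero depth")
    # guard zero-depth tips attached at the root
    d_safe = np.where(d > 0, d, np.nan)

    # ancestor sets for shared-path computation
    anc = {}
    for s in species:
        chain, node = [], tips[s]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[s] = chain

    n = len(species)
    C = np.eye(n)
    anc_index = {s: {id(node): depth[node] for node in anc[s]} for s in species}
    for i in range(n):
        for j in range(i + 1, n):
            # deepest ancestor of i that is also an ancestor of j
            shared = 0.0
            for node in anc[species[i]]:
                if id(node) in anc_index[species[j]]:
                    shared = depth[node]
                    break
            cij = shared / np.sqrt(d_safe[i] * d_safe[j])
            if np.isnan(cij):
                cij = 0.0
            C[i, j] = C[j, i] = cij
    return PhyloCorrelation(list(species), C)


def stable_inverse(corr: PhyloCorrelation | np.ndarray,
                   ridge: float = 1e-8) -> np.ndarray:
    """Inverse of (C + ridge*I), verified to machine-practical accuracy.

    Escalates the ridge by factors of 10 (up to 1e-4) when C is numerically
    singular, logging a warning; beyond that it raises.
    """
    C = corr.matrix if isinstance(corr, PhyloCorrelation) else np.asarray(corr, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    eye = np.eye(C.shape[0])
    r = ridge
    while r <= 1e-4:
        try:
            L = np.linalg.cholesky(C + r * eye)
        except np.linalg.LinAlgError:
            r *= 10
            continue
        Linv = np.linalg.inv(L)
        inv = Linv.T @ Linv
        err = np.abs((C + r * eye) @ inv - eye).max()
        if err < 1e-6:
            if r > ridge:
                logger.warning("correlation matrix rank-deficient; inverted "
                               "with ridge %.1e", r)
            return inv
        r *= 10
    raise np.linalg.LinAlgError(
        "correlation matrix singular beyond ridge rescue; supply a larger ridge"
    )


def write_correlation_csv(corr: PhyloCorrelation, path) -> None:
    pd.DataFrame(corr.matrix, index=corr.species,
                 columns=corr.species).to_csv(path)


def read_correlation_csv(path) -> PhyloCorrelation:
    df = pd.read_csv(path, index_col=0)
    return PhyloCorrelation(list(df.index.astype(str)), df.to_numpy(float))
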