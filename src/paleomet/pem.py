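"""Phylogenetic eigenvector maps (PEM), built from scratch on rooted trees.

A PEM represents the phylogeny as an orthogonal basis of "phylogenetic
eigenvectors": the left singular vectors of the column-centered, weighted
influence matrix.  The influence matrix is the binary tips x edges matrix
marking which edges lie on each root-to-tip path; edge j is weighted by
w_j = psi * l_j**((1 - a)/2), where a in [0, 1) is the steepness parameter
and psi > 0 an overall scale.  At a = 0, psi = 1 the (uncentered) Gram
matrix of the weighted influence rows equals the Brownian-motion
shared-path-length covariance, tying the basis to the Brownian trait model.

Grafted fossil tips are scored out of sample: their weighted influence row
over the *extant* basis edges (split edges contribute the weight rule
applied to the traversed length; the fossil stem has no basis column) is
centered with the stored column means and projected onto the right singular
vectors.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .phylo import PhyloTree, TreeError

__all__ = [
    "PEMError",
    "PEMBasis",
    "influence_matrix",
    "edge_weights",
    "build_pem",
    "location_scores",
]

_SV_DROP = 1e-10  # relative singular-value cutoff


class PEMError(ValueError):
    """Invalid PEM construction or scoring request."""


@dataclasses.dataclass
class PEMBasis:
    """Eigenvector basis of a tree; eigenvectors are 1-based, by descending
    singular value, with each column's largest-magnitude element positive."""

    tip_labels: list[str]
    edge_ids: list[int]            # child-node ids naming the basis edges
    a: float
    psi: float
    edge_lengths: np.ndarray       # (m,)
    weights: np.ndarray            # (m,)
    col_means: np.ndarray          # (m,) means of the weighted influence cols
    d: np.ndarray                  # (k,) singular values, descending, > 0
    U: np.ndarray                  # (n, k) tip scores, orthonormal columns
    V: np.ndarray                  # (m, k) right singular vectors

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_eigenvectors(self) -> int:
        return len(self.d)

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise PEMError(f"no tip {label!r} in basis") from None


def influence_matrix(tree: PhyloTree) -> tuple[np.ndarray, list[str], list[int]]:
    """Binary (tips x edges) matrix: entry (i, j) = 1 iff edge j is on the
    root-to-tip-i path.  Tips and edges are in preorder; an edge is named by
    its child node id."""
    edges = tree.edge_ids()
    eidx = {e: j for j, e in enumerate(edges)}
    tips = tree.tip_ids()
    B = np.zeros((len(tips), len(edges)))
    for i, t in enumerate(tips):
        v = t
        while v != tree.root:
            B[i, eidx[v]] = 1.0
            v = tree.parent[v]
    return B, [tree.label[t] for t in tips], edges


def edge_weights(lengths: np.ndarray, a: float, psi: float) -> np.ndarray:
    """w_j = psi * l_j**((1 - a)/2); zero-length edges get weight 0."""
    if not (0.0 <= a < 1.0):
        raise PEMError("steepness a must lie in [0, 1)")
    if psi <= 0.0:
        raise PEMError("scale psi must be > 0")
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 0):
        raise PEMError("edge lengths must be >= 0")
    return psi * lengths ** ((1.0 - a) / 2.0)


def build_pem(tree: PhyloTree, a: float = 0.0, psi: float = 1.0) -> PEMBasis:
    """Construct the eigenvector basis for the tips of ``tree``."""
    if tree.n_tips < 3:
        raise PEMError("PEM needs at least 3 tips")
    B, tip_labels, edges = influence_matrix(tree)
    lengths = np.array([tree.blen[e] for e in edges], dtype=float)
    w = edge_weights(lengths, a, psi)
    if not np.any(w > 0):
        raise PEMError("degenerate tree: all branch lengths are zero")
    W = B * w
    col_means = W.mean(axis=0)
    Wc = W - col_means
    U, d, Vt = np.linalg.svd(Wc, full_matrices=False)
    keep = d > _SV_DROP * d[0]
    U, d, Vt = U[:, keep], d[keep], Vt[keep, :]
    # deterministic sign: largest-|.| element of each eigenvector positive;
    # |.|-ties broken by tip label so the convention is permutation-stable
    for k in range(U.shape[1]):
        mags = np.abs(U[:, k])
        mx = mags.max()
        cand = np.flatnonzero(mags >= mx * (1.0 - 1e-9))
        i = min(cand, key=lambda j: tip_labels[j])
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    return PEMBasis(
        tip_labels=tip_labels,
        edge_ids=list(edges),
        a=a,
        psi=psi,
        edge_lengths=lengths,
        weights=w,
        col_means=col_means,
        d=d,
        U=U,
        V=Vt.T.copy(),
    )


def location_scores(basis: PEMBasis, tree: PhyloTree, fossil_label: str) -> np.ndarray:
    """Eigenvector scores of a grafted fossil tip.

    ``tree`` must derive from the basis tree by grafting (node ids and edge
    origins preserved).  The fossil's influence row over the basis edges
    accumulates the traversed length of each original edge (splits included)
    and applies the basis's weight rule; the stem edge, absent from the
    basis, contributes nothing to the scores.  Row is centered with the
    stored column means and projected: u = b_c V diag(d)^-1.
    """
    node = tree.find(fossil_label)
    if not tree.is_tip(node):
        raise PEMError(f"{fossil_label!r} is not a tip")
    eidx = {e: j for j, e in enumerate(basis.edge_ids)}
    # consistency: every basis edge must be recoverable from the tree's
    # edge origins with its original total length (splits sum back up)
    totals: dict[int, float] = {}
    for v, o in tree.origin.items():
        if o is not None:
            totals[o] = totals.get(o, 0.0) + tree.blen[v]
    for e, j in eidx.items():
        if abs(totals.get(e, 0.0) - basis.edge_lengths[j]) > 1e-9 * max(
            1.0, basis.edge_lengths[j]
        ):
            raise PEMError(
                "edge-order mismatch: tree edges do not map onto the basis "
                "(was the basis built from a different tree?)"
            )
    traversed = np.zeros(len(basis.edge_ids))
    v = node
    while tree.parent[v] is not None:
        o = tree.origin.get(v)
        if o is not None:
            j = eidx.get(o)
            if j is None:
                raise PEMError(
                    "edge-order mismatch: tree edge does not map onto the "
                    "basis (was the basis built from a different tree?)"
                )
            traversed[j] += tree.blen[v]
        v = tree.parent[v]
    b = edge_weights(traversed, basis.a, basis.psi)
    bc = b - basis.col_means
    return (bc @ basis.V) / basis.d


def unrepresented_length(tree: PhyloTree, fossil_label: str) -> float:
    """Total length of the fossil's root-path edges absent from the base
    tree (its private stem).  Trait evolution along these edges is invisible
    to the eigenvector scores and must enter prediction variance instead."""
    node = tree.find(fossil_label)
    if not tree.is_tip(node):
        raise PEMError(f"{fossil_label!r} is not a tip")
    total = 0.0
    v = node
    while tree.parent[v] is not None:
        if tree.origin.get(v) is None:
            total += tree.blen[v]
        v = tree.parent[v]
    return total
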