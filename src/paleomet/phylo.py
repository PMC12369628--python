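"""Rooted time-calibrated phylogenies.

Trees carry branch lengths in millions of years (Myr) by pipeline convention
(the unit is documented, not enforced numerically).  The module provides
Newick I/O, grafting of fossil tips at dated positions along existing edges,
pruning with an exact re-graft specification, and the maximum-likelihood
Brownian-motion root state (the generalized-least-squares mean over the
shared-path-length covariance), which is the closed-form equivalent of the
"reconstruct ancestral states" root estimate used for reconciling clade
allometric exponents.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "TreeError",
    "GraftSpec",
    "PhyloTree",
    "read_newick",
    "graft_fossil",
    "prune_tip",
    "brownian_root_state",
]

_AGE_TOL = 1e-6  # Myr tolerance for declared-age consistency checks


class NewickError(ValueError):
    """Malformed or unsupported Newick input."""


class TreeError(ValueError):
    """Structurally invalid tree or invalid tree operation."""


@dataclasses.dataclass(frozen=True)
class GraftSpec:
    """Placement of a fossil tip on an existing tree.

    Parameters
    ----------
    label
        Name of the new fossil tip (must not collide with existing tips).
    attach
        The child end of the attachment edge, given as a tip/internal label
        or a node id.  With ``attach_time=None`` the fossil is attached at
        that node itself (the node must not be a tip).
    attach_time
        Time before present (Myr) of the attachment point, which must lie
        within the span of the edge above ``attach``.
    stem_length
        Length (Myr) of the fossil's own terminal branch; >= 0.
    tip_age
        Optional declared age of the fossil tip (Myr before present).  When
        given it must equal ``attach_time - stem_length`` to within 1e-6 and
        must be >= 0.
    """

    label: str
    attach: str | int
    attach_time: float | None = None
    stem_length: float = 0.0
    tip_age: float | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise TreeError("fossil label must be non-empty")
        if self.stem_length < 0:
            raise TreeError("stem length must be >= 0")
        if self.tip_age is not None and self.tip_age < 0:
            raise TreeError("fossil tip age must be >= 0")


class PhyloTree:
    """Rooted tree with branch lengths; node ids are stable small integers.

    ``origin[v]`` tracks, for the edge above node ``v``, the id of the edge
    of the *base* tree it derives from (identity for an un-grafted tree,
    ``None`` for a fossil stem created by grafting).  Grafting preserves the
    ids of pre-existing nodes, so eigenvector bases built on the base tree
    can score grafted fossils by edge origin.
    """

    __slots__ = ("root", "parent", "children", "blen", "label", "origin")

    def __init__(
        self,
        parent: Mapping[int, int | None],
        children: Mapping[int, list[int]],
        blen: Mapping[int, float],
        label: Mapping[int, str],
        root: int,
        origin: Mapping[int, int | None] | None = None,
        validate: bool = True,
    ) -> None:
        self.parent = dict(parent)
        self.children = {v: list(c) for v, c in children.items()}
        self.blen = dict(blen)
        self.label = dict(label)
        self.root = root
        if origin is None:
            origin = {v: v for v in self.parent if v != root}
        self.origin = dict(origin)
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.root not in self.parent or self.parent[self.root] is not None:
            raise TreeError("tree must have exactly one root with no parent")
        seen = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeError("cycle detected in tree")
            seen.add(v)
            stack.extend(self.children.get(v, []))
        if seen != set(self.parent):
            raise TreeError("disconnected nodes present")
        for v, p in self.parent.items():
            if v == self.root:
                continue
            if p is None or v not in self.children.get(p, []):
                raise TreeError(f"node {v} has inconsistent parent link")
            ell = self.blen.get(v)
            if ell is None:
                raise TreeError(f"edge above node {v} is missing a branch length")
            if ell < 0:
                raise TreeError(f"negative branch length above node {v}")
        tips = self.tip_ids()
        if len(tips) < 2:
            raise TreeError("tree must have at least 2 tips")
        labels = [self.label.get(t, "") for t in tips]
        if any(not lab for lab in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.parent, self.children, self.blen, self.label, self.root,
            origin=self.origin, validate=False,
        )

    def is_tip(self, v: int) -> bool:
        return not self.children.get(v)

    def preorder(self) -> list[int]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children.get(v, [])))
        return out

    def tip_ids(self) -> list[int]:
        return [v for v in self.preorder() if self.is_tip(v)]

    def tip_labels(self) -> list[str]:
        return [self.label[v] for v in self.tip_ids()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids())

    def edge_ids(self) -> list[int]:
        """Non-root node ids in preorder; node id names the edge above it."""
        return [v for v in self.preorder() if v != self.root]

    def depths(self) -> dict[int, float]:
        d = {self.root: 0.0}
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.blen[v]
        return d

    @property
    def age(self) -> float:
        """Time span from root to the youngest tip (the 'present')."""
        d = self.depths()
        return max(d[t] for t in self.tip_ids())

    def tip_ages(self) -> dict[str, float]:
        """Time before present of every tip (0 for contemporaneous tips)."""
        d = self.depths()
        age = self.age
        return {self.label[t]: age - d[t] for t in self.tip_ids()}

    def find(self, node: str | int) -> int:
        if isinstance(node, (int, np.integer)):
            if int(node) not in self.parent:
                raise TreeError(f"no node with id {node}")
            return int(node)
        for v, lab in self.label.items():
            if lab == node:
                return v
        raise TreeError(f"no node labelled {node!r}")

    def _next_id(self) -> int:
        return max(self.parent) + 1

    # ------------------------------------------------------------------
    # metrics
    # ------------------------------------------------------------------
    def brownian_covariance(self) -> tuple[np.ndarray, list[str]]:
        """Shared path length from the root between tips (Brownian C).

        Computed by a subtree recursion on MRCA depths, independently of the
        influence-matrix route used by the eigenvector-map module.
        """
        tips = self.tip_ids()
        idx = {t: i for i, t in enumerate(tips)}
        depth = self.depths()
        n = len(tips)
        C = np.zeros((n, n))
        order = self.preorder()
        below: dict[int, list[int]] = {}
        for v in reversed(order):
            if self.is_tip(v):
                i = idx[v]
                C[i, i] = depth[v]
                below[v] = [i]
            else:
                groups = [below.pop(c) for c in self.children[v]]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        ia = np.array(groups[a])[:, None]
                        ib = np.array(groups[b])[None, :]
                        C[ia, ib] = depth[v]
                        C[ib.T, ia.T] = depth[v]
                below[v] = [i for g in groups for i in g]
        return C, [self.label[t] for t in tips]

    def tip_distances(self) -> tuple[np.ndarray, list[str]]:
        """Pairwise patristic distances between tips."""
        C, labels = self.brownian_covariance()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C, labels

    # ------------------------------------------------------------------
    # Newick
    # ------------------------------------------------------------------
    def write_newick(self) -> str:
        def quote(lab: str) -> str:
            if lab and all(c.isalnum() or c in "_.|-" for c in lab):
                return lab
            return "'" + lab.replace("'", "''") + "'"

        def fmt(v: int) -> str:
            if self.is_tip(v):
                core = quote(self.label[v])
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
                if v in self.label and self.label[v]:
                    core += quote(self.label[v])
            if v != self.root:
                core += ":" + format(self.blen[v], ".17g")
            return core

        return fmt(self.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are required on every non-root edge (a missing length is
    an explicit error, never silently defaulted); a root edge length, if
    present, is ignored.  Malformed input raises :class:`NewickError`
    naming the line/column where parsing failed.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" (line {line}, column {col})" if line is not None else ""
        raise NewickError(f"malformed Newick{where}: {exc}") from exc

    parent: dict[int, int | None] = {}
    children: dict[int, list[int]] = {}
    blen: dict[int, float] = {}
    label: dict[int, str] = {}
    counter = [0]

    def walk(dnode, par: int | None) -> int:
        vid = counter[0]
        counter[0] += 1
        parent[vid] = par
        children[vid] = []
        if par is not None:
            length = dnode.edge.length
            if length is None:
                name = _dnode_name(dnode) or f"node {vid}"
                raise NewickError(f"edge above {name!r} has no branch length")
            blen[vid] = float(length)
            children[par].append(vid)
        name = _dnode_name(dnode)
        if name:
            label[vid] = name
        for ch in dnode.child_nodes():
            walk(ch, vid)
        return vid

    root = walk(dtree.seed_node, None)
    try:
        return PhyloTree(parent, children, blen, label, root)
    except TreeError as exc:
        raise NewickError(str(exc)) from exc


def _dnode_name(dnode) -> str | None:
    if dnode.taxon is not None and dnode.taxon.label:
        return dnode.taxon.label
    return dnode.label or None


# ----------------------------------------------------------------------
# grafting / pruning
# ----------------------------------------------------------------------
def graft_fossil(tree: PhyloTree, spec: GraftSpec) -> PhyloTree:
    """Return a new tree with one extra (fossil) tip per ``spec``.

    Distances among pre-existing tips are untouched: attaching within an
    edge splits it into two collinear pieces whose lengths sum to the
    original, both of which keep the original edge's ``origin`` id.
    """
    t = tree.copy()
    if spec.label in set(t.tip_labels()):
        raise TreeError(f"fossil label {spec.label!r} already present")
    target = t.find(spec.attach)
    depth = t.depths()
    age = t.age

    if spec.attach_time is None:
        if t.is_tip(target):
            raise TreeError("cannot attach at a tip node; use the edge form")
        attach_node = target
        attach_depth = depth[target]
    else:
        par = t.parent[target]
        if par is None:
            raise TreeError("cannot attach on the root edge")
        attach_depth = age - spec.attach_time
        lo, hi = depth[par], depth[target]
        if not (lo - _AGE_TOL <= attach_depth <= hi + _AGE_TOL):
            raise TreeError(
                f"attachment time {spec.attach_time} outside edge span "
                f"[{age - hi}, {age - lo}] of edge above {spec.attach!r}"
            )
        attach_depth = min(max(attach_depth, lo), hi)
        mid = t._next_id()
        t.parent[mid] = par
        t.children[mid] = [target]
        t.parent[target] = mid
        t.blen[mid] = attach_depth - lo
        t.blen[target] = hi - attach_depth
        t.origin[mid] = t.origin.get(target)
        pos = t.children[par].index(target)
        t.children[par][pos] = mid
        attach_node = mid

    tip_depth = attach_depth + spec.stem_length
    implied_age = age - tip_depth
    # implied_age may be negative for purely mechanical re-grafts (e.g. a
    # pruned child of a collapsed root); a *declared* tip age must be >= 0
    # and consistent, which rules that out for real fossil specifications.
    if spec.tip_age is not None and abs(spec.tip_age - implied_age) > _AGE_TOL:
        raise TreeError(
            f"declared tip age {spec.tip_age} inconsistent with attachment "
            f"time minus stem ({implied_age:.6f})"
        )

    fid = t._next_id()
    t.parent[fid] = attach_node
    t.children[fid] = []
    t.children[attach_node].append(fid)
    t.blen[fid] = spec.stem_length
    t.label[fid] = spec.label
    t.origin[fid] = None
    t._validate()
    return t


def prune_tip(tree: PhyloTree, label: str) -> tuple[PhyloTree, GraftSpec]:
    """Remove a tip; return the pruned tree and the spec that re-grafts it.

    Degree-2 nodes created by the removal are suppressed (their two edges
    merged), so the pruned tree is a clean base tree with identity edge
    origins.  ``graft_fossil(pruned, spec)`` restores every original
    tip-to-tip distance exactly.  If the removed tip hung directly off a
    bifurcating root the old root collapses; the re-graft spec then attaches
    at the new root with the collapsed edge folded into the stem (tip age is
    not representable in that geometry and is left ``None``).
    """
    t = tree.copy()
    tip = t.find(label)
    if not t.is_tip(tip):
        raise TreeError(f"{label!r} is not a tip")
    depth = t.depths()
    p = t.parent[tip]
    if p is None:
        raise TreeError("cannot prune the root")
    stem = t.blen[tip]
    t.children[p].remove(tip)
    for d in (t.parent, t.blen, t.label, t.origin):
        d.pop(tip, None)
    t.children.pop(tip, None)

    remaining = t.children[p]
    if len(remaining) >= 2:
        pruned = _rebase(t)
        spec = GraftSpec(
            label=label, attach=p, attach_time=None, stem_length=stem,
            tip_age=None,
        )
        return pruned, spec

    c = remaining[0]
    if p == t.root:
        # collapse old root; c becomes the new root
        fold = t.blen.pop(c)
        t.parent[c] = None
        t.root = c
        for d in (t.parent, t.blen, t.label, t.origin):
            d.pop(p, None)
        t.children.pop(p, None)
        t.origin.pop(c, None)
        pruned = _rebase(t)
        spec = GraftSpec(
            label=label, attach=c, attach_time=None,
            stem_length=stem + fold, tip_age=None,
        )
        return pruned, spec

    # suppress degree-2 internal node p: merge edges (pp,p)+(p,c)
    pp = t.parent[p]
    t.blen[c] = t.blen[c] + t.blen[p]
    t.parent[c] = pp
    pos = t.children[pp].index(p)
    t.children[pp][pos] = c
    for d in (t.parent, t.blen, t.label, t.origin):
        d.pop(p, None)
    t.children.pop(p, None)
    pruned = _rebase(t)
    attach_time = pruned.age - depth[p]
    spec = GraftSpec(
        label=label, attach=c, attach_time=attach_time,
        stem_length=stem, tip_age=None,
    )
    return pruned, spec


def prune_tips(
    tree: PhyloTree, labels: Iterable[str]
) -> tuple[PhyloTree, dict[str, GraftSpec]]:
    """Prune several tips; every returned spec is valid on the final tree.

    Tip removal is commutative on the surviving node ids, so each tip's
    re-graft spec is derived by pruning it last (after all the others).
    """
    labels = list(labels)
    final = tree
    for lab in labels:
        final, _ = prune_tip(final, lab)
    specs: dict[str, GraftSpec] = {}
    for lab in labels:
        t1 = tree
        for other in labels:
            if other != lab:
                t1, _ = prune_tip(t1, other)
        _, specs[lab] = prune_tip(t1, lab)
    return final, specs


def _rebase(t: PhyloTree) -> PhyloTree:
    """Reset edge origins to identity (the tree becomes its own base)."""
    origin = {v: v for v in t.parent if v != t.root}
    return PhyloTree(t.parent, t.children, t.blen, t.label, t.root,
                     origin=origin)


# ----------------------------------------------------------------------
# Brownian root state
# ----------------------------------------------------------------------
def brownian_root_state(tree: PhyloTree, tip_values: Mapping[str, float]) -> float:
    """Maximum-likelihood Brownian-motion root state.

    Equals the generalized-least-squares mean (1ᵀC⁻¹y)/(1ᵀC⁻¹1) with C the
    shared-path-length covariance among tips; also the weighted
    squared-change parsimony root.  Lies within [min(y), max(y)].
    """
    C, labels = tree.brownian_covariance()
    missing = [lab for lab in labels if lab not in tip_values]
    if missing:
        raise TreeError(f"missing tip values for: {missing}")
    y = np.array([float(tip_values[lab]) for lab in labels])
    if np.ptp(y) == 0:
        return float(y[0])
    if float(np.max(np.diag(C))) <= 0.0:
        raise TreeError("zero-depth tree: root state not identifiable")
    ones = np.ones(len(y))
    try:
        w = np.linalg.solve(C, ones)
        z = np.linalg.solve(C, y)
    except np.linalg.LinAlgError:
        Cp = np.linalg.pinv(C)
        w = Cp @ ones
        z = Cp @ y
    denom = float(ones @ w)
    if denom == 0.0:
        raise TreeError("singular covariance: root state not identifiable")
    return float(ones @ z / denom)


def brownian_rate(tree: PhyloTree, tip_values: Mapping[str, float]) -> float:
    """GLS estimate of the Brownian rate (trait variance per Myr).

    With mu the GLS root state and C the shared-path covariance,
    rate = (y - mu)' C^-1 (y - mu) / (n - 1).  Tip measurement noise
    inflates the estimate (it is attributed to the branches), which makes
    downstream variance terms built on it mildly conservative.
    """
    C, labels = tree.brownian_covariance()
    missing = [lab for lab in labels if lab not in tip_values]
    if missing:
        raise TreeError(f"missing tip values for: {missing}")
    y = np.array([float(tip_values[lab]) for lab in labels])
    mu = brownian_root_state(tree, tip_values) if np.ptp(y) > 0 else y[0]
    r = y - mu
    try:
        x = np.linalg.solve(C, r)
    except np.linalg.LinAlgError:
        x = np.linalg.pinv(C) @ r
    return float(r @ x / (len(y) - 1))
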