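"""Phylogenetic trees and model-specific among-species covariance matrices.

A rooted tree with branch lengths induces a covariance structure on the
tips under Brownian-motion trait evolution: ``Cov(i, j)`` is the depth of
the most recent common ancestor of tips *i* and *j*, and ``Var(i)`` is the
root-to-tip path length.  The alternative evolution models (Pagel's λ,
Ornstein–Uhlenbeck, early burst) are expressed here as deterministic
transforms of that Brownian covariance matrix.

Newick parsing and serialisation are delegated to :mod:`dendropy`; the
in-memory :class:`Tree` is a flat node table optimised for covariance
construction.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "TreeNode",
    "PhyloCovariance",
    "NewickError",
    "parse_newick",
    "write_newick",
    "vcv_matrix",
    "transform_covariance",
]


class NewickError(ValueError):
    """Raised for malformed or unsupported Newick input."""


@dataclass
class TreeNode:
    id: int
    parent: Optional[int]  # None for the root
    length: float          # branch length above this node (0.0 for root)
    label: Optional[str]   # tip label; None for internal nodes


@dataclass
class Tree:
    """Rooted phylogeny stored as a flat node table.

    Nodes are stored in an order where every parent precedes its
    children, so a single forward pass computes node depths.
    """

    nodes: list[TreeNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nodes:
            self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> TreeNode:
        return next(n for n in self.nodes if n.parent is None)

    @property
    def tips(self) -> list[TreeNode]:
        children = {n.parent for n in self.nodes if n.parent is not None}
        return [n for n in self.nodes if n.id not in children]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def children_of(self, node_id: int) -> list[TreeNode]:
        return [n for n in self.nodes if n.parent == node_id]

    def depths(self) -> dict[int, float]:
        """Distance from the root to every node."""
        depth: dict[int, float] = {}
        for n in self.nodes:
            depth[n.id] = 0.0 if n.parent is None else depth[n.parent] + n.length
        return depth

    @property
    def height(self) -> float:
        d = self.depths()
        return max(d[t.id] for t in self.tips)

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = self.depths()
        tip_depths = [d[t.id] for t in self.tips]
        h = max(tip_depths)
        return h == 0 or all(abs(td - h) <= tol * max(h, 1.0) for td in tip_depths)

    def validate(self) -> None:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for n in self.nodes:
            if n.parent is not None and n.parent not in ids:
                raise ValueError(f"node {n.id} references unknown parent {n.parent}")
            if not math.isfinite(n.length) or n.length < 0:
                raise ValueError(f"node {n.id} has invalid branch length {n.length}")
        # acyclicity / connectivity: every node must reach the root
        parent = {n.id: n.parent for n in self.nodes}
        for n in self.nodes:
            seen = set()
            cur: Optional[int] = n.id
            while cur is not None:
                if cur in seen:
                    raise ValueError("cycle detected in tree")
                seen.add(cur)
                cur = parent[cur]
        labels = [t.label for t in self.tips]
        if any(lab is None or lab == "" for lab in labels):
            raise ValueError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dups = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")

    # -- editing -----------------------------------------------------------

    def prune_to(self, keep: Sequence[str]) -> "Tree":
        """Return a copy restricted to the tips in ``keep`` (exact match
        after trimming whitespace).  Degree-2 internal nodes created by
        pruning are suppressed, merging branch lengths."""
        keep_set = {k.strip() for k in keep}
        missing = keep_set - {lab.strip() for lab in self.tip_labels}
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        dropped = [lab for lab in self.tip_labels if lab.strip() not in keep_set]
        if dropped:
            logger.info("pruning %d unmatched tips: %s", len(dropped), dropped)
        dt = _to_dendropy(self)
        taxa = [t for t in dt.taxon_namespace if t.label.strip() in keep_set]
        dt.retain_taxa(taxa)
        dt.suppress_unifurcations()
        return _from_dendropy(dt)


@dataclass
class PhyloCovariance:
    """Among-species covariance keyed by tip-label order.

    ``matrix[i, j]`` is the shared-ancestry covariance of tips *i* and
    *j*; for the plain Brownian structure this is the depth of their most
    recent common ancestor, and the diagonal holds root-to-tip path
    lengths.
    """

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance matrix must be square")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    def reorder(self, labels: Sequence[str]) -> "PhyloCovariance":
        idx = [self.labels.index(lab) for lab in labels]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels))

    @property
    def n(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dt: dendropy.Tree) -> Tree:
    nodes: list[TreeNode] = []
    ids: dict[int, int] = {}
    for i, nd in enumerate(dt.preorder_node_iter()):
        ids[id(nd)] = i
        parent = ids[id(nd.parent_node)] if nd.parent_node is not None else None
        length = nd.edge.length
        if length is None:
            if parent is None:
                length = 0.0  # root edge length is optional
            else:
                raise NewickError(
                    f"missing branch length on edge above node {i}"
                    + (f" (tip '{nd.taxon.label}')" if nd.taxon else "")
                )
        label = nd.taxon.label.strip() if (nd.is_leaf() and nd.taxon) else None
        if nd.is_leaf() and label in (None, ""):
            raise NewickError(f"tip node {i} has no label")
        nodes.append(TreeNode(id=i, parent=parent, length=float(length), label=label))
    return Tree(nodes)


def _to_dendropy(tree: Tree) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=ns)
    dnodes: dict[int, dendropy.Node] = {}
    for n in tree.nodes:
        if n.parent is None:
            dn = dt.seed_node
        else:
            dn = dendropy.Node()
            dnodes[n.parent].add_child(dn)
        dn.edge.length = n.length
        if n.label is not None:
            dn.taxon = ns.new_taxon(label=n.label)
        dnodes[n.id] = dn
    return dt


def parse_newick(text: str) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    Branch lengths are required on all edges except (optionally) the
    root.  Internal node labels are ignored with a logged warning;
    polytomies are accepted.  Malformed input, duplicate tip labels or
    missing branch lengths raise :class:`NewickError`.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    if text.count("(") != text.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    internal_labels = [nd.label for nd in dt.preorder_internal_node_iter() if nd.label]
    if internal_labels:
        logger.warning("ignoring %d internal node labels: %s", len(internal_labels), internal_labels)
    tree = _from_dendropy(dt)
    tree.validate()
    return tree


def write_newick(tree: Tree, path: Optional[str] = None) -> str:
    """Serialise a tree to Newick with 12-significant-digit branch lengths."""
    children: dict[int, list[TreeNode]] = {}
    for n in tree.nodes:
        if n.parent is not None:
            children.setdefault(n.parent, []).append(n)

    def emit(n: TreeNode) -> str:
        kids = children.get(n.id, [])
        if not kids:
            return f"{n.label}:{n.length:.12g}"
        inner = ",".join(emit(k) for k in kids)
        if n.parent is None:
            return f"({inner})"
        return f"({inner}):{n.length:.12g}"

    out = emit(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out + "\n")
    return out


def read_newick(path: str) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Covariance construction and model transforms
# ---------------------------------------------------------------------------

def vcv_matrix(tree: Tree) -> PhyloCovariance:
    """Brownian-motion covariance: MRCA depths off-diagonal, root-to-tip
    path lengths on the diagonal."""
    tree.validate()
    tips = tree.tips
    labels = [t.label for t in tips]
    tip_index = {t.id: i for i, t in enumerate(tips)}
    n = len(tips)
    depth = tree.depths()
    C = np.zeros((n, n))
    for t in tips:
        i = tip_index[t.id]
        C[i, i] = depth[t.id]

    children: dict[int, list[TreeNode]] = {}
    for nd in tree.nodes:
        if nd.parent is not None:
            children.setdefault(nd.parent, []).append(nd)

    # postorder accumulation of tip sets; cross-child tip pairs coalesce here
    def collect(nd: TreeNode) -> list[int]:
        kids = children.get(nd.id, [])
        if not kids:
            return [tip_index[nd.id]]
        groups = [collect(k) for k in kids]
        d = depth[nd.id]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])
                ib = np.asarray(groups[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        return [i for g in groups for i in g]

    collect(tree.root)
    return PhyloCovariance(C, labels)


def transform_covariance(
    C: PhyloCovariance,
    model: str,
    params: Optional[dict] = None,
) -> PhyloCovariance:
    """Transform a Brownian covariance to the structure implied by another
    trait-evolution model.

    Models
    ------
    ``BM``
        Identity.
    ``lambda``
        Pagel's λ: off-diagonals multiplied by ``lam`` ∈ [0, 1].
    ``OU``
        Stationary Ornstein–Uhlenbeck with pull ``alpha`` ≥ 0 on an
        ultrametric tree of height T:
        ``V_ij = exp(-2α(T - s_ij)) (1 - exp(-2α s_ij)) / (2α)``
        with ``s_ij`` the MRCA depth; the σ² scale is estimated
        separately.  As α → 0 this converges to the Brownian structure.
    ``EB``
        Early burst with decay rate ``a`` ≤ 0: every node depth d is
        remapped to ``(exp(a d) - 1)/a`` (the integral of the decaying
        rate along the path), applied elementwise to the MRCA-depth
        matrix.
    """
    params = params or {}
    M = C.matrix
    if model == "BM":
        out = M.copy()
    elif model == "lambda":
        lam = float(params.get("lam", 1.0))
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        out = M * lam
        np.fill_diagonal(out, np.diag(M))
    elif model == "OU":
        alpha = float(params.get("alpha", 0.0))
        if alpha < 0:
            raise ValueError(f"OU alpha must be >= 0, got {alpha}")
        diag = np.diag(M)
        T = diag.max()
        if T > 0 and not np.allclose(diag, T, rtol=1e-8):
            raise ValueError("OU transform requires an ultrametric tree")
        if alpha == 0.0:
            out = M.copy()
        else:
            s = M
            out = np.exp(-2.0 * alpha * (T - s)) * (-np.expm1(-2.0 * alpha * s)) / (2.0 * alpha)
    elif model == "EB":
        a = float(params.get("a", 0.0))
        if a > 0:
            raise ValueError(f"EB rate must be <= 0, got {a}")
        if a == 0.0:
            out = M.copy()
        else:
            out = np.expm1(a * M) / a
    else:
        raise ValueError(f"unknown model {model!r}; expected BM, lambda, OU or EB")
    return PhyloCovariance(out, list(C.labels))
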