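"""Phylogeny handling: Newick I/O, pruning, and Brownian-motion covariance.

A rooted tree with branch lengths induces the among-species covariance
expected under Brownian-motion trait evolution: the covariance between two
tips is the shared root-to-MRCA path length, and the variance of a tip is
its root-to-tip depth. Pagel's lambda rescales the shared (off-diagonal)
part of that matrix, interpolating between a star phylogeny (lambda = 0)
and pure Brownian structure (lambda = 1). Everything downstream (PGLS,
signal estimation, trait simulation) runs on these matrices.

Parsing and topology surgery are delegated to dendropy; the covariance
construction and lambda rescaling live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "parse_trees",
    "read_trees",
    "prune_to_taxa",
    "vcv",
    "lambda_transform",
    "check_ultrametric",
]


class TreeError(ValueError):
    """Malformed, mislabelled, or otherwise unusable phylogeny."""


def _validate(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise TreeError("tree has unlabelled tips")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue  # a missing root stem length is conventional
        if node.edge.length is None:
            raise TreeError(
                "missing branch length; branch lengths are required for "
                "covariance-based analyses"
            )
        if node.edge.length < 0:
            raise TreeError(f"negative branch length: {node.edge.length}")


class Phylogeny:
    """A rooted phylogeny with branch lengths and unique tip labels.

    Thin wrapper over a ``dendropy.Tree`` that enforces the invariants the
    comparative analyses need (unique labels, non-negative lengths) and
    exposes the covariance construction. Taxa are reported in alphabetical
    order so matrices built from different trees over the same species align.
    """

    def __init__(self, tree: dendropy.Tree):
        _validate(tree)
        self._tree = tree
        self.taxa: tuple[str, ...] = tuple(
            sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    # -- basic properties ---------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per taxon."""
        depths: dict[str, float] = {}
        stack = [(self._tree.seed_node, self._tree.seed_node.edge.length or 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf():
                depths[node.taxon.label] = d
            for child in node.child_nodes():
                stack.append((child, d + (child.edge.length or 0.0)))
        return depths

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    def scale_branches(self, factor) -> "Phylogeny":
        """Return a copy with every branch length multiplied.

        ``factor`` is a scalar, or an array with one multiplier per edge in
        preorder (used by the tree-jitter generator).
        """
        clone = self._tree.clone(depth=1)
        edges = [
            nd.edge for nd in clone.preorder_node_iter() if nd.edge.length is not None
        ]
        factors = np.broadcast_to(np.asarray(factor, dtype=float), (len(edges),))
        for edge, f in zip(edges, factors):
            edge.length = edge.length * float(f)
        return Phylogeny(clone)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"

    # -- analysis surface ---------------------------------------------

    def vcv(self) -> "PhyloCovariance":
        return vcv(self)

    def prune(self, keep) -> "Phylogeny":
        return prune_to_taxa(self, keep)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return check_ultrametric(self, tol)


@dataclass
class PhyloCovariance:
    """Among-species covariance matrix with its taxon ordering.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of taxa
    ``taxa[i]`` and ``taxa[j]``; the diagonal holds root-to-tip depths.
    Symmetric and positive semi-definite by construction.
    """

    matrix: np.ndarray
    taxa: tuple[str, ...]
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance matrix must be square")
        if self.matrix.shape[0] != len(self.taxa):
            raise ValueError("taxon list does not match matrix dimension")
        self.taxa = tuple(self.taxa)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def lambda_transform(self, lam: float) -> "PhyloCovariance":
        return lambda_transform(self, lam)

    def subset(self, taxa) -> "PhyloCovariance":
        """Submatrix for the given taxa, re-sorted alphabetically."""
        keep = sorted(taxa)
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in index]
        if missing:
            raise TreeError(f"taxa absent from covariance: {missing[:5]}")
        idx = np.array([index[t] for t in keep])
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], tuple(keep))

    def has_constant_diagonal(self, rtol: float = 1e-8) -> bool:
        d = np.diag(self.matrix)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=0.0))

    def lambda_decomposition(self):
        """Cached spectral factorization shared by the whole lambda profile.

        Writing D = diag(C), the diagonally normalized B = D^-1/2 C D^-1/2
        has unit diagonal, so C(lambda) = D^1/2 [lambda B + (1-lambda) I] D^1/2
        for every lambda: one eigendecomposition of B turns each lambda
        evaluation into a diagonal-weighted least squares. Returns
        ``(d, w, Q)`` with d the diagonal of C and B = Q diag(w) Q'.
        """
        if self._eig is None:
            d = np.diag(self.matrix).copy()
            if np.any(d <= 0):
                raise TreeError("zero root-to-tip depth: covariance singular")
            s = 1.0 / np.sqrt(d)
            B = self.matrix * np.outer(s, s)
            w, Q = np.linalg.eigh(B)
            self._eig = (d, w, Q)
        return self._eig


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick record into a :class:`Phylogeny`.

    Underscores in labels are preserved verbatim (no conversion to spaces).
    Raises :class:`TreeError` on malformed syntax, duplicate tip labels, or
    missing branch lengths.
    """
    if not text or not text.strip():
        raise TreeError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def parse_trees(text: str) -> list[Phylogeny]:
    """Parse a multi-tree Newick string (one record per ``;``)."""
    if not text or not text.strip():
        raise TreeError("empty Newick input")
    try:
        tl = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc
    if len(tl) == 0:
        raise TreeError("no trees found in input")
    return [Phylogeny(t) for t in tl]


def read_trees(path, max_trees: int | None = None) -> list[Phylogeny]:
    """Read a (possibly multi-tree) Newick file."""
    with open(path) as fh:
        trees = parse_trees(fh.read())
    if max_trees is not None:
        trees = trees[:max_trees]
    return trees


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict a tree to ``keep``, collapsing unifurcations.

    Root-to-tip path lengths of retained taxa are unchanged (branch lengths
    across collapsed degree-2 nodes are summed), so the pruned tree's
    covariance equals the submatrix of the full tree's covariance.
    """
    keep = set(keep)
    unknown = keep - set(tree.taxa)
    if unknown:
        raise TreeError(f"unknown taxa in prune set: {sorted(unknown)[:5]}")
    if len(keep) < 2:
        raise TreeError("pruning requires at least 2 taxa")
    extracted = tree.dendropy_tree.extract_tree_with_taxa_labels(labels=keep)
    return Phylogeny(extracted)


def vcv(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance matrix of a rooted tree.

    Built in one postorder pass: the edge above a node adds its length to
    every pair of tips in that node's clade (including self-pairs), which is
    exactly the shared-path-length definition.
    """
    taxa = tree.taxa
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    clade_tips: dict[int, np.ndarray] = {}
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            tips = np.array([index[node.taxon.label]])
        else:
            tips = np.concatenate([clade_tips.pop(id(c)) for c in node.child_nodes()])
        clade_tips[id(node)] = tips
        elen = node.edge.length
        if node is dtree.seed_node:
            elen = elen or 0.0  # root stem, usually absent
        if elen:
            C[np.ix_(tips, tips)] += elen
    return PhyloCovariance(C, taxa)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda rescaling: multiply off-diagonal entries by ``lam``.

    ``lam`` is restricted to [0, 1]; above 1 the matrix can lose positive
    definiteness, so 1 is also the upper search bound in estimation.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    d = np.diag(C.matrix).copy()
    M = C.matrix * lam
    np.fill_diagonal(M, d)
    return PhyloCovariance(M, C.taxa)


def check_ultrametric(tree: Phylogeny, tol: float = 1e-6) -> bool:
    """True iff all root-to-tip distances agree within ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    depths = np.array(list(tree.tip_depths().values()))
    return bool(depths.max() - depths.min() <= tol)
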