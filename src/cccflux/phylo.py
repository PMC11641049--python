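"""Distance-based phylogeny: p-distance, neighbor joining, bootstrap, Newick.

Implements the classic distance pipeline for protein families from first
principles: pairwise p-distances (proportion of differing residues over
shared non-gap columns), Saitou-Nei neighbor joining (exact on additive
distance matrices), nonparametric bootstrap by alignment-column resampling
with split supports mapped onto the full-data tree, and Newick
serialization that round-trips through this module's own parser.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .signatures import GAP, AlignedFamily


class PhyloError(ValueError):
    """Invalid distance matrix, alignment, or Newick input."""


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise PhyloError(f"matrix shape {v.shape} does not match {n} labels")
        if np.any(~np.isfinite(v)):
            raise PhyloError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise PhyloError("distance matrix diagonal is not zero")
        if np.any(v < 0):
            raise PhyloError("distances must be non-negative")
        self.values = v

    def to_phylip(self) -> str:
        """PHYLIP square-format text (relaxed label width)."""
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def p_distance(family: AlignedFamily, gap_mode: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing residues per sequence pair.

    ``gap_mode="pairwise"`` (default) compares each pair over the columns
    where both are non-gap; ``"complete"`` first drops every column with a
    gap in any sequence.  A pair with no comparable columns is an error
    naming the pair.
    """
    if len(family.rows) < 2:
        raise PhyloError("p-distance needs >= 2 sequences")
    if gap_mode not in ("pairwise", "complete"):
        raise PhyloError(f"unknown gap_mode {gap_mode!r}")
    arr = np.array([list(r) for r in family.rows])
    if gap_mode == "complete":
        keep = ~np.any(arr == GAP, axis=0)
        arr = arr[:, keep]
    n = len(family.ids)
    d = np.zeros((n, n))
    nongap = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise PhyloError(
                    f"no comparable columns between {family.ids[i]!r} and {family.ids[j]!r}"
                )
            diff = int(np.sum(arr[i, both] != arr[j, both]))
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(list(family.ids), d)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    """A rooted view of one node: leaf (name, no children) or internal."""

    name: str = ""
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]


@dataclass
class Tree:
    """An unrooted tree stored rooted at a trifurcation (NJ convention)."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def splits(self) -> dict[frozenset, TreeNode]:
        """Nontrivial bipartitions keyed canonically (side without the
        lexicographically first leaf is complemented)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def visit(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(visit(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                key = below if anchor in below else all_leaves - below
                out[key] = node
            return below

        visit(self.root)
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (the additivity oracle for NJ)."""
        # build an undirected adjacency over node ids
        adj: dict[int, list[tuple[int, float]]] = {}
        leaves: dict[int, str] = {}

        def walk(node: TreeNode) -> int:
            nid = id(node)
            adj.setdefault(nid, [])
            if node.is_leaf:
                leaves[nid] = node.name
            for c in node.children:
                cid = walk(c)
                adj[nid].append((cid, c.length))
                adj[cid].append((nid, c.length))
            return nid

        walk(self.root)
        names = sorted(leaves.values())
        index = {n: i for i, n in enumerate(names)}
        d = np.zeros((len(names), len(names)))
        for start, sname in leaves.items():
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other, oname in leaves.items():
                d[index[sname], index[oname]] = dist[other]
        return DistanceMatrix(names, d)


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Exact (topology and branch lengths) for additive input.  Negative
    branch-length estimates are clamped to zero with the deficit moved to
    the sibling branch so the pair's total is preserved; Q-matrix ties
    break on the lowest (i, j) index pair.
    """
    n = len(d.labels)
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in d.labels]
    dm = d.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        best, best_q = None, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        bi = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        bj = dm[i, j] - bi
        if bi < 0:
            bj = dm[i, j]  # sibling absorbs the deficit; pair total preserved
            bi = 0.0
        elif bj < 0:
            bi = dm[i, j]
            bj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = bi, bj
        new = TreeNode(children=[child_i, child_j])
        new_d = np.array(
            [0.5 * (dm[i, k] + dm[j, k] - dm[i, j]) for k in range(m) if k != i and k != j]
        )
        new_d = np.maximum(new_d, 0.0)
        keep = [k for k in range(m) if k != i and k != j]
        dm = dm[np.ix_(keep, keep)]
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, :-1] = new_d
        dm[:-1, -1] = new_d
        nodes = [nodes[k] for k in keep] + [new]

    # join the final three around the central (unrooted) node
    (a, b, c) = nodes
    dab, dac, dbc = dm[0, 1], dm[0, 2], dm[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return Tree(TreeNode(children=[a, b, c]))


def bootstrap_support(
    family: AlignedFamily,
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise",
) -> Tree:
    """Full-data NJ tree with bootstrap split supports (percent).

    Resamples alignment columns with replacement ``n_reps`` times, builds
    an NJ tree per replicate, and maps split frequencies onto the
    full-data tree.  Replicates whose resample leaves some pair with no
    comparable columns are dropped and counted (supports are percentages
    of completed replicates).
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    if family.n_columns < 1:
        raise PhyloError("alignment has no columns")
    tree = nj_tree(p_distance(family, gap_mode))
    target_splits = tree.splits()
    counts = {key: 0 for key in target_splits}
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in family.rows])
    completed = 0
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, family.n_columns, size=family.n_columns)
        rep = AlignedFamily(
            ids=list(family.ids),
            rows=["".join(row) for row in arr[:, cols]],
            reference_id=family.reference_id,
        )
        try:
            rep_splits = nj_tree(p_distance(rep, gap_mode)).splits()
        except PhyloError:
            dropped += 1
            continue
        completed += 1
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    if dropped:
        import warnings

        warnings.warn(f"{dropped} of {n_reps} bootstrap replicates dropped")
    for key, node in target_splits.items():
        node.support = 100.0 * counts[key] / completed if completed else float("nan")
    return tree


# ---------------------------------------------------------------------------
# Newick serialization

_UNQUOTED_SAFE = re.compile(r"^[^\s()\[\]{}:;,']+$")


def _format_label(label: str) -> str:
    if label == "":
        return ""
    if _UNQUOTED_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _node_newick(node: TreeNode, with_root_length: bool) -> str:
    if node.is_leaf:
        body = _format_label(node.name)
    else:
        inner = ",".join(_node_newick(c, True) for c in node.children)
        label = (
            _format_label(node.name)
            if node.name
            else (f"{node.support:g}" if node.support is not None else "")
        )
        body = f"({inner}){label}"
    if with_root_length:
        body += f":{node.length:.10g}"
    return body


def write_newick(tree: Tree) -> str:
    """Newick text with branch lengths; bootstrap supports become internal
    node labels (the common convention)."""
    return _node_newick(tree.root, False) + ";"


class _NewickParser:
    def __init__(self, text: str):
        self.text = text.strip()
        self.pos = 0

    def error(self, msg: str):
        raise PhyloError(f"Newick parse error at char {self.pos}: {msg}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> TreeNode:
        node = self.parse_node()
        if self.peek() != ";":
            self.error("expected ';'")
        return node

    def parse_node(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            node.children.append(self.parse_node())
            while self.peek() == ",":
                self.pos += 1
                node.children.append(self.parse_node())
            if self.peek() != ")":
                self.error("expected ')'")
            self.pos += 1
        label = self.parse_label()
        if node.children:
            # numeric internal labels are bootstrap supports
            try:
                node.support = float(label) if label else None
            except ValueError:
                node.name = label
        else:
            node.name = label
        if self.peek() == ":":
            self.pos += 1
            node.length = self.parse_number()
        return node

    def parse_label(self) -> str:
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    self.error("unterminated quoted label")
                ch = self.text[self.pos]
                if ch == "'":
                    if self.text[self.pos : self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(ch)
                self.pos += 1
            return "".join(out)
        m = re.match(r"[^\s()\[\]:;,']*", self.text[self.pos :])
        label = m.group(0)
        self.pos += len(label)
        return label

    def parse_number(self) -> float:
        m = re.match(r"[-+0-9.eE]+", self.text[self.pos :])
        if not m:
            self.error("expected branch length")
        self.pos += len(m.group(0))
        return float(m.group(0))


def read_newick(text: str) -> Tree:
    """Parse Newick text produced by :func:`write_newick` (or compatible)."""
    return Tree(_NewickParser(text).parse())
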