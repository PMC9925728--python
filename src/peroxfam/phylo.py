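"""Alignment editing, NJ trees with bootstrap, newick I/O, clade assignment.

This is the desk-scale stand-in for an external maximum-likelihood
workflow: alignments computed elsewhere are gap-edited (columns with more
than 50% gaps removed, strict inequality so the 0.50 boundary column is
kept), distances are p- or Poisson-corrected, trees come from classical
neighbor-joining, and supports from classical column-resampling bootstrap.
Externally built support-annotated newick trees are first-class inputs:
subfamily labels are read off the smallest enclosing reference clade either
way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    pass


class TreeError(ValueError):
    pass


@dataclass
class Alignment:
    """Equal-length aligned rows with unique ids; ``-`` is the gap char."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    ids, rows, chunks, rid = [], [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if rid is not None:
                    ids.append(rid)
                    rows.append("".join(chunks))
                rid, chunks = line[1:].split()[0], []
            elif line.strip():
                chunks.append(line.strip().upper())
    if rid is not None:
        ids.append(rid)
        rows.append("".join(chunks))
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), wrap):
                fh.write(row[i : i + wrap] + "\n")


def filter_gap_columns(
    aln: Alignment, threshold: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction strictly exceeds ``threshold``.

    Mirrors manual "remove regions containing more than 50% gaps" editing:
    a column exactly at the boundary (gap fraction == threshold) is kept.
    Returns the edited alignment and the removed column indices (0-based).
    The operation is idempotent.
    """
    if not aln.rows:
        return Alignment(ids=[], rows=[]), []
    mat = np.array([list(r) for r in aln.rows])
    gap_frac = (mat == "-").mean(axis=0)
    removed = [int(i) for i in np.where(gap_frac > threshold)[0]]
    kept = gap_frac <= threshold
    new_rows = ["".join(row) for row in mat[:, kept]]
    return Alignment(ids=list(aln.ids), rows=new_rows), removed


def distance_matrix(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances over mutually ungapped columns.

    ``model="p"`` is the raw proportion of differing sites; ``"poisson"``
    applies the Poisson correction d = -ln(1 - p).  Selenocysteine is
    scored as cysteine for distance purposes (logged once).  A pair with
    zero comparable columns, or p == 1 under Poisson, is an error.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if any("U" in r for r in aln.rows):
        logger.info("distance_matrix: treating selenocysteine U as C")
    mat = np.array([list(r.replace("U", "C")) for r in aln.rows])
    n = aln.n_rows
    d = np.zeros((n, n))
    ungapped = mat != "-"
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise AlignmentError(
                    f"no comparable columns between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = float((mat[i, both] != mat[j, both]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise AlignmentError(
                        f"p-distance 1.0 between {aln.ids[i]} and {aln.ids[j]}: "
                        "Poisson correction undefined"
                    )
                dist = -np.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=list(aln.ids))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor-joining; negative branch lengths clamped to zero."""
    if dm.shape[0] < 3:
        raise TreeError("neighbor-joining needs at least 3 taxa")
    tree = nj(dm, neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:  # pragma: no cover
            node.length = 0.0
    return tree


def leaf_names(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised to the side *without*
    the lexicographically smallest leaf."""
    leaves = frozenset(leaf_names(tree))
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = leaves - side
        out.add(side)
    return out


def bootstrap_support(
    aln: Alignment,
    B: int = 100,
    seed: int = 0,
    model: str = "p",
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with classical column-resampling bootstrap supports.

    ``B`` alignment replicates are drawn by sampling columns with
    replacement (seeded, reproducible); each internal bipartition's support
    is the percentage of replicate NJ trees containing it.  Supports are
    attached to the corresponding internal nodes as ``.support`` and as the
    node name so they survive newick round-trips.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tree = nj_tree(distance_matrix(aln, model=model))
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    cols = np.array([list(r) for r in aln.rows])
    n_cols = cols.shape[1]
    for _ in range(B):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row) for row in cols[:, idx]]
        rep = Alignment(ids=list(aln.ids), rows=rep_rows)
        try:
            rep_tree = nj_tree(distance_matrix(rep, model=model))
        except AlignmentError:  # degenerate resample; counts unchanged
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / B for bp, c in counts.items()}
    leaves = frozenset(leaf_names(tree))
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = leaves - side if anchor in side else side
        if canon in supports:
            node.support = supports[canon]
            node.name = f"{supports[canon]:g}"
    return tree, supports


def read_newick(path: str | Path) -> TreeNode:
    """Read newick; numeric internal-node labels become ``.support`` values."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise TreeError(f"{path}: empty newick file")
    try:
        tree = TreeNode.read(StringIO(text))
    except Exception as exc:
        raise TreeError(f"{path}: {exc}") from None
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    for node in tree.non_tips(include_self=True):
        support = getattr(node, "support", None)
        if support is not None and node.name is None:
            node.name = f"{support:g}"
    tree.write(str(path))


@dataclass(frozen=True)
class CladeAssignment:
    """Subfamily label read off the smallest enclosing reference clade."""

    query: str
    label: str | None
    cause: str = ""
    support: float | None = None
    clade_size: int = 0


def _candidate_sides(tree: TreeNode, query: str) -> list[tuple[frozenset[str], float | None]]:
    """Every edge-induced bipartition side containing the query, with the
    defining edge's support (if any)."""
    leaves = frozenset(leaf_names(tree))
    sides: dict[frozenset[str], float | None] = {}
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        support = getattr(node, "support", None)
        for side in (below, leaves - below):
            if query in side and len(side) < len(leaves):
                prev = sides.get(side)
                if side not in sides or (prev is None and support is not None):
                    sides[side] = support
    return list(sides.items())


def assign_clade(
    tree: TreeNode,
    reference_labels: Mapping[str, str],
    query: str,
    min_support: float | None = None,
) -> CladeAssignment:
    """Label a query by its smallest enclosing labelled reference clade.

    Unrooted semantics: a "clade" is an edge-induced bipartition side.  The
    smallest side containing the query and at least one labelled reference
    leaf defines the assignment; the label is granted iff every reference
    leaf in it shares one label and (when ``min_support`` is set) the
    defining edge's support passes.  When several minimal-size sides tie
    they must all agree on one pure label, otherwise the placement is
    ambiguous and reported as mixed.
    """
    if query not in set(leaf_names(tree)):
        raise TreeError(f"query {query!r} is not a leaf of the tree")
    candidates = [
        (side, support)
        for side, support in _candidate_sides(tree, query)
        if any(l in reference_labels for l in side if l != query)
    ]
    if not candidates:
        return CladeAssignment(query=query, label=None, cause="no enclosing labeled clade")
    min_size = min(len(side) for side, _ in candidates)
    minimal = [(side, s) for side, s in candidates if len(side) == min_size]
    verdicts = []
    for side, support in sorted(minimal, key=lambda t: tuple(sorted(t[0]))):
        labels = {reference_labels[l] for l in side if l in reference_labels and l != query}
        verdicts.append((side, support, labels))
    all_labels = set().union(*(v[2] for v in verdicts))
    if len(all_labels) > 1 or any(len(v[2]) != 1 for v in verdicts):
        return CladeAssignment(
            query=query, label=None, cause="mixed", clade_size=min_size
        )
    side, support, labels = verdicts[0]
    label = next(iter(all_labels))
    if min_support is not None and (support is None or support < min_support):
        return CladeAssignment(
            query=query, label=None, cause="low support",
            support=support, clade_size=min_size,
        )
    return CladeAssignment(
        query=query, label=label, support=support, clade_size=min_size
    )
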