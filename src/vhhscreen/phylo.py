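"""Neighbor-joining trees and homology clustering of top-ranked clones.

Pairwise distances are p-distances on global pairwise alignments (1 minus
the fraction of identical columns, terminal gaps excluded), suitable for the
small top-K clone sets this stage sees.  The tree is built with the
Saitou–Nei neighbor-joining algorithm using the Studier–Keppler Q
criterion, with deterministic tie-breaking so runs are bit-reproducible.
Clusters are maximal groups of leaves separated by a single tree edge whose
minimum pairwise homology clears a threshold; a cluster drawn from a single
library is called mono-specific, otherwise mixed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .annotate import alignment_stats

__all__ = [
    "SpecificityGroup",
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "extract_clusters",
    "write_clusters_tsv",
    "write_phylip",
    "library_of",
]


def pairwise_distance(a: str, b: str) -> float:
    """p-distance between two sequences under global alignment.

    ``1 - matches / columns`` where columns exclude terminal gap runs
    (overhangs are length differences, not substitutions); matches score 1,
    mismatches and internal gap columns 0.  The pair is aligned in a
    canonical argument order (optimal alignments are not unique, so this
    guarantees exact symmetry); 0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("pairwise_distance requires non-empty sequences")
    if b < a:
        a, b = b, a
    matches, _columns, ops = alignment_stats(a, b)
    while ops and ops[0][1] in "ID":
        ops = ops[1:]
    while ops and ops[-1][1] in "ID":
        ops = ops[:-1]
    columns = sum(n for n, _ in ops)
    if columns == 0:
        return 1.0
    matches = sum(n for n, op in ops if op == "=")
    return 1.0 - matches / columns


def distance_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distance matrix over labelled sequences."""
    labels = list(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[labels[i]], seqs[labels[j]])
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Studier–Keppler criterion
    ``Q(i,j) = (m-2) d(i,j) - r_i - r_j`` is joined, ties broken by the
    smallest (i, j) index pair in the current matrix order.  Limb lengths
    follow the standard formulas; a negative limb is clamped to zero with
    the deficit moved to its sister so the pair's summed length is
    preserved.  The unrooted result is returned as a tree whose root is the
    final trifurcation (or the final join for the three-taxon case).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm, dtype=float))
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = dm.data.astype(float).copy()
    if not np.all(np.isfinite(D)) or np.any(D < 0):
        raise ValueError("distances must be finite and non-negative")
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)  # row-major argmin = smallest (i, j) tie-break
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            li, lj = d_ij, 0.0
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    limbs = (
        (d01 + d02 - d12) / 2,
        (d01 + d12 - d02) / 2,
        (d02 + d12 - d01) / 2,
    )
    for node, limb in zip(nodes, limbs):
        node.length = float(max(0.0, limb))
    return TreeNode(children=nodes)


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string (labels quoted as needed)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string into a tree (inverse of :func:`write_newick`)."""
    return TreeNode.read(io.StringIO(text), format="newick")


@dataclass(frozen=True)
class SpecificityGroup:
    """A homology cluster of clones with its library composition."""

    group_id: str
    member_clone_ids: tuple[str, ...]
    library_composition: dict[str, int]
    specificity: str  # mono_specific | mixed
    min_pairwise_homology: float


def library_of(clone_id: str) -> str:
    """Library-of-origin encoded in a ``<library>_<rank>`` clone id."""
    return clone_id.rsplit("_", 1)[0]


def extract_clusters(
    tree: TreeNode,
    seqs: Mapping[str, str],
    homology_threshold: float,
    min_size: int = 2,
    libraries: Mapping[str, str] | None = None,
    dm: DistanceMatrix | None = None,
) -> list[SpecificityGroup]:
    """Tree-edge clusters whose minimum pairwise homology clears a threshold.

    Candidate clusters are both leaf sets of every tree bipartition (every
    rooting of the unrooted tree on one of its edges) plus the full leaf
    set; a candidate qualifies when every leaf pair inside it has homology
    (1 - p-distance) of at least ``homology_threshold`` and it has at least
    ``min_size`` members.  Overlapping candidates are resolved by preferring
    larger clusters, so the reported clusters are disjoint.  A cluster whose
    members all come from one library is mono-specific, otherwise mixed.
    """
    if not 0 < homology_threshold <= 1:
        raise ValueError("homology_threshold must lie in (0, 1]")
    leaves = [t.name for t in tree.tips()]
    for name in leaves:
        if name not in seqs:
            raise KeyError(f"no sequence for leaf {name!r}")
    if dm is None:
        dm = distance_matrix({name: seqs[name] for name in leaves})
    idx = {name: i for i, name in enumerate(dm.ids)}
    d = dm.data

    all_leaves = frozenset(leaves)
    candidates: set[frozenset[str]] = {all_leaves}
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset([node.name])
        candidates.add(side)
        candidates.add(all_leaves - side)

    def min_homology(group: frozenset[str]) -> float:
        ids = [idx[g] for g in group]
        sub = d[np.ix_(ids, ids)]
        return 1.0 - float(sub.max())

    passing = []
    for cand in candidates:
        if len(cand) < min_size:
            continue
        h = min_homology(cand)
        if h >= homology_threshold:
            passing.append((cand, h))
    # prefer larger clusters; deterministic order via sorted member tuples
    passing.sort(key=lambda ch: (-len(ch[0]), tuple(sorted(ch[0]))))

    taken: set[str] = set()
    groups: list[SpecificityGroup] = []
    lib = libraries if libraries is not None else {l: library_of(l) for l in leaves}
    for cand, h in passing:
        if cand & taken:
            continue
        taken |= cand
        members = tuple(sorted(cand))
        comp: dict[str, int] = {}
        for m in members:
            comp[lib[m]] = comp.get(lib[m], 0) + 1
        spec = "mono_specific" if len(comp) == 1 else "mixed"
        groups.append(SpecificityGroup("", members, comp, spec, h))
    return [
        SpecificityGroup(_group_letter(i), g.member_clone_ids, g.library_composition,
                         g.specificity, g.min_pairwise_homology)
        for i, g in enumerate(groups)
    ]


def _group_letter(i: int) -> str:
    if i < 26:
        return chr(ord("A") + i)
    return f"G{i + 1}"


def write_clusters_tsv(groups: Sequence[SpecificityGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tsize\tspecificity\tmin_homology\tcomposition\tmembers\n")
        for g in groups:
            comp = ",".join(f"{k}:{v}" for k, v in sorted(g.library_composition.items()))
            fh.write(
                f"{g.group_id}\t{len(g.member_clone_ids)}\t{g.specificity}\t"
                f"{g.min_pairwise_homology:.4f}\t{comp}\t{','.join(g.member_clone_ids)}\n"
            )


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for name, row in zip(dm.ids, dm.data):
            fh.write(name + "  " + " ".join(f"{x:.6f}" for x in row) + "\n")
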