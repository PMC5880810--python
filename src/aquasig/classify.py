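"""Subfamily classification: conserved-residue rules and NJ clade placement.

Two independent routes assign a query to PIP1 / PIP2 / TIP:

* residue rules — the Ar/R selectivity filter is FHTR in all PIPs while
  TIPs carry e.g. HIAR/HIGR; the PIP1/PIP2 split follows the
  water-permeability residue pair (TM2, loop E); TIP subtypes follow the
  loop-B phosphosite motifs (RXSXXR for alpha-TIPs, TXXR for delta-TIPs);
* clade placement — neighbor joining against a labelled reference panel,
  assigning the label of the smallest label-pure surrounding clade.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ValidationError
from .extraction import ResidueExtraction
from .seqio import Alignment

TIP_ARR_REPERTOIRE = {"HIAR", "HIGR", "HIAV", "AVGR"}  # common plant TIP filters
PIP1_PERMEABILITY = {("A", "I")}
PIP2_PERMEABILITY = {("I", "V"), ("V", "V")}


@dataclass(frozen=True)
class ClassLabel:
    class_name: str                 # PIP1 | PIP2 | TIP | unknown
    subtype: str = "n/a"            # alpha-TIP | delta-TIP | other | n/a
    evidence: tuple[str, ...] = ()
    method: str = "residues"        # residues | clade | both

    def __post_init__(self) -> None:
        if self.subtype != "n/a" and self.class_name != "TIP":
            raise ValidationError("subtype only applies to TIP labels")


def tip_subtype(loopB_context: str) -> str:
    """TIP subtype from the loop-B phosphosite context window.

    RXSXXR (phospho-Ser) marks alpha-TIPs; TXXR with the conserved Thr
    marks delta-TIPs; a conserved Thr with non-matching surroundings is
    reported as 'other'.
    """
    ctx = loopB_context.upper()
    if re.search(r"R.S..R", ctx):
        return "alpha-TIP"
    if re.search(r"T..R", ctx):
        return "delta-TIP"
    if "T" in ctx:
        return "other"
    return "other"


def classify_by_residues(ext: ResidueExtraction) -> ClassLabel:
    """Assign PIP1/PIP2/TIP from the extracted conserved residues."""
    evidence = []
    arr = ext.arr
    if arr == "FHTR":
        evidence.append("arr=FHTR (PIP filter)")
        pair = ext.permeability_pair
        if pair in PIP1_PERMEABILITY:
            evidence.append(f"permeability pair {pair} (PIP1, low)")
            return ClassLabel("PIP1", evidence=tuple(evidence))
        if pair in PIP2_PERMEABILITY:
            evidence.append(f"permeability pair {pair} (PIP2, high)")
            return ClassLabel("PIP2", evidence=tuple(evidence))
        evidence.append(f"permeability pair {pair} undetermined")
        return ClassLabel("unknown", evidence=tuple(evidence))
    if arr in TIP_ARR_REPERTOIRE:
        evidence.append(f"arr={arr} (TIP repertoire)")
        ctx = ext.loopB_context()
        subtype = tip_subtype(ctx) if ctx else "other"
        evidence.append(f"loopB context {ctx!r} -> {subtype}")
        return ClassLabel("TIP", subtype=subtype, evidence=tuple(evidence))
    evidence.append(f"arr={arr} matches no PIP/TIP rule")
    return ClassLabel("unknown", evidence=tuple(evidence))


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(m)):
            raise ValidationError("non-finite distances")
        if np.any(m < 0) or np.any(np.diag(m) != 0):
            raise ValidationError("distances must be nonnegative with zero diagonal")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)


def pdistance_matrix(alignment: Alignment, poisson: bool = False
                     ) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped columns.

    ``poisson=True`` applies the Poisson correction -ln(1 - p).
    """
    if len(alignment.records) < 3:
        raise AnalysisError("need at least 3 sequences for a distance matrix")
    rows = [np.frombuffer(rec.seq.encode(), dtype="S1") for rec in alignment]
    gap = np.bytes_(b"-")
    n = len(rows)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = (rows[i] != gap) & (rows[j] != gap)
        if not ok.any():
            raise AnalysisError(
                f"no comparable columns between "
                f"{alignment.records[i].id!r} and {alignment.records[j].id!r}")
        p = float(np.mean(rows[i][ok] != rows[j][ok]))
        if poisson:
            if p >= 1.0:
                raise AnalysisError("p-distance of 1 cannot be Poisson-corrected")
            p = -np.log(1.0 - p)
        m[i, j] = m[j, i] = p
    return DistanceMatrix(tuple(r.id for r in alignment), m)


@dataclass
class TreeNode:
    """Node of an (unrooted, stored rooted) phylogenetic tree."""

    name: str | None = None
    length: float = 0.0               # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.name for lf in self.leaves())

    def newick(self, precision: int = 6) -> str:
        return self._newick_inner(precision) + ";"

    def _newick_inner(self, precision: int) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.{precision}f}"
        inner = ",".join(ch._newick_inner(precision) for ch in self.children)
        return f"({inner}):{self.length:.{precision}f}"


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree with labelled leaves and nonnegative branch lengths."""

    root: TreeNode
    taxa: tuple[str, ...]

    def newick(self, precision: int = 6) -> str:
        # top-level node carries no branch; drop its length annotation
        inner = ",".join(ch._newick_inner(precision) for ch in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> list[tuple[frozenset[str], TreeNode]]:
        """Leaf set under every edge (child side), with the child node."""
        out = []

        def walk(node: TreeNode) -> None:
            for ch in node.children:
                out.append((ch.leaf_names(), ch))
                walk(ch)

        walk(self.root)
        return out


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the lowest (i, j) taxon-index pair of the
    current working list (stable w.r.t. input order); negative branch
    lengths are clamped to zero.
    """
    n = len(d.taxa)
    if n < 3:
        raise AnalysisError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in d.taxa]
    dist = d.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = dist[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        ni, nj = nodes[i], nodes[j]
        ni.length = max(li, 0.0)
        nj.length = max(lj, 0.0)
        parent = TreeNode(children=[ni, nj])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(dist.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (dist[i, c] + dist[j, c] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    # join the final three around an unrooted central node
    i, j, k = active
    dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(ln, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, taxa=d.taxa)


def assign_by_clade(tree: PhyloTree, panel_labels: dict[str, str],
                    queries: list[str] | None = None) -> dict[str, ClassLabel]:
    """Label each query by its smallest label-pure surrounding clade.

    For every edge of positive length, the side containing the query is
    a candidate clade (zero-length edges encode arbitrary resolutions
    of an ambiguous attachment and define no clade); among candidates
    whose panel leaves all share one label (other queries ignored), the
    smallest containing at least one panel leaf wins.  With no pure
    clade — e.g. a query sister to the entire panel — the query stays
    'unknown'.
    """
    all_leaves = tree.root.leaf_names()
    if queries is None:
        queries = sorted(all_leaves - set(panel_labels))
    sides = [(side, node.length) for side, node in tree.bipartitions()]
    out: dict[str, ClassLabel] = {}
    for q in queries:
        if q not in all_leaves:
            raise AnalysisError(f"query {q!r} absent from the tree")
        best: tuple[int, str] | None = None
        for side, edge_len in sides:
            if edge_len <= 1e-9:
                continue
            for clade in (side, all_leaves - side):
                if q not in clade:
                    continue
                labels = {panel_labels[t] for t in clade if t in panel_labels}
                if len(labels) != 1:
                    continue
                size = len(clade)
                if best is None or size < best[0]:
                    best = (size, labels.pop())
        if best is None:
            out[q] = ClassLabel("unknown", method="clade")
        else:
            label = best[1]
            subtype = "n/a"
            out[q] = ClassLabel(label if label in ("PIP1", "PIP2", "TIP")
                                else "unknown",
                                subtype=subtype,
                                evidence=(f"smallest pure clade size {best[0]}",),
                                method="clade")
    return out
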