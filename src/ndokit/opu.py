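"""Operational protein units and Poisson-corrected neighbor-joining trees.

Amplified clones are trimmed of their primer footprints, translated in the
frame set by the forward core's codon phase, clustered into operational
protein units (OPUs) by complete-linkage agglomeration on 1 - identity so
that *every* within-OPU pair meets the identity threshold (>= 98% by
default), and placed on neighbor-joining trees built from Poisson-corrected
distances d = -ln(1 - p) with bootstrap support over column resampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .codehop import PrimerPair
from .pcr import find_binding_sites
from .seqcore import translate

logger = logging.getLogger(__name__)

__all__ = [
    "OPUPartition",
    "DistanceMatrix",
    "trim_and_translate",
    "pairwise_protein_identity",
    "cluster_opus",
    "prepare_phylo_alignment",
    "poisson_distance",
    "neighbor_joining",
    "bootstrap_support",
    "nearest_reference_labels",
]


# ---------------------------------------------------------------------------
# Trimming and translation
# ---------------------------------------------------------------------------

def trim_and_translate(amplicon: str, pair: PrimerPair) -> str:
    """Strip both primer footprints and translate the insert.

    The reading frame is fixed by the forward core's codon phase: a core of
    length ``3k + r`` leaves ``r`` nucleotides of a partial codon at the
    primer's 3' end, so translation of the insert starts after the
    ``(3 - r) % 3`` nucleotides that complete it.  Trailing residues of a
    partial terminal codon are dropped with a logged warning.
    """
    fwd = [s for s in find_binding_sites(
        amplicon, pair.forward, core_len=pair.forward_core_len)
        if s.strand == "+"]
    if not fwd:
        raise ValueError("amplicon lacks a forward-primer footprint")
    rev = [s for s in find_binding_sites(
        amplicon, pair.reverse, core_len=pair.reverse_core_len)
        if s.strand == "-"]
    if not rev:
        raise ValueError("amplicon lacks a reverse-primer footprint")
    f, r = fwd[0], rev[-1]
    insert = amplicon[f.end:r.start]
    offset = (3 - pair.forward_core_len % 3) % 3
    coding = insert[offset:]
    if len(coding) % 3:
        logger.warning(
            "insert length %d not a codon multiple; dropping %d trailing nt",
            len(coding), len(coding) % 3)
    if len(coding) < 3:
        raise ValueError(
            "insert too short to translate; supply the frame explicitly by "
            "trimming the amplicon yourself")
    return translate(coding, 0)


# ---------------------------------------------------------------------------
# Identity and OPU clustering
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # gaps must not be cheaper than mismatches per position, and opening must
    # be expensive: otherwise a staggered alignment can smuggle a diverged
    # prefix into pseudo-terminal gaps and overstate identity
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    # ragged ends after trimming: terminal gaps nearly free, but not exactly
    # zero, so a terminal mismatch is not silently shifted into overhangs
    try:
        aligner.open_end_insertion_score = -1.0
        aligner.extend_end_insertion_score = -0.1
        aligner.open_end_deletion_score = -1.0
        aligner.extend_end_deletion_score = -0.1
    except AttributeError:  # older attribute names
        aligner.target_end_open_gap_score = -1.0
        aligner.target_end_extend_gap_score = -0.1
        aligner.query_end_open_gap_score = -1.0
        aligner.query_end_extend_gap_score = -0.1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_protein_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / columns, terminal gaps excluded.

    Semi-global semantics (free end gaps) so ragged clone ends do not count
    against identity.  Symmetric by canonical argument ordering.
    """
    if not a or not b:
        raise ValueError("identity of an empty sequence is undefined")
    if b < a:
        a, b = b, a
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # trim terminal gap columns (either row gapped at an end)
    start = 0
    while start < len(s1) and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    end = len(s1)
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(1 for i in range(start, end) if s1[i] == s2[i] and s1[i] != "-")
    return matches / (end - start)


@dataclass(frozen=True)
class OPUPartition:
    """A clustering of sequences into OPUs at an identity threshold.

    Labels are integers starting at 1, numbered by descending OPU size
    (ties by smallest member id).
    """

    members: Mapping[str, int]
    threshold: float

    @property
    def opu_sizes(self) -> Dict[int, int]:
        sizes: Dict[int, int] = {}
        for label in self.members.values():
            sizes[label] = sizes.get(label, 0) + 1
        return dict(sorted(sizes.items()))

    @property
    def proportions(self) -> Dict[int, float]:
        n = len(self.members)
        return {k: v / n for k, v in self.opu_sizes.items()}

    @property
    def n_opus(self) -> int:
        return len(set(self.members.values()))


def cluster_opus(
    seqs: Mapping[str, str] | Sequence[Tuple[str, str]],
    threshold: float = 0.98,
) -> OPUPartition:
    """Complete-linkage clustering on 1 - identity, cut at 1 - threshold.

    Complete linkage guarantees that every within-OPU pair has identity
    >= threshold.  Deterministic: ids are processed in lexicographic order
    and merges follow lowest distance first.
    """
    items = sorted(dict(seqs).items()) if not isinstance(seqs, Mapping) \
        else sorted(seqs.items())
    if not items:
        raise ValueError("no sequences to cluster")
    ids = [i for i, _ in items]
    if len(items) == 1:
        return OPUPartition(members={ids[0]: 1}, threshold=threshold)

    n = len(items)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_protein_identity(items[i][1], items[j][1])
            dist[i, j] = dist[j, i] = d
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="complete")
    raw = fcluster(tree, t=(1.0 - threshold) + 1e-12, criterion="distance")

    # relabel by descending size, ties by smallest member id
    groups: Dict[int, List[str]] = {}
    for rid, lab in zip(ids, raw):
        groups.setdefault(int(lab), []).append(rid)
    order = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    members = {rid: k + 1 for k, group in enumerate(order) for rid in group}
    return OPUPartition(members=members, threshold=threshold)


def nearest_reference_labels(
    seqs: Mapping[str, str],
    references: Mapping[str, str],
) -> Dict[str, Tuple[str, float]]:
    """Best global identity against a reference protein set, per sequence."""
    out = {}
    for rid, seq in sorted(seqs.items()):
        best = max(sorted(references.items()),
                   key=lambda kv: pairwise_protein_identity(seq, kv[1]))
        out[rid] = (best[0], pairwise_protein_identity(seq, best[1]))
    return out


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def prepare_phylo_alignment(
    msa: Sequence[Tuple[str, str]],
) -> Tuple[List[Tuple[str, str]], int]:
    """Complete deletion: drop every column containing a gap or unknown.

    Returns the reduced alignment and the surviving column count.
    """
    rows = list(msa)
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0][1])
    if any(len(s) != width for _, s in rows):
        raise ValueError("alignment rows have unequal widths")
    keep = [
        c for c in range(width)
        if all(s[c] not in "-.X?" for _, s in rows)
    ]
    if not keep:
        raise ValueError("no alignment columns survive complete deletion")
    reduced = [(rid, "".join(s[c] for c in keep)) for rid, s in rows]
    return reduced, len(keep)


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p), p = differing sites / L.

    Expects equal-length gapless sequences (use
    :func:`prepare_phylo_alignment` first).  Saturation (p >= 1) is an error.
    """
    if len(a) != len(b) or not a:
        raise ValueError("sequences must be nonempty and of equal length")
    p = sum(1 for x, y in zip(a, b) if x != y) / len(a)
    if p >= 1.0:
        raise ValueError(f"proportion of differences {p} >= 1: distance saturated")
    return -math.log(1.0 - p)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    ids: Tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_alignment(cls, msa: Sequence[Tuple[str, str]]) -> "DistanceMatrix":
        rows = list(msa)
        n = len(rows)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = poisson_distance(rows[i][1], rows[j][1])
        return cls(ids=tuple(r[0] for r in rows), matrix=m)


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[List["_Node"]] = None,
                 length: float = 0.0):
        self.name = name
        self.children = children or []
        self.length = length

    def leaves(self) -> List[str]:
        if not self.children:
            return [self.name]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6f}"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree as Newick.

    Deterministic: among tied minimum-Q pairs the first in id order wins.
    Negative branch lengths are clamped to zero and the deficit logged.
    """
    tree = _nj_tree(dm)
    return tree.newick()


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("negative branch length %.6g at %s clamped to 0",
                    length, context)
        return 0.0
    return length


def _nj_tree(dm: DistanceMatrix) -> _Node:
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [_Node(name=i) for i in dm.ids]
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li = _clamp(li, f"join({nodes[i].name or 'internal'})")
        lj = _clamp(lj, f"join({nodes[j].name or 'internal'})")
        nodes[i].length, nodes[j].length = li, lj
        new = _Node(children=[nodes[i], nodes[j]])
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = _clamp(li, "final")
    nodes[j].length = _clamp(lj, "final")
    nodes[k].length = _clamp(lk, "final")
    return _Node(children=[nodes[i], nodes[j], nodes[k]])


def _splits(tree: _Node, all_taxa: frozenset) -> set:
    """Nontrivial bipartitions, each canonicalised to the side without the
    lexicographically smallest taxon."""
    anchor = min(all_taxa)
    out = set()

    def walk(node: _Node):
        for child in node.children:
            if child.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_taxa) - 1:
                    canon = side if anchor not in side else all_taxa - side
                    out.add(canon)
            walk(child)

    walk(tree)
    return out


def bootstrap_support(
    alignment: Sequence[Tuple[str, str]],
    n_reps: int = 1000,
    seed: int = 0,
) -> Dict[frozenset, float]:
    """Bootstrap support (%) for each internal split of the reference NJ tree.

    Columns are resampled with replacement per replicate; each replicate's
    NJ tree (on Poisson distances) votes for the reference splits it
    contains.  Replicates where a distance saturates fall back to capping
    p at 1 - 1/(2L); this keeps the replicate usable and is logged.
    """
    rows = list(alignment)
    taxa = frozenset(r[0] for r in rows)
    L = len(rows[0][1])
    ref = _nj_tree(DistanceMatrix.from_alignment(rows))
    ref_splits = _splits(ref, taxa)
    if not ref_splits:
        return {}

    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in ref_splits}
    seq_arrays = {rid: np.frombuffer(s.encode(), dtype="S1") for rid, s in rows}
    ids = [r[0] for r in rows]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        n = len(ids)
        m = np.zeros((n, n))
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                a = seq_arrays[ids[i]][cols]
                b = seq_arrays[ids[j]][cols]
                p = float(np.mean(a != b))
                if p >= 1.0:
                    p = 1.0 - 1.0 / (2 * L)
                    logger.info("saturated replicate distance capped")
                m[i, j] = m[j, i] = -math.log(1.0 - p)
        rep = _nj_tree(DistanceMatrix(ids=tuple(ids), matrix=m))
        rep_splits = _splits(rep, taxa)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: 100.0 * c / n_reps for s, c in counts.items()}
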