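"""Seeded generators of synthetic inputs with planted structure.

Each generator takes an explicit integer seed (no hidden global state) and
emulates the statistical feature an analysis depends on: conserved motifs
at a controlled per-column conservation, coding sequences under a codon
usage model, clone sets with planted identity clusters, marker-gene-like
sequences with a planted first restriction site, and microplate assays with
planted adherence classes.  Conservation targets are enforced by exact
per-column substitution counts (round((1-c)*n) rows substituted), so a
stated conservation level is a guarantee rather than an expectation; the
substitution model is uniform over the 19 alternative residues, adequate
for threshold tests and intentionally non-biological.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .codehop import ProteinMSA
from .seqcore import CodonUsage, ECOLI_USAGE

__all__ = [
    "FamilySpec",
    "gen_protein_family",
    "gen_cds",
    "gen_clone_set",
    "gen_trflp_community",
    "gen_adherence_plate",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass(frozen=True)
class FamilySpec:
    """Geometry of a synthetic protein family.

    ``motifs`` maps 0-based consensus positions to planted amino-acid
    strings; ``flanks`` optionally pins further consensus residues (e.g. the
    clamp flanks of a primer-design fixture).  ``conservation`` applies to
    background columns, ``motif_conservation`` to motif columns.
    """

    n_seqs: int = 10
    length: int = 300
    motifs: Mapping[int, str] = field(default_factory=dict)
    flanks: Mapping[int, str] = field(default_factory=dict)
    conservation: float = 0.9
    motif_conservation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_seqs < 2:
            raise ValueError("a family needs at least 2 sequences")
        spans = sorted((pos, pos + len(m)) for pos, m in self.motifs.items())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("motifs overlap")
        for pos, m in self.motifs.items():
            if pos < 0 or pos + len(m) > self.length:
                raise ValueError(f"motif at {pos} outside protein length")
        if not (0.0 <= self.conservation <= 1.0
                and 0.0 <= self.motif_conservation <= 1.0):
            raise ValueError("conservation targets must lie in [0, 1]")


def gen_protein_family(spec: FamilySpec) -> ProteinMSA:
    """Generate an ungapped protein alignment with planted motifs.

    A consensus protein is drawn, motifs and pinned flank residues are
    written in, and every column is degraded to its conservation target by
    substituting exactly ``round((1-c) * n_seqs)`` rows with a uniformly
    chosen different residue.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    consensus = list(rng.choice(list(_AA), size=spec.length))
    motif_cols = set()
    for pos, motif in spec.motifs.items():
        for k, aa in enumerate(motif):
            consensus[pos + k] = aa
            motif_cols.add(pos + k)
    for pos, aa in spec.flanks.items():
        consensus[pos] = aa

    rows = [consensus.copy() for _ in range(spec.n_seqs)]
    for col in range(spec.length):
        c = spec.motif_conservation if col in motif_cols else spec.conservation
        n_sub = int(round((1.0 - c) * spec.n_seqs))
        if n_sub == 0:
            continue
        victims = rng.choice(spec.n_seqs, size=n_sub, replace=False)
        for v in victims:
            alternatives = [a for a in _AA if a != consensus[col]]
            rows[v][col] = alternatives[int(rng.integers(len(alternatives)))]

    records = [(f"seq{i + 1:03d}", "".join(row)) for i, row in enumerate(rows)]
    return ProteinMSA.from_records(records)


def gen_cds(protein: str, codon_usage: CodonUsage = ECOLI_USAGE,
            seed: int = 0) -> str:
    """Back-translate a protein by sampling codons by usage weight.

    ``translate(gen_cds(p), 0) == p`` for any protein of standard residues.
    """
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein.upper():
        ranked = codon_usage.ranked_codons(aa)
        names = [c for c, _ in ranked]
        weights = np.array([w for _, w in ranked], dtype=float)
        weights /= weights.sum()
        codons.append(names[int(rng.choice(len(names), p=weights))])
    return "".join(codons)


def gen_clone_set(
    template_protein: Optional[str] = None,
    cluster_spec: Sequence[Tuple[int, float]] = ((42, 0.01), (4, 0.01), (2, 0.01)),
    between_divergence: float = 0.1,
    length: int = 240,
    seed: int = 0,
) -> Dict[str, str]:
    """Protein clone set with planted identity clusters.

    Cluster centers are the template with a disjoint block of
    ``ceil(between_divergence * length)`` positions rewritten per cluster, so
    any two centers differ at >= 2 * between_divergence of sites.  Each
    member carries at most ``floor(max_divergence * length / 2)`` further
    substitutions, so within-cluster pairwise identity >= 1 - max_divergence
    by the triangle inequality.  Infeasible geometry (within >= between
    separation, or blocks exceeding the protein) raises.
    """
    rng = np.random.default_rng(seed)
    if template_protein is None:
        template_protein = "".join(rng.choice(list(_AA), size=length))
    L = len(template_protein)
    k = len(cluster_spec)
    block = int(np.ceil(between_divergence * L))
    if k * block > L:
        raise ValueError(
            f"{k} clusters x {block} diverged positions exceed protein length {L}")
    if any(max_div >= between_divergence for _, max_div in cluster_spec) and k > 1:
        raise ValueError(
            "within-cluster divergence must be smaller than between-cluster "
            "divergence for planted clusters to be separable")

    clones: Dict[str, str] = {}
    for ci, (n, max_div) in enumerate(cluster_spec):
        center = list(template_protein)
        for pos in range(ci * block, (ci + 1) * block):
            alternatives = [a for a in _AA if a != center[pos]]
            center[pos] = alternatives[int(rng.integers(len(alternatives)))]
        budget = int(max_div * L / 2)
        for m in range(n):
            member = center.copy()
            if budget > 0:
                n_mut = int(rng.integers(0, budget + 1))
                if n_mut:
                    sites = rng.choice(L, size=n_mut, replace=False)
                    for s in sites:
                        alternatives = [a for a in _AA if a != member[s]]
                        member[s] = alternatives[int(rng.integers(len(alternatives)))]
            clones[f"opu{ci + 1}_clone{m + 1:03d}"] = "".join(member)
    return clones


def gen_trflp_community(
    trf_lengths: Sequence[int],
    total_length: int = 1450,
    recognition: str = "AGCT",
    cut_after: int = 2,
    seed: int = 0,
) -> Dict[str, str]:
    """One sequence per taxon whose first restriction site sets its T-RF.

    The terminal (5'-labeled) fragment of taxon ``i`` is exactly
    ``trf_lengths[i]``: the recognition site is planted so the cut falls at
    that position and no earlier site occurs.  Lengths must be distinct by
    more than 1 bp and leave room for the site.
    """
    lengths = list(trf_lengths)
    srt = sorted(lengths)
    if any(b - a <= 1 for a, b in zip(srt, srt[1:])):
        raise ValueError("planted T-RF lengths must differ by more than 1 bp")
    if any(l < cut_after or l + len(recognition) - cut_after > total_length
           for l in lengths):
        raise ValueError("planted T-RF length infeasible for the total length")
    rng = np.random.default_rng(seed)
    out: Dict[str, str] = {}
    for i, trf in enumerate(lengths):
        start = trf - cut_after
        prefix = list(rng.choice(list(_NT), size=start))
        # scrub every site occurrence upstream of the planted one by mutating
        # one prefix base inside it; sites downstream of the cut are harmless
        # because only the first (terminal) fragment is detected.
        while True:
            combined = "".join(prefix) + recognition
            idx = combined.find(recognition)
            if idx == start:
                break
            pos = int(rng.integers(idx, min(idx + len(recognition), start)))
            alternatives = [b for b in _NT if b != prefix[pos]]
            prefix[pos] = alternatives[int(rng.integers(len(alternatives)))]
        tail_len = total_length - start - len(recognition)
        tail = "".join(rng.choice(list(_NT), size=tail_len))
        out[f"taxon{i + 1}"] = "".join(prefix) + recognition + tail
    return out


def gen_adherence_plate(
    n_isolates: int = 40,
    class_mix: Sequence[float] = (0.1, 0.225, 0.2, 0.475),
    noise_sd: float = 0.01,
    a_c: float = 0.2,
    n_replicates: int = 3,
    n_controls: int = 6,
    control_noise_sd: float = 0.002,
    seed: int = 0,
) -> Tuple[Dict[str, List[float]], List[float], Dict[str, str]]:
    """Microplate with planted adherence classes.

    Class counts follow the mix deterministically (largest-remainder
    apportionment).  Wells are drawn at class-representative multiples of
    the planted cutoff (0.5x, 1.5x, 3x, 6x A_C) with Gaussian noise.
    Returns (sample wells, negative-control wells, planted class per
    isolate).
    """
    from .assays import CATEGORIES

    mix = np.asarray(class_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9 or len(mix) != 4:
        raise ValueError("class_mix must be 4 fractions summing to 1")
    raw = mix * n_isolates
    counts = np.floor(raw).astype(int)
    remainder = n_isolates - counts.sum()
    order = np.argsort(-(raw - counts))
    for idx in order[:remainder]:
        counts[idx] += 1

    rng = np.random.default_rng(seed)
    multiples = (0.5, 1.5, 3.0, 6.0)
    samples: Dict[str, List[float]] = {}
    planted: Dict[str, str] = {}
    i = 0
    for cls, cnt in enumerate(counts):
        for _ in range(cnt):
            i += 1
            name = f"isolate{i:03d}"
            mean = multiples[cls] * a_c
            wells = [max(0.0, float(rng.normal(mean, noise_sd)))
                     for _ in range(n_replicates)]
            samples[name] = wells
            planted[name] = CATEGORIES[cls]
    controls = [max(0.0, float(rng.normal(a_c, control_noise_sd)))
                for _ in range(n_controls)]
    return samples, controls, planted
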