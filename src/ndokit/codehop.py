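"""Consensus-degenerate hybrid primer design from a protein alignment.

A hybrid primer has a non-degenerate 5' *clamp* (the most frequent codon of
each consensus amino acid flanking a conserved motif) and a short degenerate
3' *core* (the fully degenerate reverse translation of the motif itself,
here 4 amino acids).  Blocks qualify by per-column amino-acid conservation
(default >= 80%) and by the degeneracy of their core (default <= 64).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from . import seqcore
from .seqcore import (CodonUsage, DegenerateSeq, ECOLI_USAGE,
                      reverse_complement, reverse_translate_degenerate)

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinMSA",
    "ConservedBlock",
    "PrimerPair",
    "DesignError",
    "column_conservation",
    "find_conserved_blocks",
    "consensus_clamp",
    "build_primer",
    "design_primer_pairs",
]

GAP = "-"
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class DesignError(ValueError):
    """A primer cannot be constructed under the requested constraints."""


@dataclass(frozen=True)
class ProteinMSA:
    """A protein multiple alignment: (id, aligned string) rows of equal width."""

    records: Tuple[Tuple[str, str], ...]

    def __post_init__(self):
        if len(self.records) < 1:
            raise ValueError("alignment needs at least one row")
        widths = {len(seq) for _, seq in self.records}
        if len(widths) != 1:
            raise ValueError(f"rows have unequal widths: {sorted(widths)}")
        for rid, seq in self.records:
            bad = set(seq.upper()) - _AA20 - {GAP, "X"}
            if bad:
                raise ValueError(
                    f"record {rid!r} contains non-amino-acid characters {sorted(bad)}"
                )

    @classmethod
    def from_records(cls, records: Sequence[Tuple[str, str]]) -> "ProteinMSA":
        return cls(tuple((rid, seq.upper()) for rid, seq in records))

    @classmethod
    def from_file(cls, path, fmt: str = "fasta") -> "ProteinMSA":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "clustal" if fmt == "clustal" else "fasta")
        return cls.from_records([(r.id, str(r.seq)) for r in aln])

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, col: int) -> List[str]:
        if not 0 <= col < self.width:
            raise IndexError(f"column {col} outside alignment width {self.width}")
        return [seq[col] for _, seq in self.records]


@dataclass(frozen=True)
class ConservedBlock:
    """A window of alignment columns qualifying for a degenerate core."""

    start_col: int
    core_aa: str
    per_column_conservation: Tuple[float, ...]
    core_degeneracy: int

    @property
    def end_col(self) -> int:
        return self.start_col + len(self.core_aa)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse hybrid primers with the expected product size.

    Both primers are reported 5'->3' on their own strand; upper case marks
    the clamp, lower case the degenerate core.
    """

    forward: DegenerateSeq
    reverse: DegenerateSeq
    forward_block: ConservedBlock
    reverse_block: ConservedBlock
    expected_product_bp: int
    forward_core_len: int
    reverse_core_len: int

    @property
    def forward_core(self) -> str:
        return str(self.forward)[-self.forward_core_len:]

    @property
    def reverse_core(self) -> str:
        return str(self.reverse)[-self.reverse_core_len:]


def column_conservation(msa: ProteinMSA, col: int) -> Tuple[str, float]:
    """Majority residue and its fraction among non-gap residues of a column.

    Ties are broken by alphabetical residue order.  An all-gap column yields
    the sentinel ``('-', 0.0)``.
    """
    residues = [r.upper() for r in msa.column(col) if r != GAP]
    if not residues:
        return (GAP, 0.0)
    counts: dict = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    majority = min(counts, key=lambda r: (-counts[r], r))
    return majority, counts[majority] / len(residues)


def _gap_fraction(msa: ProteinMSA, col: int) -> float:
    column = msa.column(col)
    return sum(1 for r in column if r == GAP) / len(column)


def find_conserved_blocks(
    msa: ProteinMSA,
    core_len: int = 4,
    min_conservation: float = 0.8,
    max_degeneracy: int = 64,
    max_gap_fraction: float = 0.5,
) -> List[ConservedBlock]:
    """All core-length windows meeting conservation and degeneracy thresholds.

    Every column of a qualifying window has majority-residue conservation
    >= ``min_conservation`` among non-gap residues and gap fraction <=
    ``max_gap_fraction``; the degenerate reverse translation of the window
    consensus has degeneracy <= ``max_degeneracy``.  Overlapping qualifying
    windows are all reported, in alignment order.
    """
    if msa.width < core_len:
        raise ValueError(
            f"alignment width {msa.width} shorter than core length {core_len}"
        )
    blocks: List[ConservedBlock] = []
    for start in range(msa.width - core_len + 1):
        consensus = []
        fractions = []
        ok = True
        for col in range(start, start + core_len):
            if _gap_fraction(msa, col) > max_gap_fraction:
                ok = False
                break
            aa, frac = column_conservation(msa, col)
            if aa == GAP or aa == "X" or frac < min_conservation:
                ok = False
                break
            consensus.append(aa)
            fractions.append(frac)
        if not ok:
            continue
        core_aa = "".join(consensus)
        deg = reverse_translate_degenerate(core_aa).degeneracy
        if deg > max_degeneracy:
            continue
        blocks.append(
            ConservedBlock(
                start_col=start,
                core_aa=core_aa,
                per_column_conservation=tuple(fractions),
                core_degeneracy=deg,
            )
        )
    return blocks


def consensus_clamp(
    msa: ProteinMSA,
    block: ConservedBlock,
    side: str,
    clamp_aa: int = 6,
    codon_usage: CodonUsage = ECOLI_USAGE,
    extend_nt: int = 0,
    max_gap_fraction: float = 0.5,
) -> str:
    """Non-degenerate clamp from the consensus flank of a block.

    The ``clamp_aa`` columns adjacent to the block on the requested side are
    encoded, 5'->3' on the sense strand, by the top-ranked codon of each
    majority residue.  ``extend_nt=2`` lengthens the clamp with the first two
    (non-wobble) nucleotides of the top codon of one additional flanking
    residue: for the upstream (forward) side that residue sits at the
    clamp-core junction, for the downstream (reverse) side it is the residue
    farthest from the core.  Columns that are all-gap or exceed the gap
    fraction limit invalidate the clamp.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    if extend_nt not in (0, 2):
        raise ValueError("extend_nt must be 0 or 2")

    n_res = clamp_aa + (1 if extend_nt else 0)
    if side == "upstream":
        cols = range(block.start_col - n_res, block.start_col)
    else:
        cols = range(block.end_col, block.end_col + n_res)
    cols = list(cols)
    if cols[0] < 0 or cols[-1] >= msa.width:
        raise DesignError(
            f"block at column {block.start_col} ({block.core_aa!r}) has fewer "
            f"than {n_res} alignment columns on the {side} side"
        )

    residues = []
    for col in cols:
        if _gap_fraction(msa, col) > max_gap_fraction:
            raise DesignError(
                f"clamp column {col} of block {block.core_aa!r} is gapped in "
                f"more than {max_gap_fraction:.0%} of rows"
            )
        aa, _ = column_conservation(msa, col)
        if aa == GAP:
            raise DesignError(
                f"clamp column {col} of block {block.core_aa!r} is all-gap"
            )
        residues.append(aa)

    codons = [codon_usage.top_codon(aa) for aa in residues]
    if extend_nt == 0:
        return "".join(codons)
    if side == "upstream":
        # residues[0:clamp_aa] are full codons, the junction residue
        # (adjacent to the core) contributes its first two nucleotides.
        return "".join(codons[:clamp_aa]) + codons[clamp_aa][:2]
    # downstream: the farthest residue is truncated; on the antisense strand
    # (the reverse primer's own 5'->3') those two nucleotides lead the clamp.
    return "".join(codons[:clamp_aa]) + codons[clamp_aa][:2]


def build_primer(
    block: ConservedBlock,
    clamp: str,
    orientation: str = "forward",
    wobble_trim: Optional[bool] = None,
    max_degeneracy: int = 64,
) -> DegenerateSeq:
    """Assemble a hybrid primer: upper-case clamp + lower-case degenerate core.

    Forward primers are ``clamp + core``.  Reverse primers are the reverse
    complement of ``core + clamp`` (sense-strand footprint: motif followed by
    its downstream clamp), reported 5'->3' on the antisense strand.  The
    wobble-trim policy drops a 3'-terminal degenerate wobble position when
    doing so halves the degeneracy (default: on for forward, off for
    reverse, reproducing 11-nt forward / 12-nt reverse cores for 4-residue
    motifs).
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward|reverse, got {orientation!r}")
    if clamp and seqcore.degeneracy(clamp) != 1:
        raise DesignError(f"clamp {clamp!r} is not fully unambiguous")
    if wobble_trim is None:
        wobble_trim = orientation == "forward"

    core = str(reverse_translate_degenerate(block.core_aa)).upper()
    if wobble_trim and len(core) >= 1:
        last = core[-1]
        if len(seqcore.base_set(last)) == 2:
            core = core[:-1]

    if orientation == "forward":
        primer = DegenerateSeq(clamp.upper() + core.lower())
    else:
        sense = DegenerateSeq(core.lower() + clamp.upper())
        primer = sense.reverse_complement()

    if primer.degeneracy > max_degeneracy:
        raise seqcore.CapacityError(
            f"{orientation} primer degeneracy {primer.degeneracy} exceeds "
            f"max {max_degeneracy}"
        )
    return primer


def _consensus_positions(msa: ProteinMSA,
                         max_gap_fraction: float = 0.5) -> List[int]:
    """Alignment columns that survive into ungapped consensus coordinates."""
    return [c for c in range(msa.width) if _gap_fraction(msa, c) <= max_gap_fraction]


def design_primer_pairs(
    msa: ProteinMSA,
    core_len: int = 4,
    min_conservation: float = 0.8,
    max_degeneracy: int = 64,
    clamp_aa: int = 6,
    extend_nt: int = 0,
    codon_usage: CodonUsage = ECOLI_USAGE,
    product_range: Tuple[int, int] = (100, 3000),
    forward_wobble_trim: bool = True,
    reverse_wobble_trim: bool = False,
) -> List[PrimerPair]:
    """Pair every upstream block with every downstream block in product range.

    The expected product size is computed in ungapped consensus coordinates
    from the forward primer's 5' end to the reverse primer's 5' end,
    inclusive of both primers.
    """
    blocks = find_conserved_blocks(
        msa, core_len=core_len, min_conservation=min_conservation,
        max_degeneracy=max_degeneracy,
    )
    if len(blocks) < 2:
        logger.info("only %d qualifying block(s); no pairs designed", len(blocks))
        return []

    cons_cols = _consensus_positions(msa)
    col_to_ungapped = {c: i for i, c in enumerate(cons_cols)}

    pairs: List[PrimerPair] = []
    for up in blocks:
        for down in blocks:
            if down.start_col <= up.start_col:
                continue
            try:
                fwd_clamp = consensus_clamp(
                    msa, up, "upstream", clamp_aa, codon_usage, extend_nt)
                rev_clamp = consensus_clamp(
                    msa, down, "downstream", clamp_aa, codon_usage, extend_nt)
                forward = build_primer(up, fwd_clamp, "forward",
                                       forward_wobble_trim, max_degeneracy)
                reverse = build_primer(down, rev_clamp, "reverse",
                                       reverse_wobble_trim, max_degeneracy)
            except (DesignError, seqcore.CapacityError) as exc:
                logger.info("pair %s/%s rejected: %s", up.core_aa, down.core_aa, exc)
                continue
            try:
                u1 = col_to_ungapped[up.start_col]
                u2 = col_to_ungapped[down.start_col]
            except KeyError:
                logger.info("block outside consensus coordinates; pair skipped")
                continue
            # forward 5' end .. reverse 5' end, inclusive of both primers:
            # 3*(aa spacing) + core codons + both clamp lengths (nt).
            product = 3 * (u2 - u1) + 3 * core_len + len(fwd_clamp) + len(rev_clamp)
            # wobble trim shortens the forward footprint but not the span
            # between 5' ends, which is what gel sizing measures.
            if not product_range[0] <= product <= product_range[1]:
                logger.info(
                    "pair %s/%s product %d bp outside [%d, %d]",
                    up.core_aa, down.core_aa, product, *product_range)
                continue
            pairs.append(
                PrimerPair(
                    forward=forward,
                    reverse=reverse,
                    forward_block=up,
                    reverse_block=down,
                    expected_product_bp=product,
                    forward_core_len=len(str(forward)) - len(fwd_clamp),
                    reverse_core_len=len(str(reverse)) - len(rev_clamp),
                )
            )
    return pairs
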