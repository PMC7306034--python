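"""IUPAC nucleotide alphabet, degeneracy arithmetic and degenerate codon tables.

A degenerate oligonucleotide is written over the 15-letter IUPAC nucleotide
alphabet; each letter denotes a set of unambiguous bases and the whole string
denotes the Cartesian product of those sets.  The *degeneracy* of the string
is the size of that product, i.e. the number of distinct unambiguous
oligonucleotides it encodes.  Case carries provenance only (lower case marks
the 3' degenerate core of a hybrid primer) and never affects matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

from Bio.Seq import Seq

__all__ = [
    "IUPAC_SETS",
    "AlphabetError",
    "CapacityError",
    "DegenerateSeq",
    "base_set",
    "degeneracy",
    "expand",
    "reverse_complement",
    "translate",
    "reverse_translate_degenerate",
    "CodonUsage",
    "ECOLI_USAGE",
    "DEGENERATE_CODON",
    "GENETIC_CODE",
]


class AlphabetError(ValueError):
    """A character outside the IUPAC nucleotide alphabet."""


class CapacityError(ValueError):
    """An expansion request whose degeneracy exceeds the caller's cap."""


#: IUPAC nucleotide code -> set of unambiguous bases.
IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: Dict[frozenset, str] = {v: k for k, v in IUPAC_SETS.items()}
_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}


def base_set(code: str, position: int | None = None) -> frozenset:
    """Return the set of unambiguous bases denoted by one IUPAC code.

    Case-insensitive.  ``position`` (0-based) is only used to enrich the
    error message when the character is not in the alphabet.
    """
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        where = "" if position is None else f" at position {position}"
        raise AlphabetError(
            f"character {code!r}{where} is not an IUPAC nucleotide code"
        ) from None


def _validate(seq: str) -> None:
    for i, ch in enumerate(seq):
        base_set(ch, i)


def degeneracy(seq: "DegenerateSeq | str") -> int:
    """Number of distinct unambiguous sequences the IUPAC string encodes.

    Exact integer product of per-position base-set sizes.
    """
    s = str(seq)
    if not s:
        raise ValueError("degeneracy of an empty sequence is undefined")
    d = 1
    for i, ch in enumerate(s):
        d *= len(base_set(ch, i))
    return d


def expand(seq: "DegenerateSeq | str", cap: int = 4096) -> List[str]:
    """All unambiguous sequences encoded by ``seq``, lexicographically sorted.

    Raises :class:`CapacityError` when the degeneracy exceeds ``cap``.
    """
    s = str(seq)
    d = degeneracy(s)
    if d > cap:
        raise CapacityError(f"degeneracy {d} exceeds expansion cap {cap}")
    choices = [sorted(base_set(ch, i)) for i, ch in enumerate(s.upper())]
    return ["".join(p) for p in itertools.product(*choices)]


def _complement_code(code: str) -> str:
    comp = frozenset(_COMPLEMENT_BASE[b] for b in base_set(code))
    return _SET_TO_CODE[comp]


def reverse_complement(seq: "DegenerateSeq | str") -> "DegenerateSeq | str":
    """Reverse complement of an IUPAC string; per-position case is preserved.

    The complement of an ambiguity code is the code of the complemented base
    set (R<->Y, K<->M, S, W, N self-complementary, B<->V, D<->H).
    """
    s = str(seq)
    out = []
    for ch in reversed(s):
        c = _complement_code(ch)
        out.append(c.lower() if ch.islower() else c)
    rc = "".join(out)
    if isinstance(seq, DegenerateSeq):
        return DegenerateSeq(rc)
    return rc


@dataclass(frozen=True)
class DegenerateSeq:
    """An IUPAC-coded nucleotide string with degeneracy semantics.

    Lower-case positions mark degenerate-core provenance in hybrid primers;
    case never affects degeneracy, expansion or matching.
    """

    bases: str

    def __post_init__(self):
        if not self.bases:
            raise ValueError("DegenerateSeq cannot be empty")
        _validate(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.bases)

    def expand(self, cap: int = 4096) -> List[str]:
        return expand(self.bases, cap)

    def reverse_complement(self) -> "DegenerateSeq":
        return DegenerateSeq(str(reverse_complement(self.bases)))


# ---------------------------------------------------------------------------
# Translation and degenerate reverse translation (standard genetic code only)
# ---------------------------------------------------------------------------

_CODON_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: Dict[str, str] = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_CODON_BASES)
    for j, b in enumerate(_CODON_BASES)
    for k, c in enumerate(_CODON_BASES)
}

#: amino acid -> minimal fully-covering IUPAC codon.  Over-inclusive for
#: Arg (MGN also encodes some Ser), Leu (YTN also Phe) and Ser (WSN broad);
#: every standard codon of the amino acid is contained in the expansion.
DEGENERATE_CODON: Dict[str, str] = {
    "A": "GCN",
    "R": "MGN",
    "N": "AAY",
    "D": "GAY",
    "C": "TGY",
    "Q": "CAR",
    "E": "GAR",
    "G": "GGN",
    "H": "CAY",
    "I": "ATH",
    "L": "YTN",
    "K": "AAR",
    "M": "ATG",
    "F": "TTY",
    "P": "CCN",
    "S": "WSN",
    "T": "ACN",
    "W": "TGG",
    "Y": "TAY",
    "V": "GTN",
}


def translate(nt: str, frame: int = 0) -> str:
    """Translate an unambiguous nucleotide string in the given frame.

    Trailing partial codons are dropped; stops are emitted as ``*``.
    Ambiguous bases are rejected: expand the sequence first.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = nt.upper()
    _validate(s)
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            raise ValueError(
                f"ambiguous base {ch!r} at position {i}: expand the sequence "
                "before translating"
            )
    coding = s[frame:]
    if len(coding) < 3:
        raise ValueError(
            f"sequence too short to translate in frame {frame} "
            f"({len(nt)} nt)"
        )
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate())


def reverse_translate_degenerate(aa: str) -> DegenerateSeq:
    """Concatenate the minimal covering degenerate codon of each residue.

    Every true coding sequence of the input protein is contained in the
    expansion of the result.
    """
    if not aa:
        raise ValueError("cannot reverse-translate an empty protein")
    codons = []
    for i, res in enumerate(aa.upper()):
        try:
            codons.append(DEGENERATE_CODON[res])
        except KeyError:
            raise ValueError(
                f"unknown amino acid {res!r} at position {i}"
            ) from None
    return DegenerateSeq("".join(codons))


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

# E. coli K-12 usage, occurrences per thousand codons (coding, sense codons).
_ECOLI_PER_THOUSAND: Dict[str, float] = {
    "TTT": 22.2, "TTC": 16.6, "TTA": 13.9, "TTG": 13.7,
    "CTT": 11.0, "CTC": 11.0, "CTA": 3.9, "CTG": 52.6,
    "ATT": 30.3, "ATC": 25.1, "ATA": 4.4, "ATG": 27.9,
    "GTT": 18.3, "GTC": 15.3, "GTA": 10.9, "GTG": 26.4,
    "TCT": 8.5, "TCC": 8.6, "TCA": 7.2, "TCG": 8.9,
    "AGT": 8.8, "AGC": 16.1,
    "CCT": 7.0, "CCC": 5.5, "CCA": 8.4, "CCG": 23.2,
    "ACT": 9.0, "ACC": 23.4, "ACA": 7.1, "ACG": 14.4,
    "GCT": 15.3, "GCC": 25.5, "GCA": 20.1, "GCG": 33.6,
    "TAT": 16.2, "TAC": 12.2,
    "CAT": 12.9, "CAC": 9.7, "CAA": 15.3, "CAG": 28.8,
    "AAT": 17.7, "AAC": 21.7, "AAA": 33.6, "AAG": 10.3,
    "GAT": 32.1, "GAC": 19.1, "GAA": 39.4, "GAG": 17.8,
    "TGT": 5.2, "TGC": 6.4, "TGG": 15.2,
    "CGT": 20.9, "CGC": 22.0, "CGA": 3.6, "CGG": 5.4,
    "AGA": 2.1, "AGG": 1.2,
    "GGT": 24.7, "GGC": 29.6, "GGA": 8.0, "GGG": 11.1,
}


@dataclass(frozen=True)
class CodonUsage:
    """Ranked codon frequencies per amino acid.

    ``weights`` maps amino acid -> {codon: weight}; weights need not be
    normalised.  ``top_codon`` returns the highest-weight codon (ties broken
    alphabetically) and is what consensus-clamp construction consumes.
    """

    weights: Mapping[str, Mapping[str, float]]
    name: str = "custom"

    @classmethod
    def from_codon_frequencies(cls, freqs: Mapping[str, float],
                               name: str = "custom") -> "CodonUsage":
        by_aa: Dict[str, Dict[str, float]] = {}
        for codon, w in freqs.items():
            codon = codon.upper()
            aa = GENETIC_CODE.get(codon)
            if aa is None or aa == "*":
                continue
            by_aa.setdefault(aa, {})[codon] = float(w)
        return cls(weights=by_aa, name=name)

    @classmethod
    def from_cds(cls, sequences: Iterable[str], name: str = "estimated") -> "CodonUsage":
        """Estimate usage by counting codons of in-frame coding sequences."""
        counts: Dict[str, float] = {}
        for seq in sequences:
            s = seq.upper()
            for i in range(0, len(s) - len(s) % 3, 3):
                codon = s[i:i + 3]
                if set(codon) <= set("ACGT"):
                    counts[codon] = counts.get(codon, 0.0) + 1.0
        if not counts:
            raise ValueError("no countable codons in the supplied sequences")
        return cls.from_codon_frequencies(counts, name=name)

    def top_codon(self, aa: str) -> str:
        aa = aa.upper()
        table = self.weights.get(aa)
        if not table:
            raise ValueError(f"no codon usage recorded for amino acid {aa!r}")
        return max(sorted(table), key=lambda c: table[c])

    def ranked_codons(self, aa: str) -> List[Tuple[str, float]]:
        table = self.weights.get(aa.upper())
        if not table:
            raise ValueError(f"no codon usage recorded for amino acid {aa!r}")
        return sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))


ECOLI_USAGE = CodonUsage.from_codon_frequencies(_ECOLI_PER_THOUSAND,
                                                name="ecoli_k12")
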