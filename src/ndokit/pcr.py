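"""In-silico PCR: degenerate-primer binding sites and amplicon prediction.

Matching is set membership per position: a primer IUPAC code matches a
template base when the base lies in the code's base set.  The 3' degenerate
core must match exactly by default (extension chemistry); the 5' clamp
tolerates a configurable number of mismatches.  Templates are expected to be
sequenced molecules: ambiguity codes other than N are rejected, and N in the
template is treated as a wildcard (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .codehop import PrimerPair
from .seqcore import DegenerateSeq, base_set, reverse_complement

__all__ = [
    "BindingSite",
    "Amplicon",
    "match_position",
    "find_binding_sites",
    "predict_amplicons",
]


@dataclass(frozen=True)
class BindingSite:
    """One primer binding location, 0-based half-open on the forward strand."""

    template_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    clamp_mismatches: int
    core_exact: bool


@dataclass(frozen=True)
class Amplicon:
    """A predicted product spanning both primer footprints (half-open)."""

    template_id: str
    start: int
    end: int
    length_bp: int
    fwd_site: BindingSite
    rev_site: BindingSite

    @property
    def sequence_slice(self) -> slice:
        return slice(self.start, self.end)


def match_position(primer_code: str, template_base: str,
                   n_is_wildcard: bool = True) -> bool:
    """True iff the template base lies in the primer code's base set.

    Template N matches anything when ``n_is_wildcard`` (sequenced templates
    use N for undetermined positions).
    """
    b = template_base.upper()
    if b == "N":
        return n_is_wildcard
    return b in base_set(primer_code)


def _validate_template(template: str) -> str:
    t = template.upper()
    for i, ch in enumerate(t):
        if ch not in "ACGTN":
            if ch in "RYSWKMBDHV":
                raise ValueError(
                    f"template contains ambiguity code {ch!r} at position {i}; "
                    "in-silico PCR templates must be unambiguous (N allowed)"
                )
            raise ValueError(
                f"template contains non-nucleotide character {ch!r} at position {i}"
            )
    return t


def _scan_strand(template: str, primer: str, core_len: int,
                 max_clamp_mismatch: int, require_core_exact: bool,
                 n_is_wildcard: bool) -> List[Tuple[int, int, bool]]:
    """(start, clamp_mismatches, core_exact) of qualifying matches on one strand."""
    hits = []
    plen = len(primer)
    clamp_len = plen - core_len
    for start in range(len(template) - plen + 1):
        window = template[start:start + plen]
        core_exact = all(
            match_position(primer[i], window[i], n_is_wildcard)
            for i in range(clamp_len, plen)
        )
        if require_core_exact and not core_exact:
            continue
        mism = sum(
            0 if match_position(primer[i], window[i], n_is_wildcard) else 1
            for i in range(clamp_len)
        )
        if mism > max_clamp_mismatch:
            continue
        hits.append((start, mism, core_exact))
    return hits


def _core_len_of(primer: DegenerateSeq) -> int:
    """Length of the trailing lower-case (degenerate core) segment."""
    s = str(primer)
    n = 0
    for ch in reversed(s):
        if ch.islower():
            n += 1
        else:
            break
    return n if n else len(s)  # caseless primers: treat whole primer as core


def find_binding_sites(
    template: str,
    primer: DegenerateSeq,
    template_id: str = "template",
    max_clamp_mismatch: int = 2,
    require_core_exact: bool = True,
    core_len: Optional[int] = None,
    n_is_wildcard: bool = True,
) -> List[BindingSite]:
    """Qualifying binding sites on both strands, sorted by start coordinate.

    A site on the '-' strand means the primer anneals to the forward strand
    as written, i.e. its reverse complement appears in the template; the
    reported coordinates are always on the forward strand.
    """
    t = _validate_template(template)
    p = str(primer)
    if len(t) < len(p):
        return []
    clen = _core_len_of(primer) if core_len is None else core_len

    sites: List[BindingSite] = []
    for start, mism, core_exact in _scan_strand(
            t, p.upper(), clen, max_clamp_mismatch, require_core_exact,
            n_is_wildcard):
        sites.append(BindingSite(template_id, start, start + len(p), "+",
                                 mism, core_exact))
    # '-' strand: the primer binds the forward strand where its reverse
    # complement matches; the RC places the core first.
    rc = str(reverse_complement(p)).upper()
    for start, mism, core_exact in _scan_strand_rc(
            t, rc, clen, max_clamp_mismatch, require_core_exact, n_is_wildcard):
        sites.append(BindingSite(template_id, start, start + len(p), "-",
                                 mism, core_exact))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _scan_strand_rc(template: str, rc_primer: str, core_len: int,
                    max_clamp_mismatch: int, require_core_exact: bool,
                    n_is_wildcard: bool) -> List[Tuple[int, int, bool]]:
    """Scan for the reverse-complemented primer: core leads the window."""
    hits = []
    plen = len(rc_primer)
    for start in range(len(template) - plen + 1):
        window = template[start:start + plen]
        core_exact = all(
            match_position(rc_primer[i], window[i], n_is_wildcard)
            for i in range(core_len)
        )
        if require_core_exact and not core_exact:
            continue
        mism = sum(
            0 if match_position(rc_primer[i], window[i], n_is_wildcard) else 1
            for i in range(core_len, plen)
        )
        if mism > max_clamp_mismatch:
            continue
        hits.append((start, mism, core_exact))
    return hits


def predict_amplicons(
    template: str,
    pair: PrimerPair,
    template_id: str = "template",
    min_len: int = 100,
    max_len: int = 3000,
    max_clamp_mismatch: int = 2,
    require_core_exact: bool = True,
) -> List[Amplicon]:
    """All convergent primer-site combinations within the length window.

    Both orientations of the same physical product are predicted: forward
    primer on '+' with the reverse primer downstream on '-', and the mirror
    (reverse on '+', forward downstream on '-'), so predictions on a
    reverse-complemented template mirror those on the template.  Product
    length is measured from the 5' end of one primer to the 5' end of the
    other, inclusive of both primers.
    """
    fwd_sites = find_binding_sites(
        template, pair.forward, template_id, max_clamp_mismatch,
        require_core_exact, core_len=pair.forward_core_len)
    rev_sites = find_binding_sites(
        template, pair.reverse, template_id, max_clamp_mismatch,
        require_core_exact, core_len=pair.reverse_core_len)

    amplicons: List[Amplicon] = []
    for left, right in (
            ([s for s in fwd_sites if s.strand == "+"],
             [s for s in rev_sites if s.strand == "-"]),
            ([s for s in rev_sites if s.strand == "+"],
             [s for s in fwd_sites if s.strand == "-"])):
        for a in left:
            for b in right:
                if b.start < a.end:
                    continue
                length = b.end - a.start
                if min_len <= length <= max_len:
                    f, r = (a, b) if a in fwd_sites else (b, a)
                    amplicons.append(
                        Amplicon(template_id, a.start, b.end, length, f, r))
    amplicons.sort(key=lambda x: (x.start, x.end))
    return amplicons
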