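"""Crystal-violet adherence classification and isolate-table summaries.

Adherence follows the four-class cutoff scheme: with A the crystal-violet
absorbance (550 nm) of a sample and A_C the cutoff (negative-control mean
plus three standard deviations),

    non-adherent        A <= A_C
    weakly adherent     A_C < A <= 2 A_C
    moderately adherent 2 A_C < A <= 4 A_C
    strongly adherent   A > 4 A_C

The isolate summary reproduces taxonomy / degradation / gene-detection
cross-tabulations from a catalogue of isolates (genus, enrichment source,
naphthalene degradation call, NDO reductase gene detection).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "AdherenceCall",
    "IsolateRecord",
    "cutoff",
    "classify",
    "classify_plate",
    "load_isolate_table",
    "summarize_isolates",
]

CATEGORIES = (
    "non-adherent",
    "weakly adherent",
    "moderately adherent",
    "strongly adherent",
)


def cutoff(negative_controls: Sequence[float]) -> float:
    """Cutoff A_C = control mean + 3 x sample standard deviation (n-1)."""
    vals = list(negative_controls)
    if len(vals) < 2:
        raise ValueError("cutoff needs at least 2 negative-control wells")
    if any(v < 0 for v in vals):
        raise ValueError("absorbances must be nonnegative")
    return statistics.mean(vals) + 3.0 * statistics.stdev(vals)


def classify(a_sample: float, a_c: float) -> str:
    """Four-class adherence call; boundaries inclusive on the lower class."""
    if a_sample < 0:
        raise ValueError(f"negative absorbance {a_sample}")
    if a_c <= 0:
        raise ValueError(f"cutoff must be positive, got {a_c}")
    if a_sample <= a_c:
        return CATEGORIES[0]
    if a_sample <= 2 * a_c:
        return CATEGORIES[1]
    if a_sample <= 4 * a_c:
        return CATEGORIES[2]
    return CATEGORIES[3]


@dataclass(frozen=True)
class AdherenceCall:
    """One isolate's adherence category and raw A/A_C ratio.

    The ratio is reported alongside the category so extreme producers
    (ratios several-fold above the strongly-adherent bound) stay visible
    without inventing a fifth class.
    """

    isolate: str
    category: str
    ratio: float


def classify_plate(
    samples: Mapping[str, Sequence[float]],
    negative_controls: Sequence[float],
) -> List[AdherenceCall]:
    """Classify each isolate from its replicate wells.

    Replicate absorbances are averaged per isolate before classification.
    """
    a_c = cutoff(negative_controls)
    calls = []
    for isolate in sorted(samples):
        wells = list(samples[isolate])
        if not wells:
            raise ValueError(f"isolate {isolate!r} has no wells")
        a = statistics.mean(wells)
        calls.append(AdherenceCall(isolate=isolate,
                                   category=classify(a, a_c),
                                   ratio=a / a_c))
    return calls


# ---------------------------------------------------------------------------
# Isolate catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsolateRecord:
    """One catalogue row: taxonomy and functional calls for an isolate."""

    strain: str
    accession: str
    enrichment: str  # aerobic | oxygen-limited
    week: int
    nearest_neighbor: str
    lineage: str
    degrades_naphthalene: bool
    ndo_detected: bool

    @property
    def genus(self) -> str:
        return self.nearest_neighbor.split()[0]


def _parse_flag(value: str, field: str, strain: str) -> bool:
    v = str(value).strip()
    if v in ("+", "1", "True", "true", "yes"):
        return True
    if v in ("-", "0", "False", "false", "no"):
        return False
    raise ValueError(f"record {strain!r}: cannot parse {field}={value!r}")


def load_isolate_table(path=None) -> List[IsolateRecord]:
    """Load an isolate catalogue TSV (default: the packaged 40-strain table)."""
    if path is None:
        ref = resources.files("ndokit") / "data" / "table1_isolates.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"strain", "enrichment", "week", "nearest_neighbor",
                "degrades_naphthalene", "ndo_detected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isolate table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(IsolateRecord(
            strain=str(row["strain"]),
            accession=str(row.get("accession", "")),
            enrichment=str(row["enrichment"]),
            week=int(row["week"]),
            nearest_neighbor=str(row["nearest_neighbor"]),
            lineage=str(row.get("lineage", "")),
            degrades_naphthalene=_parse_flag(
                row["degrades_naphthalene"], "degrades_naphthalene",
                str(row["strain"])),
            ndo_detected=_parse_flag(
                row["ndo_detected"], "ndo_detected", str(row["strain"])),
        ))
    return records


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal."""
    if total == 0:
        return 0.0
    raw = Decimal(count) / Decimal(total) * 100
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_isolates(records: Sequence[IsolateRecord]) -> Dict:
    """Counts and percentages by genus, source and functional calls.

    Includes the concordance cells between degradation and gene detection:
    degraders in which the gene was not detected, and gene-positive
    non-degraders.
    """
    if not records:
        raise ValueError("no isolate records to summarize")
    n = len(records)

    def count_by(key) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in records:
            k = key(r)
            out[k] = out.get(k, 0) + 1
        return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))

    by_genus = count_by(lambda r: r.genus)
    by_source = count_by(lambda r: r.enrichment)
    degraders = [r for r in records if r.degrades_naphthalene]
    ndo_pos = [r for r in records if r.ndo_detected]

    return {
        "n_isolates": n,
        "by_genus": {g: {"count": c, "pct": _pct(c, n)}
                     for g, c in by_genus.items()},
        "by_enrichment": {s: {"count": c, "pct": _pct(c, n)}
                          for s, c in by_source.items()},
        "degraders": {
            "count": len(degraders),
            "pct": _pct(len(degraders), n),
            "by_genus": count_by(lambda r: r.genus) and {
                g: sum(1 for r in degraders if r.genus == g)
                for g in by_genus if any(r.genus == g for r in degraders)
            },
        },
        "ndo_positive": {
            "count": len(ndo_pos),
            "pct": _pct(len(ndo_pos), n),
            "by_genus": {
                g: sum(1 for r in ndo_pos if r.genus == g)
                for g in by_genus if any(r.genus == g for r in ndo_pos)
            },
        },
        "concordance": {
            "degraders_without_ndo": sum(
                1 for r in records if r.degrades_naphthalene and not r.ndo_detected),
            "ndo_positive_non_degraders": sum(
                1 for r in records if r.ndo_detected and not r.degrades_naphthalene),
        },
    }
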