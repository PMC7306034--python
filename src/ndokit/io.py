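"""File I/O: FASTA/Clustal readers with diagnostics, tabular writers.

All tabular output is TSV with a header row and '#' comment lines; nested
summaries are JSON.  Coordinates in every output are 0-based half-open.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from Bio import SeqIO

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_abundance_fasta",
    "read_profile_tsv",
    "write_tsv",
    "write_json",
]


def read_fasta(path) -> Dict[str, str]:
    """Read a (multi-)FASTA into an ordered id -> sequence mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Mapping[str, str] | Sequence[Tuple[str, str]],
                width: int = 70) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with _atomic(path) as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_abundance_fasta(path) -> Tuple[Dict[str, str], Dict[str, float]]:
    """FASTA whose headers carry ``abundance=<x>`` annotations.

    Records without the annotation default to abundance 1.
    """
    path = Path(path)
    seqs: Dict[str, str] = {}
    abund: Dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        a = 1.0
        for token in rec.description.split():
            if token.startswith("abundance="):
                a = float(token.split("=", 1)[1])
        abund[rec.id] = a
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs, abund


def read_profile_tsv(path) -> List[Tuple[str, float, float]]:
    """Read (sample, fragment length, area) rows from a peak-list TSV."""
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            try:
                rows.append((parts[0], float(parts[1]), float(parts[2])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
    return rows


class _atomic:
    """Write to a temp file in the target directory, then rename."""

    def __init__(self, path):
        self.path = Path(path)

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, self.tmp = tempfile.mkstemp(dir=str(self.path.parent),
                                        prefix=self.path.name + ".")
        self.fh = os.fdopen(fd, "w")
        return self.fh

    def __exit__(self, exc_type, *a):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence],
              comments: Sequence[str] = ()) -> None:
    with _atomic(path) as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_json(path, obj) -> None:
    with _atomic(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
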