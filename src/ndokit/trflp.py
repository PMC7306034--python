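"""In-silico T-RFLP: restriction digestion, terminal fragments, replicate
alignment at a length tolerance, and PCA of community profile matrices.

The marker amplicon is labeled at one end (the forward, 27F-equivalent end
here); after digestion with a 4-cutter (AluI, AG^CT) only the fragment
carrying the label is detected, so a community reduces to a peak list of
(terminal fragment length, relative area).  Replicate electropherograms are
merged into consensus profiles with a confidence interval on fragment
length (0.5 bp), and consensus matrices are ordinated by PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "TRFProfile",
    "ConsensusProfileMatrix",
    "digest",
    "terminal_fragment",
    "profile_from_community",
    "align_replicates",
    "pca",
]


def digest(seq: str, recognition: str = "AGCT", cut_after: int = 2) -> List[int]:
    """Ordered fragment lengths after cutting at every recognition site.

    The cut falls between positions ``cut_after - 1`` and ``cut_after`` of
    the site (AG^CT for AluI).  Site scanning is left-to-right and allows
    overlapping occurrences; fragment lengths sum to the sequence length.
    """
    s = seq.upper()
    site = recognition.upper()
    cuts = []
    i = s.find(site)
    while i != -1:
        cuts.append(i + cut_after)
        i = s.find(site, i + 1)
    bounds = [0] + cuts + [len(s)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def terminal_fragment(seq: str, labeled_end: str = "5prime",
                      recognition: str = "AGCT", cut_after: int = 2) -> int:
    """Length of the detected (labeled-end) fragment."""
    frags = digest(seq, recognition, cut_after)
    if labeled_end == "5prime":
        return frags[0]
    if labeled_end == "3prime":
        return frags[-1]
    raise ValueError(f"labeled_end must be 5prime|3prime, got {labeled_end!r}")


@dataclass(frozen=True)
class TRFProfile:
    """One electropherogram: (fragment length bp, relative area) peaks."""

    sample_id: str
    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        if any(length <= 0 for length, _ in self.peaks):
            raise ValueError("fragment lengths must be positive")
        total = sum(area for _, area in self.peaks)
        if self.peaks and abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative areas sum to {total}, expected 1")


def profile_from_community(
    sample_id: str,
    sequences: Mapping[str, str],
    abundances: Mapping[str, float],
    labeled_end: str = "5prime",
    recognition: str = "AGCT",
    cut_after: int = 2,
    length_noise_sd: float = 0.0,
    seed: int = 0,
) -> TRFProfile:
    """Digest a community of amplicons into one T-RF peak profile.

    Peak area is the relative abundance of the source sequence; taxa whose
    terminal fragments coincide are pooled.  ``length_noise_sd`` adds
    Gaussian sizing noise (bp) emulating capillary electrophoresis so the
    sub-bp binning of replicate alignment is exercised.
    """
    rng = np.random.default_rng(seed)
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("abundances must have positive total")
    pooled: Dict[float, float] = {}
    for taxon in sorted(sequences):
        trf = float(terminal_fragment(sequences[taxon], labeled_end,
                                      recognition, cut_after))
        if length_noise_sd > 0:
            trf += float(rng.normal(0.0, length_noise_sd))
        pooled[trf] = pooled.get(trf, 0.0) + abundances.get(taxon, 0.0) / total
    peaks = tuple(sorted(pooled.items()))
    return TRFProfile(sample_id=sample_id, peaks=peaks)


@dataclass(frozen=True)
class ConsensusProfileMatrix:
    """samples x binned-fragment-length matrix of relative areas."""

    sample_ids: Tuple[str, ...]
    bin_centers: Tuple[float, ...]
    matrix: np.ndarray  # rows: samples, columns: bins

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.sample_ids),
                            columns=[f"{c:.2f}" for c in self.bin_centers])


def _consensus_pair(a: Sequence[Tuple[float, float]],
                    b: Sequence[Tuple[float, float]],
                    tolerance: float) -> List[Tuple[float, float]]:
    """Greedy nearest-first matching of two replicate peak lists.

    Matched peaks merge to (mean length, mean area); peaks present in only
    one replicate are dropped (consensus-profile semantics).
    """
    candidates = [
        (abs(la - lb), i, j)
        for i, (la, _) in enumerate(a)
        for j, (lb, _) in enumerate(b)
        if abs(la - lb) <= tolerance
    ]
    candidates.sort()
    used_a, used_b = set(), set()
    merged = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        merged.append(((a[i][0] + b[j][0]) / 2.0, (a[i][1] + b[j][1]) / 2.0))
    merged.sort()
    return merged


def align_replicates(
    profiles: Sequence[TRFProfile],
    tolerance_bp: float = 0.5,
) -> ConsensusProfileMatrix:
    """Build a consensus matrix from replicate profiles.

    Profiles sharing a ``sample_id`` are replicates: their peaks are merged
    greedily nearest-first within the length tolerance, peaks missing from a
    replicate are dropped, and consensus areas are renormalised to sum to 1.
    Consensus peaks are then binned across samples with the same tolerance.
    """
    by_sample: Dict[str, List[TRFProfile]] = {}
    for p in profiles:
        by_sample.setdefault(p.sample_id, []).append(p)
    if not by_sample:
        raise ValueError("no profiles supplied")

    consensus: Dict[str, List[Tuple[float, float]]] = {}
    for sid, reps in sorted(by_sample.items()):
        peaks = list(reps[0].peaks)
        for rep in reps[1:]:
            peaks = _consensus_pair(peaks, list(rep.peaks), tolerance_bp)
        total = sum(a for _, a in peaks)
        if total > 0:
            peaks = [(l, a / total) for l, a in peaks]
        consensus[sid] = peaks

    # cross-sample binning: sorted lengths, new bin when the gap exceeds
    # the tolerance (planted T-RFs are separated by > 1 bp, so no chaining)
    all_lengths = sorted({l for peaks in consensus.values() for l, _ in peaks})
    bins: List[List[float]] = []
    for l in all_lengths:
        if bins and l - bins[-1][-1] <= tolerance_bp:
            bins[-1].append(l)
        else:
            bins.append([l])
    centers = [float(np.mean(b)) for b in bins]
    edges = [(b[0], b[-1]) for b in bins]

    sample_ids = tuple(sorted(consensus))
    matrix = np.zeros((len(sample_ids), len(centers)))
    for r, sid in enumerate(sample_ids):
        for l, a in consensus[sid]:
            for c, (lo, hi) in enumerate(edges):
                if lo - 1e-12 <= l <= hi + 1e-12:
                    matrix[r, c] += a
                    break
    return ConsensusProfileMatrix(sample_ids=sample_ids,
                                  bin_centers=tuple(centers), matrix=matrix)


def pca(matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal component analysis by SVD of the column-centered matrix.

    Returns (scores, loadings, explained_variance) with components ordered
    by descending eigenvalue of the covariance matrix.  Sign convention:
    the largest-magnitude loading of each component is positive.  Variances
    use the n-1 denominator and sum to the total variance of the data.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise ValueError("matrix has zero variance; PCA undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    explained = S ** 2 / (X.shape[0] - 1)
    return scores, Vt, explained
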