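"""TSS-based evaluation: average precision and unique-TSS coverage.

A region at rank i is relevant (o(i) = 1) iff it overlaps at least one
annotated transcription start site, optionally widened by a symmetric flank.
Precision at rank r is p(r) = sum_{i<=r} o(i) / r, and average precision for
a list of n regions is

    AP(n) = sum_{r=1..n} p(r) * o(r) / n.

Note the denominator is the total region count n, not the number of relevant
regions as in standard information-retrieval AP: appending an irrelevant
region to a list with AP > 0 strictly decreases this AP. The standard IR
variant (denominator = number of relevant regions) is available behind an
explicit flag for comparison.

Coverage C is the number of distinct TSS — deduplicated by
(chrom, pos, strand) — overlapped by at least one region; a region spanning
two TSS contributes both, two regions hitting one TSS contribute it once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .regions import TSSRecord


def _tss_positions_by_chrom(tss: Iterable[TSSRecord]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for t in tss:
        by.setdefault(t.chrom, []).append(t.pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def relevance(ordered_regions: Sequence, tss: Iterable[TSSRecord], flank: int = 0) -> np.ndarray:
    """Binary relevance vector o over an ordered region list.

    o(i) = 1 iff the region at rank i overlaps the closed window
    [pos - flank, pos + flank] of some TSS on the same chromosome. With
    flank = 0 this is point containment under the half-open convention:
    start <= pos < end. Regions on chromosomes absent from the annotation
    score 0 (they are kept, not dropped).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    positions = _tss_positions_by_chrom(tss)
    o = np.zeros(len(ordered_regions), dtype=np.int64)
    for i, reg in enumerate(ordered_regions):
        pos = positions.get(reg.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, reg.start - flank, side="left")
        hi = np.searchsorted(pos, reg.end + flank, side="left")
        if hi > lo:
            o[i] = 1
    return o


def precision_at(o: np.ndarray, r: int) -> float:
    """Precision at rank r: running mean of relevance through rank r."""
    o = np.asarray(o)
    if not 1 <= r <= o.size:
        raise ValueError(f"rank r={r} out of range 1..{o.size}")
    return float(o[:r].sum() / r)


def precision_trace(o: np.ndarray) -> np.ndarray:
    """p(r) for every r = 1..n in one pass."""
    o = np.asarray(o, dtype=float)
    return np.cumsum(o) / np.arange(1, o.size + 1)


def average_precision(o: np.ndarray, standard: bool = False) -> float:
    """Average precision of a relevance vector.

    Default: AP(n) = sum_r p(r) o(r) / n with denominator n, the full region
    count. With ``standard=True`` the conventional IR variant is computed
    instead (denominator = number of relevant regions; 0.0 if none).
    """
    o = np.asarray(o, dtype=float)
    if o.size == 0:
        raise ValueError("average precision is undefined for an empty list")
    p = precision_trace(o)
    num = float((p * o).sum())
    if standard:
        n_rel = float(o.sum())
        return num / n_rel if n_rel > 0 else 0.0
    return num / o.size


def coverage(regions: Sequence, tss: Iterable[TSSRecord], flank: int = 0) -> int:
    """Number of unique TSS overlapped by at least one region.

    Uniqueness key is (chrom, pos, strand): transcript isoforms sharing a
    start count once. Overlap uses the same flank-widened window as
    :func:`relevance`.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chrom, []).append((reg.start, reg.end))
    # merge region windows per chromosome so each TSS needs one binary search
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in spans:
            s, e = s - flank, e + flank
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    hit: set[tuple[str, int, str]] = set()
    for t in tss:
        key = (t.chrom, t.pos, t.strand)
        if key in hit or t.chrom not in merged:
            continue
        starts, ends = merged[t.chrom]
        i = np.searchsorted(starts, t.pos, side="right") - 1
        if i >= 0 and t.pos < ends[i]:
            hit.add(key)
    return len(hit)


@dataclass
class EvalReport:
    """Evaluation of one ordered region list against a TSS annotation."""

    mode_label: str
    n_regions: int
    average_precision: float
    coverage: int
    precision_trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def to_row(self) -> dict:
        return {
            "mode_label": self.mode_label,
            "n_regions": self.n_regions,
            "average_precision": self.average_precision,
            "coverage": self.coverage,
        }


def evaluate_list(
    ordered_regions: Sequence,
    tss: Iterable[TSSRecord],
    flank: int = 0,
    mode_label: str = "",
    standard_ap: bool = False,
) -> EvalReport:
    """Full evaluation of an ordered region list: AP, coverage and p(r) trace."""
    tss = list(tss)
    o = relevance(ordered_regions, tss, flank=flank)
    return EvalReport(
        mode_label=mode_label,
        n_regions=len(ordered_regions),
        average_precision=average_precision(o, standard=standard_ap),
        coverage=coverage(ordered_regions, tss, flank=flank),
        precision_trace=precision_trace(o),
    )
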