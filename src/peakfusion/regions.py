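"""Scored peak regions, TSS records, and BED-dialect file IO.

Coordinates are BED-style 0-based half-open throughout: a region covers base
positions ``start .. end-1``. Chromosome names are compared as exact strings;
an optional flag strips a leading ``chr`` prefix at read time, because silent
renaming turns real overlaps into false non-overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class PeakParseError(ValueError):
    """Raised when a peak or TSS file line cannot be parsed or validated."""


@dataclass(frozen=True)
class Region:
    """One genomic interval with a tag-count score.

    Parameters
    ----------
    chrom : str
        Chromosome name (exact-string semantics).
    start, end : int
        0-based half-open interval; ``start < end``.
    score : float
        Tag count (number of ChIP tags in the region); non-negative.
    source_id : str
        Identifier of the system that called the peak.
    region_id : str
        Stable identifier, unique within one :class:`PeakSet`.
    """

    chrom: str
    start: int
    end: int
    score: float
    source_id: str = ""
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.score < 0:
            raise ValueError(f"region {self.region_id!r}: negative score {self.score}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """Ordered collection of regions called by one system."""

    system_name: str
    regions: list[Region] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.regions)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate region_ids in PeakSet {self.system_name!r}")
        for r in self.regions:
            if r.source_id != self.system_name:
                raise ValueError(
                    f"region {r.region_id!r} has source_id {r.source_id!r}, "
                    f"expected {self.system_name!r}"
                )

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: the 5' end of an annotated transcript."""

    chrom: str
    pos: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")


def _maybe_strip_chr(chrom: str, strip: bool) -> str:
    if strip and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def read_peaks(
    path: str | Path,
    score_column: int = 4,
    system_name: str | None = None,
    strip_chr_prefix: bool = False,
) -> PeakSet:
    """Read a scored peak file into a :class:`PeakSet`.

    The file is tab-separated BED3+ with no header (``#``-prefixed header
    lines are skipped). ``score_column`` is the 1-based column holding the tag
    count; the default 4 fits ``chrom start end count`` files, while BED6
    callers put the score in column 5.
    """
    path = Path(path)
    name = system_name if system_name is not None else path.stem
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if len(fields) < score_column:
                raise PeakParseError(
                    f"{path}:{lineno}: score column {score_column} missing "
                    f"(line has {len(fields)} fields)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[score_column - 1])
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from None
            if score < 0:
                raise PeakParseError(
                    f"{path}:{lineno}: negative score {score} not allowed"
                )
            try:
                regions.append(
                    Region(
                        chrom=_maybe_strip_chr(fields[0], strip_chr_prefix),
                        start=start,
                        end=end,
                        score=score,
                        source_id=name,
                        region_id=f"{name}_{len(regions) + 1}",
                    )
                )
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from None
    if not regions:
        warnings.warn(f"{path}: no regions parsed; returning empty PeakSet")
    return PeakSet(system_name=name, regions=regions)


def read_tss(
    path: str | Path,
    mode: str = "point",
    strip_chr_prefix: bool = False,
) -> list[TSSRecord]:
    """Read TSS positions from a point file or a BED6 gene/transcript file.

    ``point`` mode reads ``chrom pos [strand [name]]`` lines (strand defaults
    to ``+``; strand never affects overlap testing). ``gene_bed`` mode requires
    >=6 columns and derives the TSS from the transcript 5' end: the start
    coordinate for ``+`` strand records, ``end - 1`` for ``-`` strand.

    Duplicate (chrom, pos, strand) triples are retained here; coverage
    counting deduplicates them.
    """
    if mode not in ("point", "gene_bed"):
        raise ValueError(f"mode must be 'point' or 'gene_bed', got {mode!r}")
    path = Path(path)
    records: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if mode == "point":
                    if len(fields) < 2:
                        raise PeakParseError(
                            f"{path}:{lineno}: point mode needs >=2 fields"
                        )
                    strand = fields[2] if len(fields) > 2 and fields[2] else "+"
                    name = fields[3] if len(fields) > 3 else ""
                    rec = TSSRecord(
                        chrom=_maybe_strip_chr(fields[0], strip_chr_prefix),
                        pos=int(fields[1]),
                        strand=strand,
                        name=name,
                    )
                else:
                    if len(fields) < 6:
                        raise PeakParseError(
                            f"{path}:{lineno}: gene_bed mode needs >=6 columns "
                            "including strand"
                        )
                    strand = fields[5]
                    start, end = int(fields[1]), int(fields[2])
                    pos = start if strand == "+" else end - 1
                    rec = TSSRecord(
                        chrom=_maybe_strip_chr(fields[0], strip_chr_prefix),
                        pos=pos,
                        strand=strand,
                        name=fields[3],
                    )
            except PeakParseError:
                raise
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


#: Column layout of write_fused output (1-based; combined score sits in
#: column 4 so the default read_peaks score column round-trips it).
FUSED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "combined_score",
    "combined_rank",
    "kind",
    "score_x",
    "score_y",
    "norm_x",
    "norm_y",
    "rank_x",
    "rank_y",
    "provenance",
]


def write_fused(path: str | Path, scored, order_by: str = "score_comb") -> None:
    """Write a scored fusion to a BED3+ file with documented extra columns.

    ``scored`` is a :class:`~peakfusion.scoring.ScoredFusion`. Rows are
    emitted in evaluation order (``order_by`` as accepted by
    :func:`~peakfusion.scoring.order_regions`). Floating columns use 6
    significant digits; a ``#``-prefixed header names the columns.
    """
    frame = scored.to_frame().iloc[scored.order_indices(order_by)]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(FUSED_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        str(row.start),
                        str(row.end),
                        f"{row.combined_score:.6g}",
                        f"{row.combined_rank:.6g}",
                        row.kind,
                        f"{row.score_x:.6g}",
                        f"{row.score_y:.6g}",
                        f"{row.norm_x:.6g}",
                        f"{row.norm_y:.6g}",
                        f"{row.rank_x:.6g}",
                        f"{row.rank_y:.6g}",
                        row.provenance,
                    ]
                )
                + "\n"
            )


def write_peaks(path: str | Path, peaks: PeakSet) -> None:
    """Write a PeakSet as a 4-column ``chrom start end score`` BED file."""
    with open(path, "w") as fh:
        for r in peaks:
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{score}\n")


def write_tss(path: str | Path, records: Sequence[TSSRecord] | Iterable[TSSRecord]) -> None:
    """Write TSS records as a point file: ``chrom pos strand name``."""
    with open(path, "w") as fh:
        for t in records:
            fh.write(f"{t.chrom}\t{t.pos}\t{t.strand}\t{t.name}\n")
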