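"""Union and intersection region sets of two peak systems.

The union U(x, y) contains every region called by either system, with
overlapping regions merged transitively into components spanning
[min start, max end). The intersection I(x, y) is the subset of merged
union regions that contain contributing regions from *both* systems, so
I(x, y) is a subset of U(x, y) and q <= p.

Merging is the connected-components relation of the pairwise-overlap graph:
chains such as x1-y1-x2 collapse into one region. Because intervals sorted
by start form an interval graph, a single linear sweep per chromosome that
tracks the running maximum end recovers exactly those components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .regions import PeakSet, Region


def overlaps(a: Region, b: Region) -> bool:
    """True iff the two regions share >=1 bp (half-open convention)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class FusedRegion:
    """A merged or single region in a union/intersection set.

    ``kind`` is ``merged`` when both systems contribute members, otherwise
    ``single_x``/``single_y`` (a single-system component may still contain
    several same-system regions merged through within-system overlap).
    """

    chrom: str
    start: int
    end: int
    members_x: tuple[Region, ...] = ()
    members_y: tuple[Region, ...] = ()

    def __post_init__(self) -> None:
        members = self.members_x + self.members_y
        if not members:
            raise ValueError("FusedRegion must have at least one member")
        if self.start != min(m.start for m in members):
            raise ValueError("start must equal the minimum member start")
        if self.end != max(m.end for m in members):
            raise ValueError("end must equal the maximum member end")

    @property
    def kind(self) -> str:
        if self.members_x and self.members_y:
            return "merged"
        return "single_x" if self.members_x else "single_y"

    @property
    def provenance(self) -> str:
        return ",".join(m.region_id for m in self.members_x + self.members_y)


@dataclass
class FusionSet:
    """The union U(x, y) or intersection I(x, y) of two peak sets."""

    mode: str  # "union" | "intersection"
    system_x: str
    system_y: str
    regions: list[FusedRegion] = field(default_factory=list)

    @property
    def p_or_q(self) -> int:
        return len(self.regions)

    def __post_init__(self) -> None:
        if self.mode not in ("union", "intersection"):
            raise ValueError(f"mode must be union or intersection, got {self.mode!r}")
        if self.mode == "intersection":
            bad = [r for r in self.regions if r.kind != "merged"]
            if bad:
                raise ValueError("intersection regions must all be merged")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def _components(tagged: list[tuple[Region, str]]) -> list[list[tuple[Region, str]]]:
    """Connected components of the overlap graph via sort + sweep.

    ``tagged`` holds (region, side) pairs from one chromosome. Sorting by
    (start, end) and cutting whenever the next start reaches the running max
    end yields the interval-graph components.
    """
    tagged = sorted(tagged, key=lambda t: (t[0].start, t[0].end))
    comps: list[list[tuple[Region, str]]] = []
    current: list[tuple[Region, str]] = []
    max_end = -1
    for item in tagged:
        region = item[0]
        if current and region.start >= max_end:
            comps.append(current)
            current = []
        current.append(item)
        max_end = max(max_end, region.end)
    if current:
        comps.append(current)
    return comps


def _fuse_component(comp: list[tuple[Region, str]]) -> FusedRegion:
    mx = tuple(r for r, side in comp if side == "x")
    my = tuple(r for r, side in comp if side == "y")
    members = mx + my
    return FusedRegion(
        chrom=members[0].chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        members_x=mx,
        members_y=my,
    )


def build_union(x: PeakSet, y: PeakSet, intra_merge: bool = True) -> FusionSet:
    """Construct U(x, y): all regions of both systems, overlaps merged.

    Cross-system overlapping regions always merge (transitively). With
    ``intra_merge`` (default), within-system overlap chains that never touch
    the other system also collapse into one single-system region; with
    ``intra_merge=False`` such regions pass through unmerged.

    Regions are returned sorted by (chrom, start, end). Either input may be
    empty, in which case the result is the other set as singles.
    """
    by_chrom: dict[str, list[tuple[Region, str]]] = {}
    for r in x:
        by_chrom.setdefault(r.chrom, []).append((r, "x"))
    for r in y:
        by_chrom.setdefault(r.chrom, []).append((r, "y"))

    fused: list[FusedRegion] = []
    for chrom in by_chrom:
        for comp in _components(by_chrom[chrom]):
            sides = {side for _, side in comp}
            if len(sides) == 1 and not intra_merge:
                for r, side in comp:
                    fused.append(
                        FusedRegion(
                            chrom=r.chrom,
                            start=r.start,
                            end=r.end,
                            members_x=(r,) if side == "x" else (),
                            members_y=(r,) if side == "y" else (),
                        )
                    )
            else:
                fused.append(_fuse_component(comp))
    fused.sort(key=lambda f: (f.chrom, f.start, f.end))
    return FusionSet(
        mode="union", system_x=x.system_name, system_y=y.system_name, regions=fused
    )


def build_intersection(x: PeakSet, y: PeakSet, intra_merge: bool = True) -> FusionSet:
    """Construct I(x, y): the merged components of U(x, y).

    Exactly the union regions with contributing members from both systems;
    their spans are unchanged, so I(x, y) region spans are a subset of the
    union's merged-region spans.
    """
    union = build_union(x, y, intra_merge=intra_merge)
    merged = [r for r in union.regions if r.kind == "merged"]
    return FusionSet(
        mode="intersection",
        system_x=x.system_name,
        system_y=y.system_name,
        regions=merged,
    )
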