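"""Shared fixtures and independent reference implementations (oracles).

The oracles deliberately take the slow, obvious route: the fusion oracle
builds the full pairwise-overlap graph and takes its connected components
via networkx; the evaluation oracles are naive double loops. They exist to
cross-check the sweep-line and vectorized implementations, never to share
code with them.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from peakfusion import PeakSet, Region, TSSRecord, overlaps


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def two_system_pair() -> tuple[PeakSet, PeakSet]:
    """The worked two-caller example used across modules.

    Union: merged [100,250) from x1+y1, single_x [500,600), single_y
    [800,900); normalized scores x {1, .5, 0}, y {1, 0, .5}; combined scores
    {1, .25, .25}; combined ranks {1, 2.5, 2.5}. Intersection: [100,250) only.
    """
    x = PeakSet("x", [
        Region("chr1", 100, 200, 10, "x", "x_1"),
        Region("chr1", 500, 600, 5, "x", "x_2"),
    ])
    y = PeakSet("y", [
        Region("chr1", 150, 250, 8, "y", "y_1"),
        Region("chr1", 800, 900, 4, "y", "y_2"),
    ])
    return x, y


def random_peakset(rng: np.random.Generator, name: str,
                   max_regions: int = 100, genome: int = 5000,
                   n_chroms: int = 2) -> PeakSet:
    """A random scored peak set dense enough to force overlap chains."""
    n = int(rng.integers(0, max_regions + 1))
    regions = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, genome - 1))
        width = int(rng.integers(1, 200))
        regions.append(Region(chrom, start, start + width,
                              float(rng.integers(0, 50)), name, f"{name}_{i+1}"))
    return PeakSet(name, regions)


def random_tss(rng: np.random.Generator, n: int = 50, genome: int = 5000,
               n_chroms: int = 2) -> list[TSSRecord]:
    return [
        TSSRecord(f"chr{int(rng.integers(1, n_chroms + 1))}",
                  int(rng.integers(0, genome)),
                  str(rng.choice(["+", "-"])))
        for _ in range(n)
    ]


# ----------------------------------------------------------------- oracles

def oracle_union_spans(x: PeakSet, y: PeakSet):
    """Connected components of the explicit pairwise-overlap graph.

    Returns sorted (chrom, start, end, kind) tuples — the ground truth for
    build_union under transitive within- and cross-system merging.
    """
    tagged = [(r, "x") for r in x] + [(r, "y") for r in y]
    g = nx.Graph()
    g.add_nodes_from(range(len(tagged)))
    for i in range(len(tagged)):
        for j in range(i + 1, len(tagged)):
            if overlaps(tagged[i][0], tagged[j][0]):
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        members = [tagged[i] for i in comp]
        sides = {side for _, side in members}
        kind = "merged" if sides == {"x", "y"} else f"single_{sides.pop()}"
        regs = [r for r, _ in members]
        out.append((regs[0].chrom, min(r.start for r in regs),
                    max(r.end for r in regs), kind))
    return sorted(out)


def oracle_relevance(regions, tss, flank=0):
    o = []
    for reg in regions:
        hit = 0
        for t in tss:
            if t.chrom == reg.chrom and reg.start <= t.pos + flank and t.pos - flank < reg.end:
                hit = 1
                break
        o.append(hit)
    return o


def oracle_average_precision(o):
    n = len(o)
    total = 0.0
    for r in range(1, n + 1):
        p_r = sum(o[:r]) / r
        total += p_r * o[r - 1]
    return total / n


def oracle_coverage(regions, tss, flank=0):
    seen = set()
    for t in tss:
        for reg in regions:
            if t.chrom == reg.chrom and reg.start <= t.pos + flank and t.pos - flank < reg.end:
                seen.add((t.chrom, t.pos, t.strand))
                break
    return len(seen)
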