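"""Seeded synthetic TSS annotations and imperfect peak-caller outputs.

The generator emulates the empirical structure of ChIP-seq peak calling for
TSS-proximal signals (e.g. H3K4me3): a fraction of each caller's peaks are
"true" peaks centred near a TSS with high tag counts, the rest are background
peaks placed uniformly with low tag counts. Two callers are correlated only
through a shared subset of true-peak TSS targets — the ``shared_frac`` knob
spans the diversity axis that drives how much union/intersection fusion can
add over either caller alone.

Defaults: peaks a few hundred bases wide (point-source peaks are ~500 bp),
centre displacement sd 100 bp (so some true peaks miss their TSS — the
relevance noise evaluation must tolerate), tag counts Poisson + 1 (a called
peak has at least one tag) with a 10x true/background mean ratio.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .regions import PeakSet, Region, TSSRecord

_TSS_STREAM = 1
_POOL_STREAM = 2


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    genome_length is the total simulated genome in bp, split evenly across
    n_chroms chromosomes named chr1..chrN.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 2
    n_tss: int = 200
    min_tss_spacing: int = 2_000
    n_peaks_per_caller: int = 300
    frac_true: float = 0.7
    shared_frac: float = 0.6
    peak_width_range: tuple[int, int] = (200, 800)
    offset_sd: float = 100.0
    lambda_true: float = 50.0
    lambda_bg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_true <= 1:
            raise ValueError("frac_true must be in [0, 1]")
        if not 0 <= self.shared_frac <= 1:
            raise ValueError("shared_frac must be in [0, 1]")
        if not self.lambda_true > self.lambda_bg > 0:
            raise ValueError("need lambda_true > lambda_bg > 0")
        if self.n_tss * self.min_tss_spacing >= self.genome_length:
            raise ValueError(
                f"infeasible TSS spacing: {self.n_tss} x {self.min_tss_spacing} bp "
                f"does not fit in {self.genome_length} bp"
            )
        wmin, wmax = self.peak_width_range
        if not 0 < wmin <= wmax:
            raise ValueError("peak_width_range must satisfy 0 < min <= max")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chroms

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_width_range"] = list(self.peak_width_range)
        return d


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _caller_stream(caller_id: str) -> int:
    # salt the RNG stream with the caller label so identical configs yield
    # distinct but reproducible peak sets per caller
    return 16 + zlib.crc32(caller_id.encode())


def simulate_tss(cfg: SimConfig) -> list[TSSRecord]:
    """Draw n_tss positions with pairwise spacing >= min_tss_spacing.

    TSS are spread over chromosomes proportionally to length (even split),
    positions drawn uniformly subject to the spacing constraint via the
    standard shift trick, strands uniform. Deterministic given cfg.seed.
    """
    rng = _rng(cfg, _TSS_STREAM)
    if cfg.n_tss == 0:
        return []
    counts = np.full(cfg.n_chroms, cfg.n_tss // cfg.n_chroms)
    counts[: cfg.n_tss % cfg.n_chroms] += 1
    L = cfg.chrom_length
    records: list[TSSRecord] = []
    for chrom, k in zip(cfg.chrom_names, counts):
        k = int(k)
        if k == 0:
            continue
        slack = L - (k - 1) * cfg.min_tss_spacing - 1
        if slack <= 0:
            raise ValueError(
                f"infeasible TSS spacing on {chrom}: {k} sites with "
                f"{cfg.min_tss_spacing} bp spacing exceed {L} bp"
            )
        base = np.sort(rng.integers(0, slack, size=k))
        pos = base + np.arange(k) * cfg.min_tss_spacing
        strands = rng.choice(["+", "-"], size=k)
        for j in range(k):
            records.append(
                TSSRecord(chrom=chrom, pos=int(pos[j]), strand=str(strands[j]),
                          name=f"{chrom}_tss{j + 1}")
            )
    return records


def shared_tss_pool(cfg: SimConfig, tss: list[TSSRecord]) -> np.ndarray:
    """Indices of the TSS subset common to both callers' true-peak targets.

    Pool size is round(shared_frac * n_tss); drawn once per experiment so
    every caller generated under the same config sees the same pool.
    """
    rng = _rng(cfg, _POOL_STREAM)
    size = int(round(cfg.shared_frac * len(tss)))
    return np.sort(rng.choice(len(tss), size=size, replace=False))


def simulate_caller(
    cfg: SimConfig,
    tss: list[TSSRecord],
    caller_id: str,
    shared_pool: np.ndarray | None = None,
) -> PeakSet:
    """Generate one imperfect peak-caller output.

    round(frac_true * n_peaks) true peaks target TSS — a shared_frac fraction
    of them drawn from the shared pool, the rest from the remaining TSS —
    with centres displaced by Normal(0, offset_sd), widths uniform in
    peak_width_range and tag counts Poisson(lambda_true) + 1. Remaining peaks
    are uniform background with Poisson(lambda_bg) + 1 tags. Deterministic
    given (cfg.seed, caller_id).
    """
    if cfg.frac_true > 0 and not tss:
        raise ValueError("frac_true > 0 requires a non-empty TSS set")
    rng = _rng(cfg, _caller_stream(caller_id))
    n_true = int(round(cfg.frac_true * cfg.n_peaks_per_caller))
    n_bg = cfg.n_peaks_per_caller - n_true

    targets: list[int] = []
    if n_true:
        if shared_pool is None:
            shared_pool = shared_tss_pool(cfg, tss)
        n_shared = int(round(cfg.shared_frac * n_true))
        others = np.setdiff1d(np.arange(len(tss)), shared_pool)
        if n_shared and len(shared_pool):
            targets.extend(
                rng.choice(shared_pool, size=n_shared,
                           replace=n_shared > len(shared_pool)).tolist()
            )
        n_rest = n_true - len(targets)
        pool = others if len(others) else np.arange(len(tss))
        if n_rest:
            targets.extend(
                rng.choice(pool, size=n_rest, replace=n_rest > len(pool)).tolist()
            )

    wmin, wmax = cfg.peak_width_range
    L = cfg.chrom_length
    regions: list[Region] = []

    for idx in targets:
        site = tss[int(idx)]
        width = int(rng.integers(wmin, wmax + 1))
        center = int(round(site.pos + rng.normal(0.0, cfg.offset_sd)))
        start = max(0, min(center - width // 2, L - width))
        regions.append(
            Region(
                chrom=site.chrom,
                start=start,
                end=start + width,
                score=float(rng.poisson(cfg.lambda_true) + 1),
                source_id=caller_id,
                region_id=f"{caller_id}_{len(regions) + 1}",
            )
        )
    for _ in range(n_bg):
        chrom = cfg.chrom_names[int(rng.integers(0, cfg.n_chroms))]
        width = int(rng.integers(wmin, wmax + 1))
        start = int(rng.integers(0, max(1, L - width)))
        regions.append(
            Region(
                chrom=chrom,
                start=start,
                end=start + width,
                score=float(rng.poisson(cfg.lambda_bg) + 1),
                source_id=caller_id,
                region_id=f"{caller_id}_{len(regions) + 1}",
            )
        )
    return PeakSet(system_name=caller_id, regions=regions)


def simulate_callers(
    cfg: SimConfig, tss: list[TSSRecord], caller_ids: list[str]
) -> dict[str, PeakSet]:
    """Generate several callers sharing one true-target TSS pool."""
    pool = shared_tss_pool(cfg, tss) if tss else np.empty(0, dtype=int)
    return {cid: simulate_caller(cfg, tss, cid, shared_pool=pool) for cid in caller_ids}
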