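"""Per-system rescoring, normalization, ranking and combination of fused regions.

Given a fusion set over systems x and y, each region receives a raw score per
system (the sum of that system's member tag counts, 0 for regions the system
did not call), which is min-max scaled to [0, 1] within the fusion set at
hand and ranked in descending order (rank 1 = highest score, tied scores
receive midranks). The score combination is the per-region mean of the two
normalized scores; the rank combination is the mean of the two ranks (lower
combined rank = better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .intervals import FusionSet


def assign_system_scores(fusion: FusionSet, side: str) -> np.ndarray:
    """Raw per-region score of one system over the fusion set.

    Single regions from the named side keep their own tag count, merged
    regions get the sum of that side's member tag counts, and regions with no
    members on that side score 0.
    """
    if side not in ("x", "y"):
        raise ValueError(f"side must be 'x' or 'y', got {side!r}")
    out = np.empty(len(fusion.regions))
    for i, reg in enumerate(fusion.regions):
        members = reg.members_x if side == "x" else reg.members_y
        out[i] = sum(m.score for m in members)
    return out


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Min-max scale raw scores to [0, 1] within the region set at hand.

    s* = (s - s_min) / (s_max - s_min). When every score is equal (including
    the single-region case) the scale is undefined; all values are set to 0.5
    so a constant column contributes neutrally to the half-weighted
    combination.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw.copy()
    s_min, s_max = raw.min(), raw.max()
    if s_max == s_min:
        return np.full_like(raw, 0.5)
    return (raw - s_min) / (s_max - s_min)


def rank_scores(raw: np.ndarray) -> np.ndarray:
    """Descending-order ranks: 1 = highest raw score; ties get midranks.

    Midranks keep the rank sum at p(p+1)/2 and make ranking symmetric and
    order-independent. Ranking the normalized scores would give the identical
    result since min-max scaling is monotone.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw.copy()
    return rankdata(-raw, method="average")


def combine_scores(s_x_star: np.ndarray, s_y_star: np.ndarray) -> np.ndarray:
    """Score combination: per-region mean of the two normalized scores."""
    return 0.5 * (np.asarray(s_x_star, dtype=float) + np.asarray(s_y_star, dtype=float))


def combine_ranks(r_x: np.ndarray, r_y: np.ndarray) -> np.ndarray:
    """Rank combination: per-region mean of the two ranks (lower = better)."""
    return 0.5 * (np.asarray(r_x, dtype=float) + np.asarray(r_y, dtype=float))


@dataclass
class ScoredFusion:
    """A fusion set with all per-system and combined scores attached.

    Arrays are aligned with ``fusion.regions`` (sorted genomic order).
    """

    fusion: FusionSet
    s_x_prime: np.ndarray
    s_y_prime: np.ndarray
    s_x_star: np.ndarray
    s_y_star: np.ndarray
    r_x_prime: np.ndarray
    r_y_prime: np.ndarray
    s_comb: np.ndarray
    r_comb: np.ndarray

    @classmethod
    def from_fusion(cls, fusion: FusionSet) -> "ScoredFusion":
        sx = assign_system_scores(fusion, "x")
        sy = assign_system_scores(fusion, "y")
        sxs, sys_ = normalize_scores(sx), normalize_scores(sy)
        rx, ry = rank_scores(sx), rank_scores(sy)
        return cls(
            fusion=fusion,
            s_x_prime=sx,
            s_y_prime=sy,
            s_x_star=sxs,
            s_y_star=sys_,
            r_x_prime=rx,
            r_y_prime=ry,
            s_comb=combine_scores(sxs, sys_),
            r_comb=combine_ranks(rx, ry),
        )

    def order_indices(self, by: str = "score_comb") -> np.ndarray:
        """Indices into ``fusion.regions`` in evaluation order.

        ``score_comb``: descending combined score. ``rank_comb``: ascending
        combined rank value. ``system_x``/``system_y``: descending raw side
        score. Ties are broken by (chrom, start, end) ascending so outputs
        are reproducible across runs and platforms.
        """
        keys = {
            "score_comb": -self.s_comb,
            "rank_comb": self.r_comb,
            "system_x": -self.s_x_prime,
            "system_y": -self.s_y_prime,
        }
        if by not in keys:
            raise ValueError(f"unknown ordering {by!r}; choose from {sorted(keys)}")
        regs = self.fusion.regions
        order = sorted(
            range(len(regs)),
            key=lambda i: (keys[by][i], regs[i].chrom, regs[i].start, regs[i].end),
        )
        return np.asarray(order, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        regs = self.fusion.regions
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in regs],
                "start": [r.start for r in regs],
                "end": [r.end for r in regs],
                "combined_score": self.s_comb,
                "combined_rank": self.r_comb,
                "kind": [r.kind for r in regs],
                "score_x": self.s_x_prime,
                "score_y": self.s_y_prime,
                "norm_x": self.s_x_star,
                "norm_y": self.s_y_star,
                "rank_x": self.r_x_prime,
                "rank_y": self.r_y_prime,
                "provenance": [r.provenance for r in regs],
            }
        )


def order_regions(scored: ScoredFusion, by: str = "score_comb") -> list:
    """The fused regions in evaluation order (see ScoredFusion.order_indices)."""
    return [scored.fusion.regions[i] for i in scored.order_indices(by)]
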