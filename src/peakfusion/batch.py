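"""All-pairs fusion experiment: every single system and every 2-combination.

For k input systems the driver evaluates the k singles (each ordered by its
own tag counts) and all k(k-1)/2 unordered pairs under
{intersection, union} x {score, rank} combination, reporting average
precision and unique-TSS coverage for each list. A pair is a *positive case*
for a metric when it performs at least as well as the better of its two
component systems, and a negative case otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .evaluation import evaluate_list
from .intervals import build_intersection, build_union
from .regions import PeakSet, TSSRecord
from .scoring import ScoredFusion, order_regions

_MODE_GLYPH = {"intersection": "*", "union": "+"}


@dataclass
class BatchReport:
    """Long-form results of an all-pairs experiment.

    ``rows`` has one row per evaluated list with columns label, mode
    (single | intersection | union), combiner (none | score | rank),
    average_precision, coverage, n_regions, and for pair rows the
    positive-case flags per metric.
    """

    rows: pd.DataFrame

    def singles(self, metric: str = "average_precision") -> pd.DataFrame:
        sub = self.rows[self.rows["mode"] == "single"]
        cols = ["label", "average_precision", "coverage", "n_regions"]
        return (
            sub[cols]
            .sort_values(metric, ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )

    def table(self, metric: str, mode: str) -> pd.DataFrame:
        """One ranked pair table: metric in {average_precision, coverage},
        mode in {intersection, union}; columns give score- and
        rank-combination values side by side."""
        sub = self.rows[(self.rows["mode"] == mode) & (self.rows["combiner"] != "none")]
        wide = sub.pivot_table(
            index="label", columns="combiner", values=metric, aggfunc="first"
        ).rename(columns={"score": "score_combination", "rank": "rank_combination"})
        extras = (
            sub[sub["combiner"] == "score"]
            .set_index("label")[["n_regions", f"positive_{metric}"]]
        )
        out = wide.join(extras).sort_values(
            "score_combination", ascending=False, kind="mergesort"
        )
        return out.reset_index()


def run_batch(
    peaksets: list[PeakSet],
    tss: list[TSSRecord],
    flank: int = 0,
    intra_merge: bool = True,
    standard_ap: bool = False,
) -> BatchReport:
    """Evaluate all singles and all unordered pairs of the given systems."""
    if len(peaksets) < 2:
        raise ValueError("batch experiment needs at least 2 input systems")

    rows: list[dict] = []
    single_metrics: dict[str, dict[str, float]] = {}

    for ps in peaksets:
        ordered = sorted(
            ps.regions, key=lambda r: (-r.score, r.chrom, r.start, r.end)
        )
        rep = evaluate_list(
            ordered, tss, flank=flank, mode_label=ps.system_name,
            standard_ap=standard_ap,
        )
        single_metrics[ps.system_name] = {
            "average_precision": rep.average_precision,
            "coverage": rep.coverage,
        }
        rows.append(
            {"label": ps.system_name, "mode": "single", "combiner": "none",
             **rep.to_row()}
        )

    for a, b in itertools.combinations(peaksets, 2):
        for mode, builder in (
            ("intersection", build_intersection),
            ("union", build_union),
        ):
            fusion = builder(a, b, intra_merge=intra_merge)
            label = f"{a.system_name}{_MODE_GLYPH[mode]}{b.system_name}"
            if not fusion.regions:
                for combiner in ("score", "rank"):
                    rows.append(
                        {"label": label, "mode": mode, "combiner": combiner,
                         "mode_label": label, "n_regions": 0,
                         "average_precision": 0.0, "coverage": 0,
                         "positive_average_precision": False,
                         "positive_coverage": False}
                    )
                continue
            scored = ScoredFusion.from_fusion(fusion)
            best = {
                m: max(single_metrics[a.system_name][m],
                       single_metrics[b.system_name][m])
                for m in ("average_precision", "coverage")
            }
            for combiner, order_by in (("score", "score_comb"), ("rank", "rank_comb")):
                rep = evaluate_list(
                    order_regions(scored, order_by), tss, flank=flank,
                    mode_label=f"{label} {combiner}", standard_ap=standard_ap,
                )
                rows.append(
                    {"label": label, "mode": mode, "combiner": combiner,
                     **rep.to_row(),
                     "positive_average_precision":
                         rep.average_precision >= best["average_precision"],
                     "positive_coverage": rep.coverage >= best["coverage"]}
                )

    return BatchReport(rows=pd.DataFrame(rows))
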