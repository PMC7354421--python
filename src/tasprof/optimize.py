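"""Grid-search of the seven detection thresholds on a simulated panel.

Mapping and genotyping are done once per sample; every threshold
combination is then applied to the cached per-gene evidence (all seven
parameters act downstream of alignment), which is what makes very large
grids tractable.  The resulting (mean JI, mean FPR) cloud is reduced to
a Pareto shortlist -- non-dominated points under (maximize JI, minimize
FPR) -- and the operating point is the shortlist member with the lowest
FPR whose JI is within a slack of the best.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .calling import GeneCall, ThresholdConfig, call_strains
from .catalog import Catalog
from .evaluate import aggregate, score_sample
from .simulate import TruthSet

__all__ = ["GridSpec", "GridPoint", "grid_search", "pareto_shortlist", "choose_optimal"]


@dataclass
class GridSpec:
    """Value lists for each threshold parameter (Cartesian product)."""

    uniqueness_max: Sequence[int] = (1, 5, 10, 15)
    min_marker_coverage_bp: Sequence[int] = (30, 100, 170, 280)
    min_gene_coverage_pct: Sequence[float] = (40, 70, 98, 100)
    min_significant_snps: Sequence[int] = (0, 3, 10, 20)
    min_tas_species: Sequence[int] = (2, 5, 10, 15)
    min_tas_summary: Sequence[int] = (1, 5, 10)
    min_tas_short: Sequence[int] = (1, 2, 5, 10)

    @property
    def size(self) -> int:
        out = 1
        for f in dataclasses.fields(self):
            out *= len(getattr(self, f.name))
        return out

    def configs(self):
        names = [f.name for f in dataclasses.fields(self)]
        for values in itertools.product(*(getattr(self, n) for n in names)):
            yield ThresholdConfig(**dict(zip(names, values)))


@dataclass(frozen=True)
class GridPoint:
    config: ThresholdConfig
    mean_ji: float
    mean_fpr: float

    @property
    def score(self) -> float:
        return self.mean_ji - self.mean_fpr / 100.0


def grid_search(
    grid: GridSpec,
    evidence: Mapping[str, Mapping[str, GeneCall]],
    truths: Mapping[str, TruthSet],
    catalog: Catalog,
    level: str = "species",
) -> list[GridPoint]:
    """Evaluate every grid configuration on cached per-sample evidence.

    ``evidence`` maps sample id -> per-gene :class:`GeneCall`; these are
    computed once (mapping + genotyping) and re-thresholded per config.
    """
    if grid.size == 0:
        raise ValueError("empty grid")
    samples = sorted(evidence)
    if not samples or set(samples) != set(truths):
        raise ValueError("evidence and truths must cover the same samples")
    strain_species = catalog.strain_species()
    points: list[GridPoint] = []
    for cfg in grid.configs():
        results = []
        for sample in samples:
            report = call_strains(evidence[sample], catalog, cfg)
            predicted = (
                report.detected_species if level == "species" else report.detected
            )
            results.append(
                score_sample(
                    truths[sample],
                    predicted,
                    level=level,
                    strain_species=strain_species,
                    sample_id=sample,
                )
            )
        agg = aggregate(results)
        points.append(
            GridPoint(config=cfg, mean_ji=agg.mean_ji, mean_fpr=agg.mean_fpr)
        )
    return points


def _dominates(a: GridPoint, b: GridPoint) -> bool:
    return (
        a.mean_ji >= b.mean_ji
        and a.mean_fpr <= b.mean_fpr
        and (a.mean_ji > b.mean_ji or a.mean_fpr < b.mean_fpr)
    )


def pareto_shortlist(points: Sequence[GridPoint], k: int = 12) -> list[GridPoint]:
    """The (at most) k best non-dominated (JI, FPR) operating points.

    Dominated points never enter the shortlist.  A front larger than k
    is trimmed to the k highest ``mean_ji - mean_fpr/100`` scores; ties
    break toward lower FPR, then lexicographically smaller config.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not points:
        return []
    unique = list({(p.config): p for p in points}.values())
    front = [
        p for p in unique if not any(_dominates(q, p) for q in unique if q is not p)
    ]
    front.sort(key=lambda p: (-p.score, p.mean_fpr, p.config))
    return front[:k]


def choose_optimal(shortlist: Sequence[GridPoint], ji_slack: float = 0.1) -> GridPoint:
    """Lowest-FPR shortlist member whose JI is within ``ji_slack`` of the best."""
    if not shortlist:
        raise ValueError("empty shortlist")
    best_ji = max(p.mean_ji for p in shortlist)
    eligible = [p for p in shortlist if p.mean_ji >= best_ji - ji_slack]
    return min(eligible, key=lambda p: (p.mean_fpr, -p.mean_ji, p.config))


def points_table(points: Sequence[GridPoint]) -> pd.DataFrame:
    """One row per grid point (config fields + mean JI/FPR)."""
    rows = []
    for p in points:
        row = dataclasses.asdict(p.config)
        row["mean_ji"] = p.mean_ji
        row["mean_fpr"] = p.mean_fpr
        rows.append(row)
    return pd.DataFrame(rows)
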