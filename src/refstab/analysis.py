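"""High-level pipeline: raw wells -> calibrated, collapsed, ranked.

Convenience layer used by the CLI, the examples and the acceptance
checks; everything here is a thin composition of the per-method modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bestkeeper import BestkeeperResult, bestkeeper
from .consensus import ConsensusRanking, consensus_rank
from .deltact import DeltaCtResult, deltact_scores
from .genorm import GenormResult, genorm_rank, genorm_v_curve
from .io import CqTable, RqTable, collapse_replicates, linearise, plate_calibrate
from .normfinder import NormfinderResult, normfinder_ungrouped


def prepare(table: CqTable, efficiency=2.0, calibrate: bool = True) -> tuple[CqTable, RqTable]:
    """Replicate-level wells -> (collapsed CqTable, RqTable).

    Plate calibration runs first when the table spans several plates and
    has calibrator samples; otherwise it is skipped.
    """
    if not table.is_collapsed:
        multi_plate = table.wells["plate"].nunique() > 1
        if calibrate and multi_plate and table.meta["is_calibrator"].astype(bool).any():
            table = plate_calibrate(table)
        table = collapse_replicates(table)
    return table, linearise(table, efficiency)


@dataclass
class SubsetRanking:
    """All four method results plus the consensus for one sample subset."""

    context: str
    genorm: GenormResult
    v_curve: pd.Series
    deltact: DeltaCtResult
    bestkeeper: BestkeeperResult
    normfinder: NormfinderResult
    consensus: ConsensusRanking


def rank_subset(
    table: CqTable, subset: str = "all", efficiency=2.0, calibrate: bool = True
) -> SubsetRanking:
    """Run geNorm, deltaCt, BestKeeper, ungrouped NormFinder and the consensus."""
    collapsed, rq = prepare(table, efficiency=efficiency, calibrate=calibrate)
    collapsed = collapsed.subset(subset)
    rq = rq.subset(subset)
    g = genorm_rank(rq)
    vc = genorm_v_curve(rq, g)
    d = deltact_scores(collapsed)
    b = bestkeeper(collapsed)
    n = normfinder_ungrouped(rq)
    c = consensus_rank(g, d, b, n, context=subset)
    return SubsetRanking(
        context=subset, genorm=g, v_curve=vc, deltact=d, bestkeeper=b,
        normfinder=n, consensus=c,
    )
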