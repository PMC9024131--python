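"""Integrated consensus ranking across the four stability methods.

Each gene receives one score per method on a common scale where lower is
better: geNorm M at removal (both best-pair genes sharing the final M),
the deltaCt mean pairwise SD, the inverted BestKeeper correlation
``1 - max(r, 0)``, and the ungrouped NormFinder stability.  The consensus
score is the per-gene geometric mean of the four, with scores floored at a
small epsilon so one perfect method cannot force the product to zero;
genes are ranked ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bestkeeper import BestkeeperResult
from .deltact import DeltaCtResult
from .errors import SchemaError
from .genorm import GenormResult
from .normfinder import NormfinderResult

EPSILON = 1e-6


@dataclass
class ConsensusRanking:
    context: str
    scores: pd.DataFrame  # columns: genorm, deltact, bestkeeper, normfinder, consensus
    ranks: pd.Series  # 1 = most stable

    def table(self) -> pd.DataFrame:
        """Scores plus rank, ordered most to least stable."""
        out = self.scores.copy()
        out["rank"] = self.ranks
        return out.sort_values("rank")


def invert_bestkeeper(r: pd.Series | float):
    """Map a Pearson r in [-1, 1] to a lower-is-better score 1 - max(r, 0)."""
    if np.isscalar(r):
        if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of [-1, 1]: {r}")
        return 1.0 - max(float(r), 0.0)
    r = pd.Series(r, dtype=float)
    if ((r < -1.0 - 1e-12) | (r > 1.0 + 1e-12)).any():
        raise ValueError("correlation out of [-1, 1]")
    return 1.0 - r.clip(lower=0.0)


def consensus_rank(
    genorm: GenormResult,
    dct: DeltaCtResult,
    bk: BestkeeperResult,
    nf: NormfinderResult,
    context: str = "all",
    epsilon: float = EPSILON,
    genorm_full_panel: bool = False,
) -> ConsensusRanking:
    """Geometric-mean consensus of the four method scores.

    All four results must cover the same gene panel and ``nf`` must be the
    ungrouped analysis.  ``genorm_full_panel`` switches the geNorm
    contribution from M-at-removal (default) to full-panel M.
    """
    if nf.mode != "ungrouped":
        raise SchemaError("consensus uses the ungrouped NormFinder analysis")
    g_scores = genorm.m_full_panel if genorm_full_panel else genorm.m_at_removal
    panels = {
        "genorm": set(g_scores.index),
        "deltact": set(dct.scores.index),
        "bestkeeper": set(bk.r.index),
        "normfinder": set(nf.stability.index),
    }
    common = set.intersection(*panels.values())
    mismatched = {m: sorted(p - common) for m, p in panels.items() if p != common}
    if mismatched:
        raise SchemaError(f"gene panels differ across methods: {mismatched}")
    genes = sorted(common)
    scores = pd.DataFrame(
        {
            "genorm": g_scores.loc[genes],
            "deltact": dct.scores.loc[genes],
            "bestkeeper": invert_bestkeeper(bk.r.loc[genes]),
            "normfinder": nf.stability.loc[genes],
        }
    )
    floored = scores.clip(lower=epsilon)
    consensus = np.exp(np.log(floored).mean(axis=1))
    scores["consensus"] = consensus
    order = consensus.sort_values(kind="stable").index
    ranks = pd.Series(np.arange(1, len(genes) + 1), index=order).loc[genes]
    return ConsensusRanking(context=context, scores=scores, ranks=ranks)
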