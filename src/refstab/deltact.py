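"""Comparative deltaCt stability scores.

Each candidate is scored by the mean, over all other panel genes, of the
sample standard deviation of the per-sample Cq difference (Cq_j - Cq_k);
low scores indicate stable genes.  Works directly on mean (collapsed) Cq
values -- no linearisation.  With a common efficiency of 2 this score is
algebraically identical to the geNorm M value, since
log2(RQ_j/RQ_k) = (Cq_k - Cq_j) + const.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InsufficientDataError, SchemaError
from .io import CqTable, complete_case


@dataclass
class DeltaCtResult:
    scores: pd.Series  # per-gene mean pairwise-deltaCq SD, cycles
    excluded_genes: list[str]
    dropped_samples: list[str]


def deltact_scores(t: CqTable | pd.DataFrame) -> DeltaCtResult:
    """score_j = mean over k != j of SD over samples of (Cq_j - Cq_k)."""
    frame = t.cq if isinstance(t, CqTable) else t
    if frame is None:
        raise SchemaError("deltact_scores requires a collapsed CqTable")
    frame, excluded, dropped = complete_case(frame)
    if frame.shape[0] < 3:
        raise InsufficientDataError(f"deltaCt needs >=3 genes, got {frame.shape[0]}")
    if frame.shape[1] < 3:
        raise InsufficientDataError(
            f"deltaCt needs >=3 complete samples, got {frame.shape[1]}"
        )
    y = frame.to_numpy()
    diffs = y[:, None, :] - y[None, :, :]
    sd = diffs.std(axis=2, ddof=1)
    k = sd.shape[0]
    scores = pd.Series(sd.sum(axis=1) / (k - 1), index=frame.index)
    return DeltaCtResult(scores=scores, excluded_genes=excluded, dropped_samples=dropped)
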