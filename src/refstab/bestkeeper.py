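"""BestKeeper consensus-index correlation.

The BestKeeper index is a per-sample consensus Cq profile -- the geometric
mean of all candidate genes' Cq values (arithmetic mean available behind a
flag).  Candidates are then ranked by the Pearson correlation coefficient
r of their own Cq profile with the index: high r means the gene tracks the
panel consensus.  Per-gene Cq SD and CV (percent of mean Cq) are reported
as descriptive spread measures.  Genes with zero Cq variance have no
defined correlation and are assigned r = 0 with a recorded warning; note
that an r-based ranking structurally penalises perfectly constant genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SchemaError
from .io import CqTable, complete_case


@dataclass
class BestkeeperResult:
    index: pd.Series  # per-sample consensus Cq
    r: pd.Series  # per-gene Pearson r vs the index
    cq_sd: pd.Series
    cq_cv: pd.Series  # percent (100 * SD / mean Cq)
    excluded_genes: list[str]
    dropped_samples: list[str]
    warnings: list[str] = field(default_factory=list)


def bestkeeper(t: CqTable | pd.DataFrame, geometric: bool = True) -> BestkeeperResult:
    """Rank genes by Pearson correlation with the consensus Cq index."""
    frame = t.cq if isinstance(t, CqTable) else t
    if frame is None:
        raise SchemaError("bestkeeper requires a collapsed CqTable")
    frame, excluded, dropped = complete_case(frame)
    if frame.shape[1] < 3:
        raise InsufficientDataError(
            f"BestKeeper needs >=3 complete samples, got {frame.shape[1]}"
        )
    if (frame.to_numpy() <= 0).any():
        raise SchemaError("BestKeeper geometric index requires positive Cq values")
    if geometric:
        index = pd.Series(
            np.exp(np.log(frame.to_numpy()).mean(axis=0)), index=frame.columns
        )
    else:
        index = frame.mean(axis=0)
    warnings: list[str] = []
    r = {}
    for g in frame.index:
        x = frame.loc[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(index.to_numpy()) == 0:
            r[g] = 0.0
            warnings.append(f"gene {g!r}: zero Cq variance, r set to 0")
        else:
            r[g] = float(stats.pearsonr(x, index.to_numpy()).statistic)
    return BestkeeperResult(
        index=index,
        r=pd.Series(r).loc[frame.index],
        cq_sd=frame.std(axis=1, ddof=1),
        cq_cv=100.0 * frame.std(axis=1, ddof=1) / frame.mean(axis=1),
        excluded_genes=excluded,
        dropped_samples=dropped,
        warnings=warnings,
    )
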