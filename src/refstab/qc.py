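"""Detection of cDNA-synthesis batches with failed random priming.

Reverse transcription of non-polyadenylated RNAs (rRNAs such as 18S) and
of the 5' ends of long transcripts depends on random priming; a batch
whose random priming failed shows late Cq values for those sentinel genes
only, while oligo-dT-primed genes are unaffected.  The detector contrasts,
per cDNA batch, the median Cq shift of the sentinel genes against the
median shift of the rest of the panel: a batch is flagged when the
sentinels move late by at least ``sentinel_threshold`` cycles *more than
the panel does*.  Flagging on the sentinel-minus-panel difference makes
the decision exactly invariant to global (all-gene) batch shifts, which
are quality effects, not priming failures.  Medians are used throughout to
resist single-sample outliers.  Batches whose panel-wide shift exceeds
``panel_threshold`` cycles are additionally annotated as carrying a global
shift (informational, independent of the priming flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InsufficientDataError, SchemaError
from .io import CqTable


@dataclass
class PrimingQcReport:
    sentinels: list[str]
    sentinel_threshold: float
    panel_threshold: float
    per_batch: pd.DataFrame  # batch, sentinel_deviation, panel_deviation, flagged
    notes: list[str] = field(default_factory=list)

    @property
    def flagged_batches(self) -> list[str]:
        return list(self.per_batch.index[self.per_batch["flagged"]])


def priming_qc(
    t: CqTable,
    sentinels: list[str] | None = None,
    sentinel_threshold: float = 1.5,
    panel_threshold: float = 0.5,
) -> PrimingQcReport:
    """Flag cDNA batches whose sentinel genes run late but whose panel does not.

    Per batch: ``sentinel_deviation`` is the median over sentinel genes of
    (batch median Cq - global median Cq); ``panel_deviation`` is the same
    contrast over the non-sentinel genes.  A batch is flagged when
    ``sentinel_deviation - panel_deviation >= sentinel_threshold``; a
    uniform shift of the whole panel therefore never triggers the flag.
    """
    if sentinels is None:
        sentinels = ["18S"]
    frame = t.cq
    if frame is None:
        raise SchemaError("priming_qc requires a collapsed CqTable")
    absent = [g for g in sentinels if g not in frame.index]
    if absent:
        raise SchemaError(f"sentinel gene(s) absent from panel: {absent}")
    batches = t.meta["cdna_batch"]
    if batches.isna().any():
        raise SchemaError("cdna_batch must be present for all samples")
    levels = list(pd.unique(batches))
    if len(levels) < 2:
        return PrimingQcReport(
            sentinels=list(sentinels),
            sentinel_threshold=sentinel_threshold,
            panel_threshold=panel_threshold,
            per_batch=pd.DataFrame(
                columns=["sentinel_deviation", "panel_deviation", "flagged"]
            ),
            notes=["single cDNA batch: priming QC not applicable"],
        )
    others = [g for g in frame.index if g not in sentinels]
    if not others:
        raise InsufficientDataError("priming_qc needs at least one non-sentinel gene")
    global_median = frame.median(axis=1)
    rows = {}
    for b in levels:
        cols = t.meta.index[batches == b]
        dev = frame.loc[:, cols].median(axis=1) - global_median
        rows[b] = {
            "sentinel_deviation": float(dev.loc[sentinels].median()),
            "panel_deviation": float(dev.loc[others].median()),
        }
    per_batch = pd.DataFrame.from_dict(rows, orient="index")
    per_batch["flagged"] = (
        per_batch["sentinel_deviation"] - per_batch["panel_deviation"]
        >= sentinel_threshold
    )
    per_batch["global_shift"] = per_batch["panel_deviation"].abs() > panel_threshold
    per_batch.index.name = "batch"
    return PrimingQcReport(
        sentinels=list(sentinels),
        sentinel_threshold=sentinel_threshold,
        panel_threshold=panel_threshold,
        per_batch=per_batch,
    )
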