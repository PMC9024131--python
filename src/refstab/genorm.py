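"""geNorm stability analysis.

For genes j, k with relative quantities RQ, the pairwise variation
``V_jk`` is the sample standard deviation (n-1 denominator) over samples
of ``log2(RQ_j / RQ_k)``.  A gene's expression stability ``M_j`` is the
arithmetic mean of ``V_jk`` over all other panel genes; high M means an
unstable gene.  The iterative algorithm repeatedly drops the gene with the
highest M (recomputing M among the survivors) until two genes -- the
"best pair" -- remain.  The V(n/n+1) curve measures the benefit of using
n+1 rather than n reference genes: it is the SD over samples of the
log-ratio of normalization factors (per-sample geometric means of the
top-n and top-(n+1) genes' RQs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import RqTable, complete_case


@dataclass
class GenormResult:
    """Full output of the iterative geNorm run on one sample subset."""

    m_full_panel: pd.Series  # M per gene with the whole panel included
    removal_order: list[tuple[str, float]]  # (gene, M at removal), worst first
    best_pair: tuple[str, str]
    final_m: float  # shared M of the best pair
    excluded_genes: list[str]
    dropped_samples: list[str]
    tie_breaks: list[str]

    @property
    def m_at_removal(self) -> pd.Series:
        """M at the exclusion stage, best pair sharing the final M.

        This is the per-gene quantity for which assigning the best pair a
        common score is well defined, and the default geNorm contribution
        to the consensus ranking.
        """
        scores = {g: m for g, m in self.removal_order}
        scores[self.best_pair[0]] = self.final_m
        scores[self.best_pair[1]] = self.final_m
        return pd.Series(scores).loc[list(self.m_full_panel.index)]

    def ranking(self) -> list[str]:
        """Genes from most to least stable (best pair first, then reverse removal)."""
        return list(self.best_pair) + [g for g, _ in reversed(self.removal_order)]


def _log_matrix(rq: pd.DataFrame) -> pd.DataFrame:
    return np.log2(rq)


def _check_samples(frame: pd.DataFrame) -> None:
    if frame.shape[1] < 3:
        raise InsufficientDataError(
            f"geNorm needs >=3 complete samples, got {frame.shape[1]}"
        )


def pairwise_v(rq: RqTable | pd.DataFrame, j: str, k: str) -> float:
    """V_jk = sample SD over samples of log2(RQ_j / RQ_k)."""
    frame = rq.rq if isinstance(rq, RqTable) else rq
    if j == k:
        raise ValueError("pairwise_v requires two distinct genes")
    sub = frame.loc[[j, k]].dropna(axis=1)
    _check_samples(sub)
    ratios = np.log2(sub.loc[j] / sub.loc[k])
    return float(ratios.std(ddof=1))


def _v_matrix(log_rq: pd.DataFrame) -> pd.DataFrame:
    """All pairwise V_jk at once (SD of row differences)."""
    y = log_rq.to_numpy()
    diffs = y[:, None, :] - y[None, :, :]  # (k, k, n)
    v = diffs.std(axis=2, ddof=1)
    return pd.DataFrame(v, index=log_rq.index, columns=log_rq.index)


def genorm_m(rq: RqTable | pd.DataFrame) -> pd.Series:
    """Full-panel M values: M_j = mean over k != j of V_jk."""
    frame = rq.rq if isinstance(rq, RqTable) else rq
    frame, _, _ = complete_case(frame)
    if frame.shape[0] < 3:
        raise InsufficientDataError(f"geNorm needs >=3 genes, got {frame.shape[0]}")
    _check_samples(frame)
    v = _v_matrix(_log_matrix(frame))
    k = v.shape[0]
    return v.sum(axis=1) / (k - 1)


def genorm_rank(rq: RqTable | pd.DataFrame) -> GenormResult:
    """Iterative exclusion to the best pair.

    Ties in the maximum M are broken deterministically by removing the
    gene latest in reverse alphabetical order (i.e. the lexicographically
    greatest name); every tie-break is recorded in the result.
    """
    frame = rq.rq if isinstance(rq, RqTable) else rq
    frame, excluded, dropped = complete_case(frame)
    if frame.shape[0] < 3:
        raise InsufficientDataError(f"geNorm needs >=3 genes, got {frame.shape[0]}")
    _check_samples(frame)
    v = _v_matrix(_log_matrix(frame))
    m_full = v.sum(axis=1) / (v.shape[0] - 1)

    removal_order: list[tuple[str, float]] = []
    tie_breaks: list[str] = []
    remaining = list(frame.index)
    while len(remaining) > 2:
        sub = v.loc[remaining, remaining]
        m = sub.sum(axis=1) / (len(remaining) - 1)
        worst_val = m.max()
        ties = sorted(m.index[np.isclose(m, worst_val, rtol=0, atol=1e-12)])
        worst = ties[-1]  # reverse-alphabetical tie-break
        if len(ties) > 1:
            tie_breaks.append(
                f"M tie at {worst_val:.6g} among {ties}; removed {worst!r}"
            )
        removal_order.append((worst, float(m[worst])))
        remaining.remove(worst)
    final_m = float(v.loc[remaining[0], remaining[1]])
    best_pair = tuple(sorted(remaining))
    return GenormResult(
        m_full_panel=m_full,
        removal_order=removal_order,
        best_pair=best_pair,  # type: ignore[arg-type]
        final_m=final_m,
        excluded_genes=excluded,
        dropped_samples=dropped,
        tie_breaks=tie_breaks,
    )


def genorm_v_curve(rq: RqTable | pd.DataFrame, ranking: GenormResult) -> pd.Series:
    """V(n/n+1) for n = 2 .. k-1 along the geNorm stability ranking.

    ``NF_n`` is the per-sample geometric mean of the top-n genes' RQs;
    ``V(n/n+1)`` is the sample SD over samples of ``log2(NF_n / NF_{n+1})``.
    Values below ~0.2 conventionally indicate that adding the (n+1)-th
    reference gene is unnecessary.
    """
    frame = rq.rq if isinstance(rq, RqTable) else rq
    order = ranking.ranking()
    frame, _, _ = complete_case(frame.loc[order])
    _check_samples(frame)
    log_rq = _log_matrix(frame).to_numpy()
    k = len(order)
    out = {}
    for n in range(2, k):
        log_nf_n = log_rq[:n].mean(axis=0)
        log_nf_n1 = log_rq[: n + 1].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    return pd.Series(out)
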