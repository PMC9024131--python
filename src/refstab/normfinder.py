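"""NormFinder model-based stability on log-scale relative quantities.

The model for ungrouped data is the additive two-way layout
``y_gs = alpha_g + beta_s + eps_gs`` on ``y = log2(RQ)``, with gene-specific
error variance ``sigma_g^2``.  After double-centering, the naive residual
variance of gene g,

    s2_g = sum_s r_gs^2 / (n - 1),

is contaminated by every other gene's noise through the per-sample mean;
the closed-form bias-corrected estimator used throughout is

    sigma2_g = (k / (k - 2)) * (s2_g - mean(s2) / (k - 1)),  floored at 0,

whose square root is the ungrouped stability value (0 = perfectly stable).

Grouped mode decomposes stability into an intragroup variance (the same
estimator applied within each group) and an intergroup deviation d of the
gene's sample-centred group mean from its grand mean.  d is shrunk toward 0
by an empirical-Bayes factor based on the across-gene spread of the d's,
and the stability value is the mean over groups of |d_shrunk| plus the
standard error of the group mean.  The grouped best pair is the two-gene
combination whose averaged deviations and pooled variance give the lowest
combined stability -- two genes deviating in opposite directions can beat
any single gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import RqTable, complete_case


@dataclass
class NormfinderResult:
    mode: str  # "ungrouped" | "grouped"
    stability: pd.Series  # per-gene, >= 0
    sigma2: pd.DataFrame | pd.Series  # intragroup variance (per gene, per group if grouped)
    d: pd.DataFrame | None = None  # intergroup deviation per (gene, group)
    d_shrunk: pd.DataFrame | None = None
    group_sizes: pd.Series | None = None
    best_pair: tuple[str, str] | None = None
    best_pair_stability: float | None = None
    excluded_genes: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


def _prepare(rq: RqTable | pd.DataFrame):
    frame = rq.rq if isinstance(rq, RqTable) else rq
    frame, excluded, dropped = complete_case(frame)
    k, n = frame.shape
    if k < 3:
        raise InsufficientDataError(
            f"NormFinder bias correction is undefined for k < 3 genes (got {k})"
        )
    if n < 3:
        raise InsufficientDataError(f"NormFinder needs >=3 samples, got {n}")
    return np.log2(frame.to_numpy()), frame, excluded, dropped


def _sigma2_hat(y: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene variance from the double-centred residuals."""
    k, n = y.shape
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    s2 = (resid**2).sum(axis=1) / (n - 1)
    sigma2 = (k / (k - 2)) * (s2 - s2.mean() / (k - 1))
    return np.maximum(sigma2, 0.0)


def normfinder_ungrouped(rq: RqTable | pd.DataFrame) -> NormfinderResult:
    """Per-gene stability = sqrt of the bias-corrected error variance."""
    y, frame, excluded, dropped = _prepare(rq)
    sigma2 = _sigma2_hat(y)
    return NormfinderResult(
        mode="ungrouped",
        stability=pd.Series(np.sqrt(sigma2), index=frame.index),
        sigma2=pd.Series(sigma2, index=frame.index),
        excluded_genes=excluded,
        dropped_samples=dropped,
    )


def normfinder_grouped(rq: RqTable | pd.DataFrame, groups) -> NormfinderResult:
    """Grouped stability with shrunken intergroup deviations and best pair.

    ``groups`` maps sample id -> group label (dict or Series); every group
    must contain at least two samples.
    """
    y, frame, excluded, dropped = _prepare(rq)
    groups = pd.Series(groups)
    missing = set(frame.columns) - set(groups.index)
    if missing:
        raise InsufficientDataError(f"group labels missing for samples: {sorted(missing)}")
    labels = groups.loc[frame.columns]
    level_names = [str(g) for g in pd.unique(labels)]
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise InsufficientDataError(
            f"group(s) with fewer than 2 samples: {list(small.index)}"
        )
    k, n = y.shape
    genes = list(frame.index)

    # sample-centred expression: removes the per-sample (global) effect
    z = y - y.mean(axis=0, keepdims=True)
    grand = z.mean(axis=1)

    sigma2 = pd.DataFrame(index=genes, columns=level_names, dtype=float)
    d = pd.DataFrame(index=genes, columns=level_names, dtype=float)
    d_shrunk = pd.DataFrame(index=genes, columns=level_names, dtype=float)
    sizes = pd.Series({g: int(counts[g]) for g in level_names})

    for g in level_names:
        cols = np.asarray(labels == g)
        sigma2[g] = _sigma2_hat(y[:, cols])
        d[g] = z[:, cols].mean(axis=1) - grand
        gamma2 = float(d[g].var(ddof=1))
        denom = gamma2 + sigma2[g].to_numpy() / sizes[g]
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(denom > 0, gamma2 / denom, 0.0)
        d_shrunk[g] = d[g].to_numpy() * shrink

    se = np.sqrt(sigma2.to_numpy() / sizes.to_numpy()[None, :])
    stability = pd.Series(
        (np.abs(d_shrunk.to_numpy()) + se).mean(axis=1), index=genes
    )

    best_pair, best_val = None, np.inf
    for a, b in combinations(genes, 2):
        pair_dev = np.abs((d_shrunk.loc[a] + d_shrunk.loc[b]).to_numpy() / 2.0)
        pair_se = np.sqrt(
            (sigma2.loc[a].to_numpy() + sigma2.loc[b].to_numpy())
            / (4.0 * sizes.to_numpy())
        )
        val = float((pair_dev + pair_se).mean())
        if val < best_val:
            best_pair, best_val = tuple(sorted((a, b))), val

    return NormfinderResult(
        mode="grouped",
        stability=stability,
        sigma2=sigma2,
        d=d,
        d_shrunk=d_shrunk,
        group_sizes=sizes,
        best_pair=best_pair,  # type: ignore[arg-type]
        best_pair_stability=best_val,
        excluded_genes=excluded,
        dropped_samples=dropped,
    )


def groups_from_meta(meta: pd.DataFrame, by: str) -> pd.Series:
    """Group labels from sample metadata (``by`` = 'tissue' or 'age_days')."""
    if by not in meta.columns:
        raise InsufficientDataError(f"metadata has no column {by!r}")
    return meta[by].astype(str)
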