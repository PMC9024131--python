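"""Normalization factors and their validation.

A normalization factor (NF) is the per-sample geometric mean of the chosen
reference genes' relative quantities; gene-of-interest RQs are divided by
it.  Validation follows two routes: (i) the summed per-timepoint
coefficient of variation (CoV = SD/mean per timepoint, summed over the
timepoints of a tissue) should drop after normalization when sample-quality
variation dominates, and (ii) NFs built from different reference
combinations should agree (Pearson r and OLS gradient near 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SchemaError
from .io import RqTable


@dataclass
class NormalizationFactor:
    nf: pd.Series  # per-sample, > 0
    refs: list[str]


@dataclass
class NfComparison:
    r: float
    gradient: float  # OLS slope of nf_b on nf_a, free intercept
    intercept: float


@dataclass
class ValidationReport:
    """Raw vs normalized trajectories and CoV per target gene and tissue."""

    refs: list[str]
    targets: list[str]
    cov: pd.DataFrame  # rows (gene, tissue), columns raw/normalized total CoV
    trajectories: pd.DataFrame  # long: gene, tissue, sample, age, raw, normalized
    warnings: list[str] = field(default_factory=list)


def normalization_factor(rq: RqTable | pd.DataFrame, refs: list[str]) -> NormalizationFactor:
    """NF_s = geometric mean over the reference genes of RQ[ref, s]."""
    frame = rq.rq if isinstance(rq, RqTable) else rq
    if not refs:
        raise SchemaError("normalization_factor requires at least one reference gene")
    missing = [g for g in refs if g not in frame.index]
    if missing:
        raise SchemaError(f"reference gene(s) absent from panel: {missing}")
    sub = frame.loc[refs]
    if sub.isna().any().any():
        bad = list(sub.columns[sub.isna().any(axis=0)])
        raise SchemaError(f"missing reference RQs for samples: {bad}")
    if len(refs) == 1:  # keep the self-normalization identity exact
        nf = sub.iloc[0].copy()
    else:
        nf = pd.Series(np.exp(np.log(sub.to_numpy()).mean(axis=0)), index=sub.columns)
    return NormalizationFactor(nf=nf, refs=list(refs))


def normalize_goi(goi_rq: pd.Series, nf: NormalizationFactor) -> pd.Series:
    """Divide gene-of-interest RQs by the per-sample NF (RQs are linear)."""
    common = goi_rq.index.intersection(nf.nf.index)
    dropped = goi_rq.index.difference(nf.nf.index)
    out = goi_rq.loc[common] / nf.nf.loc[common]
    if len(dropped):
        out.attrs["dropped_samples"] = list(dropped)
    return out


def total_cov(values: pd.Series, timepoints: pd.Series) -> float:
    """Sum over timepoints of (sample SD / mean) of the values at that timepoint."""
    timepoints = pd.Series(timepoints).loc[values.index]
    total = 0.0
    for tp, grp in values.groupby(timepoints):
        if len(grp) < 2:
            raise InsufficientDataError(
                f"timepoint {tp!r} has {len(grp)} sample(s); CoV needs >=2"
            )
        mean = grp.mean()
        if mean == 0:
            raise InsufficientDataError(f"timepoint {tp!r} has zero mean; CoV undefined")
        total += float(grp.std(ddof=1) / mean)
    return total


def compare_nfs(nf_a: NormalizationFactor, nf_b: NormalizationFactor) -> NfComparison:
    """Pearson r and OLS gradient (free intercept) of nf_b against nf_a."""
    common = nf_a.nf.index.intersection(nf_b.nf.index)
    if len(common) < 3:
        raise InsufficientDataError(f"NF comparison needs >=3 shared samples, got {len(common)}")
    a = nf_a.nf.loc[common].to_numpy()
    b = nf_b.nf.loc[common].to_numpy()
    fit = stats.linregress(a, b)
    return NfComparison(r=float(fit.rvalue), gradient=float(fit.slope), intercept=float(fit.intercept))


def validation_report(
    rq: RqTable, refs: list[str], targets: list[str]
) -> ValidationReport:
    """Raw vs normalized per-tissue age trajectories and total CoV per target.

    CoV is computed per tissue independently (each tissue has its own
    gestational-age timepoints) and summed over that tissue's timepoints.
    """
    frame = rq.rq
    missing = [g for g in targets if g not in frame.index]
    if missing:
        raise SchemaError(f"target gene(s) absent from panel: {missing}")
    nf = normalization_factor(rq, refs)
    meta = rq.meta
    rows = []
    cov_rows = []
    warnings: list[str] = []
    tissues = [t for t in pd.unique(meta["tissue"].dropna())]
    if not tissues:
        raise InsufficientDataError("validation requires tissue metadata")
    for gene in targets:
        raw = frame.loc[gene]
        norm = normalize_goi(raw, nf)
        for tissue in tissues:
            sel = meta.index[meta["tissue"] == tissue]
            sel = [s for s in sel if s in norm.index and not pd.isna(raw[s])]
            if len(sel) < 2:
                warnings.append(f"{gene}/{tissue}: fewer than 2 samples, skipped")
                continue
            ages = meta.loc[sel, "age_days"]
            cov_rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "cov_raw": total_cov(raw.loc[sel], ages),
                    "cov_normalized": total_cov(norm.loc[sel], ages),
                }
            )
            for s in sel:
                rows.append(
                    {
                        "gene": gene,
                        "tissue": tissue,
                        "sample_id": s,
                        "age_days": float(ages[s]),
                        "raw_rq": float(raw[s]),
                        "normalized_rq": float(norm[s]),
                    }
                )
    return ValidationReport(
        refs=list(refs),
        targets=list(targets),
        cov=pd.DataFrame(cov_rows),
        trajectories=pd.DataFrame(rows),
        warnings=warnings,
    )
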