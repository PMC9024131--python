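"""Reading, validating, calibrating and collapsing raw Cq data.

The universal input is a table of quantification-cycle (Cq) values for a
panel of candidate reference genes measured across samples, either at
replicate (well) level or collapsed to one mean Cq per (gene, sample).
Downstream stability methods consume the collapsed matrix or its
linearised relative-quantity (RQ) form, ``RQ = E**(Cq_min - Cq)`` with E
the per-gene amplification efficiency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    DuplicateRecordError,
    InsufficientDataError,
    SchemaError,
)

TISSUES = ("embryo", "head", "forelimb")

#: columns the long dialect must provide
REQUIRED_LONG = ("sample_id", "gene", "cq")
#: optional long-dialect columns copied into per-sample metadata
META_COLUMNS = ("tissue", "age_days", "litter", "cdna_batch", "is_calibrator")

_MISSING_TOKENS = {"", "na", "nan", "n/a", "none", "null"}

CQ_LOW, CQ_HIGH = 0.0, 45.0


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes", "y"}
    return bool(x) and not pd.isna(x)


@dataclass
class CqTable:
    """Cq data plus per-sample metadata.

    Exactly one of the two states holds: replicate-level (``wells`` set,
    ``cq`` None) or collapsed (``cq`` set, genes x samples).
    """

    meta: pd.DataFrame
    cq: pd.DataFrame | None = None
    wells: pd.DataFrame | None = None
    cq_sd: pd.DataFrame | None = None
    sd_flags: pd.DataFrame | None = None
    plate_offsets: dict[str, float] | None = None
    diagnostics: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.cq is None) == (self.wells is None):
            raise SchemaError(
                "CqTable must be exactly one of replicate-level or collapsed"
            )

    @property
    def is_collapsed(self) -> bool:
        return self.cq is not None

    @property
    def genes(self) -> list[str]:
        if self.is_collapsed:
            return list(self.cq.index)
        return sorted(self.wells["gene"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def n_missing(self) -> int:
        if self.is_collapsed:
            return int(self.cq.isna().to_numpy().sum())
        return int(self.wells["cq"].isna().sum())

    def subset(self, which: str = "all") -> "CqTable":
        """Restrict to one tissue context (``all`` keeps every sample)."""
        if which == "all":
            return self
        if which not in TISSUES:
            raise SchemaError(f"unknown subset {which!r}; expected all|{'|'.join(TISSUES)}")
        keep = self.meta.index[self.meta["tissue"] == which]
        if len(keep) == 0:
            raise InsufficientDataError(f"subset {which!r} contains no samples")
        new = dataclasses.replace(
            self,
            meta=self.meta.loc[keep],
            cq=None if self.cq is None else self.cq.loc[:, keep],
            wells=None
            if self.wells is None
            else self.wells[self.wells["sample_id"].isin(keep)].reset_index(drop=True),
            cq_sd=None if self.cq_sd is None else self.cq_sd.loc[:, keep],
            sd_flags=None if self.sd_flags is None else self.sd_flags.loc[:, keep],
        )
        return new


@dataclass
class RqTable:
    """Relative quantities per gene (unitless, max 1 at each gene's min-Cq sample)."""

    rq: pd.DataFrame  # genes x samples
    meta: pd.DataFrame
    efficiency: pd.Series  # per-gene E in [1.6, 2.1]

    @property
    def genes(self) -> list[str]:
        return list(self.rq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rq.columns)

    def subset(self, which: str = "all") -> "RqTable":
        if which == "all":
            return self
        if which not in TISSUES:
            raise SchemaError(f"unknown subset {which!r}")
        keep = self.meta.index[self.meta["tissue"] == which]
        if len(keep) == 0:
            raise InsufficientDataError(f"subset {which!r} contains no samples")
        return RqTable(self.rq.loc[:, keep], self.meta.loc[keep], self.efficiency)


def _build_meta(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample metadata from the first occurrence of each sample_id."""
    cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df.drop_duplicates("sample_id").set_index("sample_id")[cols].copy()
    for c in META_COLUMNS:
        if c not in meta.columns:
            meta[c] = np.nan
    if meta["tissue"].notna().any():
        bad = set(meta["tissue"].dropna()) - set(TISSUES)
        if bad:
            raise SchemaError(f"unknown tissue value(s) {sorted(bad)}; expected {TISSUES}")
    meta["is_calibrator"] = meta["is_calibrator"].map(_as_bool)
    if meta["age_days"].notna().any():
        meta["age_days"] = pd.to_numeric(meta["age_days"], errors="raise")
        if (meta["age_days"].dropna() <= 0).any():
            raise SchemaError("age_days must be > 0")
    meta.index = meta.index.astype(str)
    return meta


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, dtype=str)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_cq(
    path: str | Path,
    dialect: str = "long",
    meta_path: str | Path | None = None,
) -> CqTable:
    """Read a Cq table from CSV/TSV (or xlsx with the same column layout).

    ``long`` dialect: one row per well with columns ``sample_id, gene, cq``
    plus optional ``plate, well`` and the metadata columns; returns a
    replicate-level table.  ``wide`` dialect: first column ``gene``,
    remaining columns are sample ids (one value per cell, i.e. already
    collapsed); per-sample metadata may be supplied via ``meta_path``.

    Rows with non-numeric or out-of-range Cq are rejected and reported in
    ``table.diagnostics``; literal NA tokens become missing cells.
    """
    df = _read_table(path)
    if dialect == "long":
        return _read_long(df)
    if dialect == "wide":
        return _read_wide(df, meta_path)
    raise SchemaError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")


def _parse_cq_column(raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Return (numeric cq with NaN for missing, boolean mask of rejected rows)."""
    stripped = raw.astype(str).str.strip()
    is_missing = raw.isna() | stripped.str.lower().isin(_MISSING_TOKENS)
    num = pd.to_numeric(stripped.where(~is_missing), errors="coerce")
    unparseable = ~is_missing & num.isna()
    out_of_range = num.notna() & ~((num > CQ_LOW) & (num < CQ_HIGH))
    return num, (unparseable | out_of_range)


def _read_long(df: pd.DataFrame) -> CqTable:
    for col in REQUIRED_LONG:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    if "well" not in df.columns:
        # implicit well id: occurrence index within each (sample, gene)
        df["well"] = df.groupby(["sample_id", "gene"]).cumcount().astype(str)
    if "plate" not in df.columns:
        df["plate"] = "plate1"
    dup = df.duplicated(["sample_id", "gene", "well"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise DuplicateRecordError(
            f"duplicate (sample_id, gene, well) records at rows {rows}"
        )
    cq, rejected = _parse_cq_column(df["cq"])
    diagnostics = [
        f"row {i}: rejected cq value {df.at[i, 'cq']!r} "
        f"(not a finite Cq in ({CQ_LOW:g}, {CQ_HIGH:g}))"
        for i in df.index[rejected]
    ]
    df["cq"] = cq
    meta = _build_meta(df)
    wells = df.loc[~rejected, ["sample_id", "gene", "cq", "plate", "well"]].reset_index(
        drop=True
    )
    return CqTable(meta=meta, wells=wells, diagnostics=diagnostics)


def _read_wide(df: pd.DataFrame, meta_path: str | Path | None) -> CqTable:
    first = df.columns[0]
    if first.lower() != "gene":
        raise SchemaError(f"wide dialect: first column must be 'gene', got {first!r}")
    df = df.set_index(first)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    diagnostics: list[str] = []
    parsed = {}
    for col in df.columns:
        vals, rejected = _parse_cq_column(df[col])
        vals[rejected] = np.nan
        diagnostics += [
            f"cell ({g!r}, {col!r}): rejected cq value {df.at[g, col]!r}"
            for g in df.index[rejected]
        ]
        parsed[col] = vals
    cq = pd.DataFrame(parsed, index=df.index)
    if meta_path is not None:
        mdf = _read_table(meta_path)
        if "sample_id" not in mdf.columns:
            raise SchemaError("metadata file: missing required column: 'sample_id'")
        meta = _build_meta(mdf)
        missing = set(cq.columns) - set(meta.index)
        if missing:
            raise SchemaError(f"metadata missing for samples: {sorted(missing)}")
        meta = meta.loc[list(cq.columns)]
    else:
        meta = _build_meta(pd.DataFrame({"sample_id": cq.columns}))
    return CqTable(meta=meta, cq=cq, diagnostics=diagnostics)


def collapse_replicates(t: CqTable, max_sd: float = 0.5) -> CqTable:
    """Collapse replicate wells to per-(gene, sample) mean Cq.

    The replicate standard deviation (n-1 denominator; 0 for singleton
    wells, with a note) is recorded alongside, and cells whose replicate SD
    exceeds ``max_sd`` cycles are flagged -- never dropped.
    """
    if t.is_collapsed:
        raise SchemaError("collapse_replicates requires a replicate-level table")
    wells = t.wells.dropna(subset=["cq"])
    grouped = wells.groupby(["gene", "sample_id"])["cq"]
    mean = grouped.mean().unstack()
    sd = grouped.std(ddof=1).unstack()
    n = grouped.size().unstack()
    warnings = list(t.warnings)
    singletons = int(((n == 1) & mean.notna()).to_numpy().sum())
    if singletons:
        warnings.append(
            f"{singletons} (gene, sample) cell(s) had a single replicate; SD set to 0"
        )
    sd = sd.where(~(n == 1), 0.0)
    # align to the full sample set (samples with no usable well stay missing)
    all_samples = list(t.meta.index)
    mean = mean.reindex(columns=all_samples)
    sd = sd.reindex(columns=all_samples)
    empty = int(mean.isna().to_numpy().sum())
    if empty:
        warnings.append(f"{empty} (gene, sample) cell(s) have no replicate; left missing")
    flags = (sd > max_sd).fillna(False)
    nflag = int(flags.to_numpy().sum())
    if nflag:
        warnings.append(f"{nflag} cell(s) flagged with replicate SD > {max_sd:g} cycles")
    return CqTable(
        meta=t.meta,
        cq=mean,
        cq_sd=sd,
        sd_flags=flags,
        plate_offsets=t.plate_offsets,
        diagnostics=list(t.diagnostics),
        warnings=warnings,
    )


def plate_calibrate(
    t: CqTable,
    reference_plate: str | None = None,
    per_gene: bool = False,
) -> CqTable:
    """Between-plate correction via calibrator samples shared across plates.

    For each plate p, the offset is the mean over shared (calibrator, gene)
    pairs of (Cq on p - Cq on the reference plate); that offset is then
    subtracted from every Cq on plate p.  Offsets are pooled across genes by
    default (``per_gene=True`` computes and applies per-gene offsets).
    Requires a replicate-level table carrying a ``plate`` column.
    """
    if t.is_collapsed:
        raise SchemaError("plate_calibrate requires a replicate-level table")
    wells = t.wells
    plates = sorted(wells["plate"].unique())
    if reference_plate is None:
        reference_plate = plates[0]
    elif reference_plate not in plates:
        raise CalibrationError(f"reference plate {reference_plate!r} not present")
    calib = set(t.meta.index[t.meta["is_calibrator"].astype(bool)])
    if not calib:
        raise CalibrationError("no calibrator samples (is_calibrator) in metadata")
    cal = wells[wells["sample_id"].isin(calib)]
    # mean calibrator Cq per (plate, sample, gene)
    means = cal.groupby(["plate", "sample_id", "gene"])["cq"].mean()
    ref = means.xs(reference_plate, level="plate")
    offsets: dict = {}
    no_shared = []
    for p in plates:
        if p == reference_plate:
            offsets[p] = 0.0 if not per_gene else pd.Series(0.0, index=sorted(wells["gene"].unique()))
            continue
        diff = (means.xs(p, level="plate") - ref).dropna()
        if diff.empty:
            no_shared.append(p)
            continue
        if per_gene:
            offsets[p] = diff.groupby("gene").mean()
        else:
            offsets[p] = float(diff.mean())
    if no_shared:
        raise CalibrationError(
            f"plate(s) with no calibrator shared with {reference_plate!r}: {no_shared}"
        )
    new_wells = wells.copy()
    if per_gene:
        for p, series in offsets.items():
            mask = new_wells["plate"] == p
            shift = new_wells.loc[mask, "gene"].map(series).fillna(0.0)
            new_wells.loc[mask, "cq"] = new_wells.loc[mask, "cq"] - shift
        report = {p: dict(s.round(10)) if isinstance(s, pd.Series) else s for p, s in offsets.items()}
    else:
        shift = new_wells["plate"].map(offsets)
        new_wells["cq"] = new_wells["cq"] - shift
        report = {p: float(v) for p, v in offsets.items()}
    return CqTable(
        meta=t.meta,
        wells=new_wells,
        plate_offsets=report,
        diagnostics=list(t.diagnostics),
        warnings=list(t.warnings),
    )


EFFICIENCY_LOW, EFFICIENCY_HIGH = 1.6, 2.1


def linearise(t: CqTable, efficiency=2.0) -> RqTable:
    """Linearise collapsed Cq values to relative quantities.

    ``RQ[g, s] = E_g ** (min_s' Cq[g, s'] - Cq[g, s])`` so the minimum-Cq
    sample of each gene has RQ exactly 1 and all RQ lie in (0, 1].
    ``efficiency`` is a scalar, dict or Series of per-gene amplification
    factors (2.0 = perfect doubling).
    """
    if not t.is_collapsed:
        raise SchemaError("linearise requires a collapsed table (collapse_replicates first)")
    genes = list(t.cq.index)
    if np.isscalar(efficiency):
        eff = pd.Series(float(efficiency), index=genes)
    else:
        eff = pd.Series(efficiency).astype(float)
        missing = set(genes) - set(eff.index)
        if missing:
            raise SchemaError(f"efficiency missing for genes: {sorted(missing)}")
        eff = eff.loc[genes]
    if ((eff < EFFICIENCY_LOW) | (eff > EFFICIENCY_HIGH)).any():
        bad = eff[(eff < EFFICIENCY_LOW) | (eff > EFFICIENCY_HIGH)]
        raise SchemaError(
            f"efficiencies outside [{EFFICIENCY_LOW}, {EFFICIENCY_HIGH}]: {dict(bad)}"
        )
    delta = t.cq.min(axis=1, skipna=True).to_numpy()[:, None] - t.cq.to_numpy()
    rq = pd.DataFrame(
        np.power(eff.to_numpy()[:, None], delta), index=genes, columns=t.cq.columns
    )
    return RqTable(rq=rq, meta=t.meta, efficiency=eff)


def complete_case(
    frame: pd.DataFrame, max_missing_frac: float = 0.2
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Complete-case gene x sample submatrix for downstream analyses.

    Genes missing in more than ``max_missing_frac`` of the samples are
    excluded first; remaining samples with any missing value are then
    dropped.  Returns (submatrix, excluded_genes, dropped_samples).
    """
    frac = frame.isna().mean(axis=1)
    excluded = list(frame.index[frac > max_missing_frac])
    kept = frame.drop(index=excluded)
    dropped = list(kept.columns[kept.isna().any(axis=0)])
    return kept.drop(columns=dropped), excluded, dropped
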