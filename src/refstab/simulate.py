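"""Synthetic Cq dataset generator with ground truth.

The generator emulates a developmental RT-qPCR reference-gene study: 44
samples (24 whole embryos over seven gestational days E11.5-E18.5, 11
heads and 9 forelimbs over E13.5/E16.5/E18.5), a 15-gene candidate panel,
technical replicate wells, plate offsets corrected via shared calibrator
samples, a global per-sample quality effect, and a cDNA-batch-specific
random-priming failure hitting only the rRNA-like gene.

The well-level model (Cq cycles; lower Cq = more template) is

    Cq[g,s,w] = baseline_g
                - slope_{g,tissue(s)} * (age_s - age0)      # expression trend
                + c_g * u_s                                  # shared latent
                + q_s                                        # sample quality
                + plate_offset[plate(s,w)]
                + delta_b * 1[g priming-sensitive]           # priming failure
                + bio[g,s] ~ N(0, sigma_g^2)
                + tech[g,s,w] ~ N(0, sigma_tech^2)

Gene archetypes control baseline, trend slopes (log2 expression per day,
entering Cq with a minus sign), latent loading, gene noise and priming
sensitivity.  Every realized effect is recorded in ``SyntheticTruth`` so
parameter-recovery tests can compare estimates against truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .io import CqTable

AGE_CENTER = 14.5  # design midpoint: baselines are mid-gestation expectations


@dataclass(frozen=True)
class GeneArchetype:
    """Generating parameters for one candidate gene.

    ``slopes`` maps tissue -> log2-expression change per gestational day
    ("*" sets a common slope for all tissues); the Cq contribution is
    ``-slope * (age - age0)``.  ``latent_loading`` couples the gene to the
    shared per-sample latent trajectory (Cq cycles per latent unit).
    ``archetype`` is the ground-truth class used by recovery tests:
    stable | noisy | trending | cotrending | rrna.
    """

    name: str
    baseline_cq: float
    sigma_g: float
    slopes: dict[str, float] = field(default_factory=dict)
    latent_loading: float = 0.0
    priming_sensitive: bool = False
    archetype: str = "stable"

    def __post_init__(self) -> None:
        if not 5.0 < self.baseline_cq < 40.0:
            raise SchemaError(f"{self.name}: baseline_cq must be in (5, 40)")
        if self.sigma_g < 0:
            raise SchemaError(f"{self.name}: sigma_g must be >= 0")

    def slope(self, tissue: str) -> float:
        return self.slopes.get(tissue, self.slopes.get("*", 0.0))


@dataclass(frozen=True)
class StudyDesign:
    """Sample layout: per-tissue (age_days, n) blocks plus assignment policy."""

    blocks: tuple[tuple[str, float, int], ...]  # (tissue, age_days, n_samples)
    replicates: int = 3
    n_plates: int = 3
    n_batches: int = 4
    n_calibrators: int = 3

    @property
    def n_samples(self) -> int:
        return sum(n for _, _, n in self.blocks)

    def tissue_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tissue, _, n in self.blocks:
            out[tissue] = out.get(tissue, 0) + n
        return out


def default_design() -> StudyDesign:
    """The 44-sample developmental layout (24 embryos, 11 heads, 9 forelimbs)."""
    embryo = [(11.5, 3), (12.5, 3), (13.5, 4), (14.5, 3), (15.5, 3), (16.5, 3), (18.5, 5)]
    head = [(13.5, 3), (16.5, 3), (18.5, 5)]
    forelimb = [(13.5, 3), (16.5, 3), (18.5, 3)]
    blocks = (
        *[("embryo", a, n) for a, n in embryo],
        *[("head", a, n) for a, n in head],
        *[("forelimb", a, n) for a, n in forelimb],
    )
    return StudyDesign(blocks=blocks)


@dataclass(frozen=True)
class SimParams:
    """Noise and artifact configuration (Cq cycles unless noted)."""

    sigma_q: float = 0.5  # per-sample quality effect SD
    sigma_tech: float = 0.15  # per-well technical noise SD
    sigma_plate: float = 0.3  # between-plate offset SD
    priming_shift: float = 3.0  # Cq added to priming-sensitive genes in the bad batch
    priming_batch: str | None = "B2"  # None disables the artifact
    litter_sd: float = 0.0  # optional litter effect, off by default
    age_center: float = AGE_CENTER

    def validate(self) -> None:
        for name in ("sigma_q", "sigma_tech", "sigma_plate", "litter_sd"):
            if getattr(self, name) < 0:
                raise SchemaError(f"{name} must be >= 0")


def default_archetypes() -> list[GeneArchetype]:
    """The default 15-gene panel.

    Six trend-free housekeeping candidates; two noisy-but-trendless
    classics (GAPDH, SDHA); two genes upregulated with gestational age
    (HPRT1, B2M); a co-trending pair sharing a mild age decrease and a
    strong common latent loading (CDC40, HTATSF1); two tissue-conditional
    genes whose trend direction depends on tissue (CYC1, EIF4A); and an
    abundant rRNA-like gene exposed to the random-priming artifact (18S).

    The latent trajectory models a per-sample RNA-quality/composition axis
    to which transcripts are differentially sensitive: the housekeeping
    cluster responds coherently (loading 0.65), the co-regulated pair more
    strongly (0.95), developmentally-driven genes only weakly (0.40) and
    the rRNA/noisy genes not at all.  This is what makes the pair's
    behaviour method-dependent, as observed for co-regulated genes in real
    panels: pairwise-ratio methods see two genes that track each other
    tightly, variance-based methods see two genes that deviate from the
    panel consensus.
    """
    A = GeneArchetype
    return [
        A("ACTB", 17.0, 0.27, latent_loading=0.65, archetype="stable"),
        A("RPL13A", 18.0, 0.28, latent_loading=0.65, archetype="stable"),
        A("AP3D1", 22.0, 0.28, latent_loading=0.65, archetype="stable"),
        A("PAK1IP1", 23.0, 0.29, latent_loading=0.65, archetype="stable"),
        A("CSNK2A2", 22.0, 0.29, latent_loading=0.65, archetype="stable"),
        A("UBC", 19.0, 0.30, latent_loading=0.65, archetype="stable"),
        A("SDHA", 21.0, 0.28, archetype="noisy"),
        A("GAPDH", 18.0, 0.30, slopes={"*": 0.05}, archetype="noisy"),
        A("HPRT1", 22.0, 0.15, slopes={"*": 0.25}, latent_loading=0.40, archetype="trending"),
        A("B2M", 19.0, 0.15, slopes={"*": 0.30}, latent_loading=0.40, archetype="trending"),
        A("CYC1", 21.0, 0.15, slopes={"embryo": 0.08, "head": -0.25, "forelimb": 0.28}, latent_loading=0.40, archetype="trending"),
        A("EIF4A", 24.0, 0.15, slopes={"embryo": -0.06, "head": 0.25, "forelimb": -0.25}, latent_loading=0.40, archetype="trending"),
        A("CDC40", 23.0, 0.10, slopes={"*": -0.02}, latent_loading=0.95, archetype="cotrending"),
        A("HTATSF1", 22.0, 0.10, slopes={"*": -0.02}, latent_loading=0.95, archetype="cotrending"),
        A("18S", 10.0, 0.12, priming_sensitive=True, archetype="rrna"),
    ]


@dataclass
class SyntheticTruth:
    """Every realized effect of one simulation, for parameter-recovery tests."""

    seed: int
    design: StudyDesign
    params: SimParams
    archetypes: list[GeneArchetype]
    q: pd.Series  # per-sample quality offsets
    u: pd.Series  # per-sample latent trajectory
    plate_offsets: dict[str, float]
    batch_offsets: dict[str, float]  # priming shift per batch (on sensitive genes)
    litter_offsets: dict[str, float]

    def by_class(self, *classes: str) -> list[str]:
        return [a.name for a in self.archetypes if a.archetype in classes]

    @property
    def stable_genes(self) -> list[str]:
        return self.by_class("stable")

    @property
    def trending_genes(self) -> list[str]:
        return self.by_class("trending")

    @property
    def cotrending_pair(self) -> tuple[str, str]:
        pair = self.by_class("cotrending")
        return tuple(sorted(pair))  # type: ignore[return-value]

    def expected_cq(self, meta: pd.DataFrame) -> pd.DataFrame:
        """Noise-free Cq (gene x sample): all systematic terms, no plate/bio/tech."""
        rows = {}
        for a in self.archetypes:
            vals = []
            for s, m in meta.iterrows():
                cq = a.baseline_cq - a.slope(m["tissue"]) * (
                    m["age_days"] - self.params.age_center
                )
                cq += a.latent_loading * self.u[s] + self.q[s]
                cq += self.litter_offsets.get(m["litter"], 0.0)
                if a.priming_sensitive:
                    cq += self.batch_offsets.get(m["cdna_batch"], 0.0)
                vals.append(cq)
            rows[a.name] = vals
        return pd.DataFrame(rows, index=meta.index).T

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "design": {
                "blocks": [list(b) for b in self.design.blocks],
                "replicates": self.design.replicates,
                "n_plates": self.design.n_plates,
                "n_batches": self.design.n_batches,
                "n_calibrators": self.design.n_calibrators,
            },
            "archetypes": [dataclasses.asdict(a) for a in self.archetypes],
            "q": self.q.round(10).to_dict(),
            "u": self.u.round(10).to_dict(),
            "plate_offsets": self.plate_offsets,
            "batch_offsets": self.batch_offsets,
            "litter_offsets": self.litter_offsets,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _sample_frame(design: StudyDesign) -> pd.DataFrame:
    """Sample ids, tissues, ages, litters, batches, plates, calibrator flags."""
    rows = []
    for tissue, age, n in design.blocks:
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{tissue}_E{age:g}_{i + 1}",
                    "tissue": tissue,
                    "age_days": age,
                    # one litter per (tissue, age) block, split when large
                    "litter": f"L_{tissue[0]}{age:g}" + ("b" if i >= 4 else ""),
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    idx = np.arange(len(meta))
    per_batch = int(np.ceil(len(meta) / design.n_batches))
    meta["cdna_batch"] = [f"B{1 + i // per_batch}" for i in idx]
    meta["plate"] = [f"P{1 + i % design.n_plates}" for i in idx]
    meta["is_calibrator"] = False
    meta.iloc[: design.n_calibrators, meta.columns.get_loc("is_calibrator")] = True
    return meta


def simulate(
    design: StudyDesign | None = None,
    archetypes: list[GeneArchetype] | None = None,
    params: SimParams | None = None,
    seed: int = 0,
) -> tuple[CqTable, SyntheticTruth]:
    """Draw one replicate-level synthetic dataset plus its ground truth.

    The same seed always yields the same dataset.  Calibrator samples are
    measured on every plate (so between-plate offsets are identifiable);
    all other samples sit on a single plate.
    """
    design = design or default_design()
    archetypes = archetypes or default_archetypes()
    params = params or SimParams()
    params.validate()
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate gene names in archetype list")

    rng = np.random.default_rng(seed)
    meta = _sample_frame(design)
    samples = list(meta.index)
    n = len(samples)

    q = pd.Series(rng.normal(0.0, params.sigma_q, n), index=samples)
    # latent trajectory, standardized across the sample set: the loadings
    # c_g carry the scale, so the realized amplitude is fixed by design
    u_raw = rng.normal(0.0, 1.0, n)
    u = pd.Series((u_raw - u_raw.mean()) / u_raw.std(ddof=0), index=samples)
    plates = sorted(meta["plate"].unique())
    plate_offsets = dict(zip(plates, rng.normal(0.0, params.sigma_plate, len(plates))))
    plate_offsets[plates[0]] = 0.0  # reference plate
    litters = sorted(meta["litter"].unique())
    litter_offsets = (
        dict(zip(litters, rng.normal(0.0, params.litter_sd, len(litters))))
        if params.litter_sd > 0
        else {}
    )
    batches = sorted(meta["cdna_batch"].unique())
    batch_offsets = {}
    if params.priming_batch is not None:
        if params.priming_batch not in batches:
            raise SchemaError(
                f"priming_batch {params.priming_batch!r} not among batches {batches}"
            )
        batch_offsets[params.priming_batch] = params.priming_shift

    truth = SyntheticTruth(
        seed=seed,
        design=design,
        params=params,
        archetypes=list(archetypes),
        q=q,
        u=u,
        plate_offsets={k: float(v) for k, v in plate_offsets.items()},
        batch_offsets=batch_offsets,
        litter_offsets={k: float(v) for k, v in litter_offsets.items()},
    )
    systematic = truth.expected_cq(meta)  # gene x sample, no plate/noise

    k = len(archetypes)
    bio = rng.normal(0.0, 1.0, (k, n)) * np.array([a.sigma_g for a in archetypes])[:, None]

    rows = []
    for gi, a in enumerate(archetypes):
        for si, s in enumerate(samples):
            base = systematic.iat[gi, si] + bio[gi, si]
            # calibrators run on every plate; others on their assigned plate
            sample_plates = plates if meta.at[s, "is_calibrator"] else [meta.at[s, "plate"]]
            for p in sample_plates:
                tech = rng.normal(0.0, params.sigma_tech, design.replicates)
                for w in range(design.replicates):
                    rows.append(
                        (s, a.name, base + plate_offsets[p] + tech[w], p, f"{p}w{w + 1}")
                    )
    wells = pd.DataFrame(rows, columns=["sample_id", "gene", "cq", "plate", "well"])
    table = CqTable(meta=meta, wells=wells)
    return table, truth


def write_long_csv(t: CqTable, path: str | Path) -> None:
    """Write a replicate-level table in the long CSV dialect ``read_cq`` accepts."""
    if t.is_collapsed:
        raise SchemaError("write_long_csv expects a replicate-level table")
    meta = t.meta.drop(columns=["plate"], errors="ignore")
    df = t.wells.merge(meta.reset_index(), on="sample_id", how="left")
    cols = ["sample_id", "gene", "cq", "plate", "well",
            "tissue", "age_days", "litter", "cdna_batch", "is_calibrator"]
    df[cols].to_csv(path, index=False)
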