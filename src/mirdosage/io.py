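"""Domain containers, TSV/BED/YAML readers and writers, and validation.

All genomic coordinates are 0-based, half-open (BED convention).
Expression values are assumed to be on a normalised, log-like scale
already; no platform normalisation is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mirdosage")

HISTOLOGY_LEVELS = ("adenoma", "carcinoma", "cell_line", "unknown")
GAIN_LEVELS = ("gain", "no_gain", "unknown")

#: canonical names of the four target-prediction catalogs
DEFAULT_TOOLS = ("targetscan", "pita", "microcosm", "mirtarbase")

SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "value")


# ---------------------------------------------------------------------------
# segmented copy number
# ---------------------------------------------------------------------------

@dataclass
class SegmentedCNProfile:
    """Per-sample genomic segments carrying log2 copy-number ratios.

    ``segments`` holds columns ``chrom, start, end, value`` with 0-based
    half-open intervals; segments on one chromosome must not overlap.
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seg = self.segments
        missing = {"chrom", "start", "end", "value"} - set(seg.columns)
        if missing:
            raise ValueError(f"segments missing columns {sorted(missing)}")
        if len(seg) == 0:
            raise ValueError(f"sample {self.sample_id!r}: no segments")
        if not np.isfinite(seg["value"].to_numpy(float)).all():
            raise ValueError(f"sample {self.sample_id!r}: non-finite segment value")
        if (seg["start"] >= seg["end"]).any():
            raise ValueError(f"sample {self.sample_id!r}: segment with start >= end")
        for chrom, grp in seg.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]).any():
                raise ValueError(
                    f"overlapping segments in sample {self.sample_id!r} on {chrom}"
                )

    def chrom_segments(self, chrom: str) -> pd.DataFrame:
        """Segments on one chromosome, sorted by start."""
        sel = self.segments[self.segments["chrom"] == chrom]
        return sel.sort_values("start").reset_index(drop=True)


def read_segments(path: str | Path) -> list[SegmentedCNProfile]:
    """Read a SEG-like TSV (sample, chrom, start, end, value) into profiles.

    Rows are grouped by sample in order of first appearance. A non-numeric
    coordinate or value raises with the offending 1-based line number.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SEGMENT_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    conv = {}
    for col in ("start", "end", "value"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} at line {line}")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
            raise ValueError(f"{path}: empty {col!r} at line {line}")
        conv[col] = vals
    df = pd.DataFrame(
        {
            "sample": raw["sample"],
            "chrom": raw["chrom"],
            "start": conv["start"].astype(np.int64),
            "end": conv["end"].astype(np.int64),
            "value": conv["value"].astype(float),
        }
    )
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        profiles.append(
            SegmentedCNProfile(str(sample), grp.drop(columns="sample").reset_index(drop=True))
        )
    return profiles


def write_segments(profiles: Iterable[SegmentedCNProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        df = p.segments.copy()
        df.insert(0, "sample", p.sample_id)
        frames.append(df[list(SEGMENT_COLUMNS)])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomic grid and resampled copy number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicGrid:
    """Equally spaced genomic positions over a genome description.

    Positions are sorted by chromosome (genome insertion order), then bp.
    """

    genome: dict[str, int]
    chrom_index: np.ndarray  # int code per point, indexing into chrom order
    positions: np.ndarray    # bp per point

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.genome)

    @property
    def n_points(self) -> int:
        return int(self.positions.size)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous slice of grid indices on one chromosome."""
        code = self.chroms.index(chrom)
        lo, hi = np.searchsorted(self.chrom_index, [code, code + 1])
        return slice(int(lo), int(hi))

    def labels(self) -> list[str]:
        chroms = self.chroms
        return [f"{chroms[c]}:{p}" for c, p in zip(self.chrom_index, self.positions)]


@dataclass
class GridCNMatrix:
    """Samples x grid-positions matrix of resampled log2 copy number.

    Missing data (a chromosome absent from a sample's segmentation) is NaN.
    """

    samples: list[str]
    grid: GenomicGrid
    values: np.ndarray  # (n_samples, n_points)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), self.grid.n_points):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {self.grid.n_points} grid points"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def restrict_samples(self, samples: Sequence[str]) -> "GridCNMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GridCNMatrix(list(samples), self.grid, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.grid.labels())


def write_gridcn(gridcn: GridCNMatrix, path: str | Path) -> None:
    df = gridcn.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression with optional genomic annotation.

    ``annotation`` (chrom, start), indexed by feature id, carries miRNA
    loci; mRNA matrices are identified by gene-symbol feature ids and
    usually carry no annotation.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy(float)
        if not np.isfinite(vals[~np.isnan(vals)]).all():
            raise ValueError("non-finite expression values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.annotation)

    def locus(self, feature_id: str) -> tuple[str, int] | None:
        """(chrom, start) for a feature, or None when unannotated."""
        if self.annotation is None or feature_id not in self.annotation.index:
            return None
        row = self.annotation.loc[feature_id]
        if pd.isna(row["chrom"]) or pd.isna(row["start"]):
            return None
        return str(row["chrom"]), int(row["start"])


def read_expression(path: str | Path, loci_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a features-x-samples TSV, optionally with a BED locus sidecar.

    The BED sidecar (chrom, start, end, name; no header) annotates features
    by name; loci naming features absent from the matrix are dropped with a
    logged warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    annotation = None
    if loci_path is not None:
        bed = pd.read_csv(
            loci_path, sep="\t", header=None,
            names=["chrom", "start", "end", "name"], dtype={"name": str},
        )
        extra = bed.loc[~bed["name"].isin(df.index), "name"].tolist()
        if extra:
            logger.warning(
                "%d annotation features absent from expression matrix: %s",
                len(extra), extra,
            )
        bed = bed[bed["name"].isin(df.index)]
        annotation = bed.set_index("name")[["chrom", "start"]]
    return ExpressionMatrix(df.astype(float), annotation)


def write_expression(em: ExpressionMatrix, path: str | Path,
                     loci_path: str | Path | None = None) -> None:
    out = em.values.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", na_rep="NA")
    if loci_path is not None and em.annotation is not None:
        bed = em.annotation.copy()
        bed["end"] = bed["start"] + 1
        bed["name"] = bed.index
        bed[["chrom", "start", "end", "name"]].to_csv(
            loci_path, sep="\t", index=False, header=False
        )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """One row per sample: histology and 13q-gain status."""

    table: pd.DataFrame  # indexed by sample_id; columns histology, gain13q

    def __post_init__(self) -> None:
        t = self.table
        missing = {"histology", "gain13q"} - set(t.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        if t.index.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        bad_h = set(t["histology"]) - set(HISTOLOGY_LEVELS)
        if bad_h:
            raise ValueError(f"invalid histology values {sorted(bad_h)}")
        bad_g = set(t["gain13q"]) - set(GAIN_LEVELS)
        if bad_g:
            raise ValueError(f"invalid gain13q values {sorted(bad_g)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def restrict_samples(self, samples: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.table.loc[list(samples)])

    def samples_where(self, histology: str | None = None,
                      gain13q: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if histology is not None:
            mask &= self.table["histology"] == histology
        if gain13q is not None:
            mask &= self.table["gain13q"] == gain13q
        return list(self.table.index[mask])


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    df.index = df.index.astype(str)
    return PhenotypeTable(df[["histology", "gain13q"]])


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    out = pt.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# target-prediction catalogs
# ---------------------------------------------------------------------------

@dataclass
class TargetPredictionCatalog:
    """One tool's predicted (miRNA, gene) pairs."""

    tool_name: str
    pairs: frozenset  # of (mirna_id, gene_symbol)

    def targets_of(self, mirna_id: str) -> set[str]:
        return {g for m, g in self.pairs if m == mirna_id}


def read_catalog(path: str | Path, tool_name: str | None = None) -> TargetPredictionCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mirna", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if tool_name is None:
        if "tool" not in df.columns or df["tool"].nunique() != 1:
            raise ValueError(f"{path}: tool name not given and not unique in file")
        tool_name = str(df["tool"].iloc[0])
    pairs = frozenset(zip(df["mirna"], df["gene"]))
    return TargetPredictionCatalog(tool_name, pairs)


def write_catalog(cat: TargetPredictionCatalog, path: str | Path) -> None:
    rows = sorted(cat.pairs)
    pd.DataFrame(rows, columns=["mirna", "gene"]).assign(tool=cat.tool_name).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# qPCR cycle-threshold tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Raw qPCR Ct values, one per (sample, assay) after replicate averaging."""

    data: pd.DataFrame  # columns sample, assay, ct
    reference_assay: str

    def __post_init__(self) -> None:
        d = self.data
        missing = {"sample", "assay", "ct"} - set(d.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (d["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if d.duplicated(["sample", "assay"]).any():
            raise ValueError("multiple Ct rows per (sample, assay); average replicates first")
        if self.reference_assay not in set(d["assay"]):
            raise ValueError(f"reference assay {self.reference_assay!r} absent from table")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    def restrict_samples(self, samples: Sequence[str]) -> "CtTable":
        sel = self.data[self.data["sample"].isin(set(samples))]
        order = {s: i for i, s in enumerate(samples)}
        sel = sel.sort_values("sample", key=lambda s: s.map(order), kind="stable")
        return CtTable(sel.reset_index(drop=True), self.reference_assay)

    def pivot(self) -> pd.DataFrame:
        """samples x assays matrix of Ct values (NaN where unmeasured)."""
        return self.data.pivot(index="sample", columns="assay", values="ct")


def read_ct(path: str | Path, reference_assay: str) -> CtTable:
    """Read a Ct TSV (sample, assay, ct); technical replicates are averaged
    on the Ct scale."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "assay": str})
    df = (
        df.groupby(["sample", "assay"], sort=False, as_index=False)["ct"].mean()
    )
    return CtTable(df, reference_assay)


def write_ct(ct: CtTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Thresholds and sizes for the dosage-effect cascade.

    window_bp is the *total* width of the copy-number window centred on
    each miRNA start (2 Mb default, i.e. +/-1 Mb).
    """

    window_bp: int = 2_000_000
    fdr_alpha: float = 0.05
    target_p_cut: float = 0.01
    consensus_min_tools: int = 3
    grid_points: int = 30_000
    gain_threshold: float = 0.2
    permutations: int = 9_999
    seed: int = 0
    scale_covariates: bool = True
    exact_cap: int = 5_040  # enumerate all n! permutations when n! <= cap
    region: tuple[str, int, int] | None = None  # restrict tested miRNAs

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.window_bp % 2:
            raise ValueError("window_bp must be a positive even integer")
        if not 0 < self.fdr_alpha <= 1:
            raise ValueError("fdr_alpha must be in (0, 1]")
        if not 0 < self.target_p_cut <= 1:
            raise ValueError("target_p_cut must be in (0, 1]")
        if self.consensus_min_tools < 1:
            raise ValueError("consensus_min_tools must be >= 1")
        if self.grid_points < 1:
            raise ValueError("grid_points must be >= 1")
        if self.permutations < 99:
            raise ValueError("permutations must be >= 99")
        if self.region is not None:
            self.region = (str(self.region[0]), int(self.region[1]), int(self.region[2]))

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["region"] is not None:
            d["region"] = list(d["region"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "region" in raw and raw["region"] is not None:
            raw["region"] = tuple(raw["region"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# sample alignment
# ---------------------------------------------------------------------------

def align_samples(objects: Sequence):
    """Restrict sample-indexed objects to their common samples, common order.

    Order follows the first object. Returns (aligned objects, dropped) where
    dropped maps object position to the sample ids removed from it.
    Raises if fewer than two objects are given or the intersection is empty.
    """
    if len(objects) < 2:
        raise ValueError("align_samples needs at least two objects")
    sample_sets = [set(o.sample_ids) for o in objects]
    common_set = set.intersection(*sample_sets)
    if not common_set:
        raise ValueError("no samples common to all objects")
    common = [s for s in objects[0].sample_ids if s in common_set]
    dropped = {
        i: [s for s in o.sample_ids if s not in common_set]
        for i, o in enumerate(objects)
    }
    for i, d in dropped.items():
        if d:
            logger.info("align_samples: dropped %d samples from object %d", len(d), i)
    return [o.restrict_samples(common) for o in objects], dropped
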