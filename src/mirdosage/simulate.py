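"""Seeded synthetic cohorts with a 13q dosage-effect structure.

The generator emulates the statistical skeleton of a colorectal tumour
cohort: a recurrent chromosome-13q arm gain in a configurable fraction of
samples, a handful of region miRNAs whose expression is affine in their
local copy number (the planted dosage miRNAs), target genes whose
expression is negatively (occasionally positively) coupled to a dosage
miRNA, four noisy target-prediction catalogs, qPCR cycle thresholds
derived from the simulated expression, and histology labels in which
carcinomas are enriched for the gain. Everything is drawn from one seeded
generator, so the same seed yields a bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (CtTable, DEFAULT_TOOLS, ExpressionMatrix, PhenotypeTable,
                 SegmentedCNProfile, TargetPredictionCatalog, read_catalog,
                 read_ct, read_expression, read_phenotypes, read_segments,
                 write_catalog, write_ct, write_expression, write_phenotypes,
                 write_segments)

#: GRCh37 autosome lengths (bp)
DEFAULT_GENOME: dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}

#: start of the chromosome 13 q arm (GRCh37 cytoband boundary, approximate)
Q13_START = 17_900_000
#: the 13q gain region used for arm-level calls and the simulated segment
Q13_REGION = ("chr13", Q13_START, DEFAULT_GENOME["chr13"])

#: the 14 chromosome-13q miRNAs with detectable expression, with genomic
#: start positions (GRCh37); used as the default region annotation
MIRNA_LOCI_13Q: dict[str, int] = {
    "hsa-mir-20a": 90_801_327,
    "hsa-mir-92a-1": 90_801_618,
    "hsa-mir-17": 90_800_874,
    "hsa-mir-15a": 49_521_268,
    "hsa-mir-19a": 90_801_194,
    "hsa-mir-19b-1": 90_801_463,
    "hsa-mir-16-1": 49_521_123,
    "hsa-mir-18a": 90_801_011,
    "hsa-mir-320d-1": 40_199_964,
    "hsa-mir-622": 89_681_504,
    "hsa-mir-623": 98_806_372,
    "hsa-mir-1297": 53_784_118,
    "hsa-mir-1267": 106_981_565,
    "hsa-mir-621": 40_282_935,
}

#: dosage miRNAs planted by default, in preference order
PLANTED_PREFERENCE = ("hsa-mir-15a", "hsa-mir-17", "hsa-mir-20a")


@dataclass
class ScenarioConfig:
    """Generative parameters of one synthetic cohort (the stated world)."""

    n_samples: int = 125
    gain_fraction: float = 0.5
    gain_level_mean: float = 0.4      # log2 ratio of the 13q-arm gain
    gain_level_sd: float = 0.05
    baseline_sd: float = 0.05         # per-sample per-chromosome log2 baseline
    n_mirnas_region: int = 14
    planted_dosage_mirnas: int = 3
    dosage_slope: float = 1.0         # expression units per log2 copy number
    n_genes: int = 2_000
    targets_per_mirna: int = 20
    true_repressed_fraction: float = 0.25
    repression_slope: float = 0.7
    positive_target_fraction: float = 0.05
    noise_sd: float = 0.5
    tool_sensitivity: float = 0.8
    tool_false_targets: int = 30      # decoy pairs per tool per miRNA
    carcinoma_odds_nogain: float = 0.6
    histology_gain_odds: float = 4.0  # odds multiplier for carcinoma given gain
    ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gain_fraction", "true_repressed_fraction",
                     "positive_target_fraction", "tool_sensitivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("gain_level_sd", "baseline_sd", "noise_sd", "ct_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 <= self.planted_dosage_mirnas <= self.n_mirnas_region:
            raise ValueError("planted_dosage_mirnas must be <= n_mirnas_region")
        if self.n_genes < self.n_mirnas_region * self.targets_per_mirna:
            raise ValueError("n_genes too small for the requested target blocks")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class SyntheticCohort:
    """A complete generated cohort plus its ground truth."""

    profiles: list[SegmentedCNProfile]
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    phenotypes: PhenotypeTable
    catalogs: list[TargetPredictionCatalog]
    ct: CtTable
    genome: dict[str, int]
    truth: dict


def _region_loci(config: ScenarioConfig) -> dict[str, int]:
    if config.n_mirnas_region == len(MIRNA_LOCI_13Q):
        return dict(MIRNA_LOCI_13Q)
    lo, hi = Q13_START + 5_000_000, DEFAULT_GENOME["chr13"] - 5_000_000
    starts = np.linspace(lo, hi, config.n_mirnas_region).astype(int)
    return {f"sim-mir-{i + 1}": int(s) for i, s in enumerate(starts)}


def generate_cohort(config: ScenarioConfig | None = None) -> SyntheticCohort:
    """Draw one cohort from the scenario. Same seed, same cohort, bit for bit."""
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    genome = dict(DEFAULT_GENOME)

    # --- gain assignment and copy-number segments -------------------------
    n_gain = int(round(n * config.gain_fraction))
    gain_mask = np.zeros(n, dtype=bool)
    gain_mask[rng.permutation(n)[:n_gain]] = True
    baselines = rng.normal(0.0, config.baseline_sd, size=(n, len(genome)))
    gain_levels = rng.normal(config.gain_level_mean, config.gain_level_sd, size=n)
    chrom_list = list(genome)
    c13 = chrom_list.index("chr13")
    profiles = []
    for i, sid in enumerate(samples):
        rows = []
        for j, chrom in enumerate(chrom_list):
            if chrom == "chr13" and gain_mask[i]:
                rows.append((chrom, 0, Q13_START, baselines[i, j]))
                rows.append((chrom, Q13_START, genome[chrom], gain_levels[i]))
            else:
                rows.append((chrom, 0, genome[chrom], baselines[i, j]))
        profiles.append(SegmentedCNProfile(
            sid, pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        ))

    # --- region miRNAs -----------------------------------------------------
    loci = _region_loci(config)
    mirna_ids = list(loci)
    preferred = [m for m in PLANTED_PREFERENCE if m in loci]
    others = [m for m in mirna_ids if m not in preferred]
    planted = (preferred + others)[: config.planted_dosage_mirnas]
    local_cn = np.empty((len(mirna_ids), n))
    for k, mid in enumerate(mirna_ids):
        on_arm = loci[mid] >= Q13_START
        local_cn[k] = np.where(gain_mask & on_arm, gain_levels, baselines[:, c13])
    mirna_base = rng.normal(6.0, 1.0, size=len(mirna_ids))
    mirna_vals = np.empty((len(mirna_ids), n))
    for k, mid in enumerate(mirna_ids):
        noise = rng.normal(0.0, config.noise_sd, size=n)
        dosage = config.dosage_slope * local_cn[k] if mid in planted else 0.0
        mirna_vals[k] = mirna_base[k] + dosage + noise
    annotation = pd.DataFrame(
        {"chrom": "chr13", "start": [loci[m] for m in mirna_ids]}, index=mirna_ids
    )
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=mirna_ids, columns=samples), annotation
    )

    # --- target genes and mRNA expression ----------------------------------
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    block_idx = rng.choice(config.n_genes,
                           size=config.n_mirnas_region * config.targets_per_mirna,
                           replace=False)
    blocks = {
        mid: [genes[j] for j in block_idx[k * config.targets_per_mirna:
                                          (k + 1) * config.targets_per_mirna]]
        for k, mid in enumerate(mirna_ids)
    }
    n_rep = int(round(config.targets_per_mirna * config.true_repressed_fraction))
    n_pos = int(round(config.targets_per_mirna * config.positive_target_fraction))
    coupled: dict[str, dict[str, list[str]]] = {}
    coupling = {}  # gene -> (mirna index, slope)
    for mid in planted:
        block = blocks[mid]
        pick = rng.permutation(len(block))[: n_rep + n_pos]
        neg = [block[j] for j in pick[:n_rep]]
        pos = [block[j] for j in pick[n_rep:]]
        coupled[mid] = {"negative": neg, "positive": pos}
        k = mirna_ids.index(mid)
        for g in neg:
            coupling[g] = (k, -config.repression_slope)
        for g in pos:
            coupling[g] = (k, config.repression_slope)
    gene_base = rng.normal(7.0, 1.0, size=config.n_genes)
    mrna_vals = gene_base[:, None] + rng.normal(0.0, config.noise_sd,
                                                size=(config.n_genes, n))
    mirna_centered = mirna_vals - mirna_vals.mean(axis=1, keepdims=True)
    for gi, g in enumerate(genes):
        if g in coupling:
            k, slope = coupling[g]
            mrna_vals[gi] += slope * mirna_centered[k]
    mrna = ExpressionMatrix(pd.DataFrame(mrna_vals, index=genes, columns=samples))

    # --- prediction catalogs -----------------------------------------------
    target_gene_set = {g for b in blocks.values() for g in b}
    decoy_pool = np.array([g for g in genes if g not in target_gene_set])
    catalogs = []
    for tool in DEFAULT_TOOLS:
        pairs = set()
        for mid in mirna_ids:
            hits = rng.random(config.targets_per_mirna) < config.tool_sensitivity
            pairs.update((mid, g) for g, h in zip(blocks[mid], hits) if h)
            k_decoys = min(config.tool_false_targets, decoy_pool.size)
            decoys = rng.choice(decoy_pool, size=k_decoys, replace=False)
            pairs.update((mid, str(g)) for g in decoys)
        catalogs.append(TargetPredictionCatalog(tool, frozenset(pairs)))

    # --- phenotypes ---------------------------------------------------------
    odds = np.where(gain_mask,
                    config.carcinoma_odds_nogain * config.histology_gain_odds,
                    config.carcinoma_odds_nogain)
    p_carc = odds / (1.0 + odds)
    carcinoma = rng.random(n) < p_carc
    phen = pd.DataFrame(
        {
            "histology": np.where(carcinoma, "carcinoma", "adenoma"),
            "gain13q": np.where(gain_mask, "gain", "no_gain"),
        },
        index=pd.Index(samples, name="sample"),
    )
    phenotypes = PhenotypeTable(phen)

    # --- qPCR cycle thresholds ----------------------------------------------
    ref_candidates = [m for m in mirna_ids if m not in planted]
    ref_assay = ("hsa-mir-16-1" if "hsa-mir-16-1" in ref_candidates
                 else (ref_candidates[0] if ref_candidates else mirna_ids[0]))
    assays = list(planted) + [ref_assay]
    offsets = rng.uniform(28.0, 34.0, size=len(assays))
    rows = []
    for off, assay in zip(offsets, assays):
        expr = mirna_vals[mirna_ids.index(assay)]
        cts = off - expr + rng.normal(0.0, config.ct_noise_sd, size=n)
        rows.extend(zip(samples, [assay] * n, cts))
    ct = CtTable(pd.DataFrame(rows, columns=["sample", "assay", "ct"]), ref_assay)

    truth = {
        "planted_mirnas": list(planted),
        "targets": coupled,
        "predicted_blocks": blocks,
        "gain_samples": [s for s, g in zip(samples, gain_mask) if g],
        "reference_assay": ref_assay,
        "scenario": config.to_dict(),
    }
    return SyntheticCohort(profiles, mirna, mrna, phenotypes, catalogs, ct,
                           genome, truth)


def truth_metrics(result, truth: dict) -> dict:
    """Recovery metrics of a cascade run against the generating truth.

    sensitivity: planted miRNAs selected / planted; false_selections:
    selected non-planted miRNAs; target_recovery: coupled target genes of
    planted miRNAs retained at the individual-p cut; sign_accuracy:
    fraction of retained coupled targets whose sign matches the truth.
    """
    planted = list(truth["planted_mirnas"])
    universe = set(result.summary["mirna"])
    if planted and not set(planted) <= universe:
        raise ValueError("truth refers to miRNAs absent from the cascade result")
    selected = set(result.selected)
    sensitivity = (len(selected & set(planted)) / len(planted)) if planted else float("nan")
    false_selections = len(selected - set(planted))
    truth_pairs = {}
    for mid, d in truth["targets"].items():
        for g in d["negative"]:
            truth_pairs[(mid, g)] = "negative"
        for g in d["positive"]:
            truth_pairs[(mid, g)] = "positive"
    retained = set(zip(result.targets["mirna"], result.targets["gene"]))
    hit = retained & set(truth_pairs)
    target_recovery = (len(hit) / len(truth_pairs)) if truth_pairs else float("nan")
    if hit:
        signs = result.targets.set_index(["mirna", "gene"])["sign"]
        correct = sum(signs[pair] == truth_pairs[pair] for pair in hit)
        sign_accuracy = correct / len(hit)
    else:
        sign_accuracy = float("nan")
    return {
        "sensitivity": sensitivity,
        "false_selections": false_selections,
        "target_recovery": target_recovery,
        "sign_accuracy": sign_accuracy,
    }


# ---------------------------------------------------------------------------
# cohort directory round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> list[Path]:
    """Write a cohort as plain-text files; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "catalogs").mkdir(exist_ok=True)
    paths = []

    def _p(name: str) -> Path:
        paths.append(outdir / name)
        return outdir / name

    write_segments(cohort.profiles, _p("segments.seg"))
    write_expression(cohort.mirna, _p("mirna.tsv"), _p("loci.bed"))
    write_expression(cohort.mrna, _p("mrna.tsv"))
    write_phenotypes(cohort.phenotypes, _p("phenotype.tsv"))
    for cat in cohort.catalogs:
        write_catalog(cat, _p(f"catalogs/{cat.tool_name}.tsv"))
    write_ct(cohort.ct, _p("ct.tsv"))
    genome = pd.DataFrame(cohort.genome.items(), columns=["chrom", "length"])
    genome.to_csv(_p("genome.tsv"), sep="\t", index=False)
    with open(_p("truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return paths


def read_cohort(indir: str | Path) -> SyntheticCohort:
    """Read a cohort directory written by write_cohort (truth optional)."""
    indir = Path(indir)
    profiles = read_segments(indir / "segments.seg")
    mirna = read_expression(indir / "mirna.tsv", indir / "loci.bed")
    mrna = read_expression(indir / "mrna.tsv")
    phenotypes = read_phenotypes(indir / "phenotype.tsv")
    catalogs = [read_catalog(p) for p in sorted((indir / "catalogs").glob("*.tsv"))]
    genome_df = pd.read_csv(indir / "genome.tsv", sep="\t")
    genome = dict(zip(genome_df["chrom"].astype(str), genome_df["length"].astype(int)))
    truth_path = indir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    ref = truth.get("reference_assay")
    if ref is None:
        ct_df = pd.read_csv(indir / "ct.tsv", sep="\t")
        ref = str(ct_df["assay"].iloc[-1])
    ct = read_ct(indir / "ct.tsv", ref)
    return SyntheticCohort(profiles, mirna, mrna, phenotypes, catalogs, ct,
                           genome, truth)
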