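"""Two-level dosage-effect inference.

Level 1 asks, per miRNA, whether the copy-number values in a window around
its locus are jointly associated with its expression (dosage effect).
Level 2 asks whether the expression of its consensus-predicted target
genes is jointly associated with its expression (downstream effect).
miRNAs passing the BH-FDR filter at both levels are candidates; their
individual targets are then prioritised with single-covariate tests and
annotated with the correlation sign.

The miRNA expression vector is always the response; copy number or target
expression always the covariate set. Do not invert this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cngrid import window_covariates
from .io import AnalysisConfig, ExpressionMatrix, GridCNMatrix, TargetPredictionCatalog
from .stats import (association_sign, bh_fdr, draw_permutations,
                    global_test_pvalue)

logger = logging.getLogger("mirdosage")


@dataclass
class ConsensusTargetSet:
    """Genes predicted as targets of one miRNA by >= min_tools catalogs."""

    mirna_id: str
    genes: set[str]
    support: dict[str, int]  # gene -> number of tools predicting it


def consensus_targets(catalogs: list[TargetPredictionCatalog], mirna_id: str,
                      min_tools: int = 3) -> ConsensusTargetSet:
    """Combine prediction catalogs into one consensus target set."""
    if len(catalogs) < min_tools:
        raise ValueError(
            f"{len(catalogs)} catalogs supplied but min_tools={min_tools}"
        )
    tally: dict[str, int] = {}
    seen = False
    for cat in catalogs:
        targets = cat.targets_of(mirna_id)
        seen = seen or bool(targets)
        for g in targets:
            tally[g] = tally.get(g, 0) + 1
    if not seen:
        logger.warning("miRNA %s absent from all prediction catalogs", mirna_id)
    genes = {g for g, k in tally.items() if k >= min_tools}
    return ConsensusTargetSet(mirna_id, genes, {g: tally[g] for g in genes})


def consensus_for_all(catalogs: list[TargetPredictionCatalog],
                      mirna_ids, min_tools: int = 3) -> dict[str, ConsensusTargetSet]:
    return {m: consensus_targets(catalogs, m, min_tools) for m in mirna_ids}


def _shared_permutations(config: AnalysisConfig, n: int,
                         rng: np.random.Generator | None) -> np.ndarray | None:
    """One permutation-index matrix shared across a stage's tests.

    Sharing keeps a stage deterministic per feature (a duplicated response
    row gets an identical p) and amortises the draw. None when small n
    triggers exact enumeration instead.
    """
    if math.factorial(n) <= config.exact_cap:
        return None
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return draw_permutations(rng, config.permutations, n)


def _in_region(chrom: str, start: int, region) -> bool:
    return region is None or (
        chrom == region[0] and region[1] <= start < region[2]
    )


def associate_cn(mirnas: ExpressionMatrix, gridcn: GridCNMatrix,
                 config: AnalysisConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Association 1: windowed copy-number covariate set -> miRNA expression.

    Returns one row per tested miRNA (mirna, chrom, start, n_covariates,
    n_samples, statistic, p, fdr, method). miRNAs without a locus (or
    outside config.region) are skipped with a warning; samples with missing
    window values are dropped per miRNA.
    """
    if mirnas.sample_ids != gridcn.sample_ids:
        raise ValueError("inputs are not sample-aligned; call align_samples first")
    n = len(mirnas.sample_ids)
    perms = _shared_permutations(config, n, rng)
    rows = []
    for mid in mirnas.feature_ids:
        locus = mirnas.locus(mid)
        if locus is None:
            logger.warning("miRNA %s has no locus annotation; skipped", mid)
            continue
        chrom, start = locus
        if not _in_region(chrom, start, config.region):
            continue
        wcs = window_covariates(mid, chrom, start, gridcn, config.window_bp)
        X = wcs.values
        y = mirnas.values.loc[mid].to_numpy(float)
        ok = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
        if ok.sum() < n:
            logger.info("miRNA %s: %d samples dropped for missing data", mid, n - ok.sum())
        res = global_test_pvalue(
            y[ok], X[ok], B=config.permutations, scale=config.scale_covariates,
            exact_cap=config.exact_cap,
            perm_indices=perms if ok.all() and perms is not None else None,
            seed=np.random.default_rng(config.seed) if not ok.all() else None,
        )
        rows.append((mid, chrom, start, X.shape[1], int(ok.sum()),
                     res.statistic, res.p_value, res.method))
    out = pd.DataFrame(rows, columns=["mirna", "chrom", "start", "n_covariates",
                                      "n_samples", "statistic", "p", "method"])
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out[["mirna", "chrom", "start", "n_covariates", "n_samples",
                "statistic", "p", "fdr", "method"]]


def associate_targets(mirnas: ExpressionMatrix, mrnas: ExpressionMatrix,
                      consensus: dict[str, ConsensusTargetSet],
                      config: AnalysisConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Association 2: consensus target-expression covariate set -> miRNA.

    A miRNA whose consensus set is empty (or entirely absent from the mRNA
    matrix) is not determined — its fdr is NaN and it is excluded from the
    BH denominator, mirroring "n.d." in published summaries.
    """
    if mirnas.sample_ids != mrnas.sample_ids:
        raise ValueError("inputs are not sample-aligned; call align_samples first")
    n = len(mirnas.sample_ids)
    perms = _shared_permutations(config, n, rng)
    mrna_index = set(mrnas.feature_ids)
    rows = []
    for mid in mirnas.feature_ids:
        cset = consensus.get(mid)
        genes = sorted(cset.genes & mrna_index) if cset is not None else []
        if cset is not None and len(genes) < len(cset.genes):
            logger.warning("miRNA %s: %d consensus genes absent from mRNA matrix",
                           mid, len(cset.genes) - len(genes))
        if not genes:
            rows.append((mid, 0, np.nan, np.nan, False, "none"))
            continue
        X = mrnas.values.loc[genes].to_numpy(float).T
        y = mirnas.values.loc[mid].to_numpy(float)
        res = global_test_pvalue(
            y, X, B=config.permutations, scale=config.scale_covariates,
            exact_cap=config.exact_cap, perm_indices=perms,
        )
        rows.append((mid, len(genes), res.statistic, res.p_value, True, res.method))
    out = pd.DataFrame(rows, columns=["mirna", "n_targets", "statistic", "p",
                                      "determined", "method"])
    out["fdr"] = np.nan
    det = out["determined"].to_numpy()
    if det.any():
        out.loc[det, "fdr"] = bh_fdr(out.loc[det, "p"].to_numpy())
    return out


def select_candidates(cn_results: pd.DataFrame, target_results: pd.DataFrame,
                      fdr_alpha: float = 0.05) -> list[str]:
    """miRNAs significant at both levels (not-determined never selects).

    Inputs need columns (mirna, fdr) and (mirna, fdr [, determined]); a NaN
    level-2 fdr counts as not determined.
    """
    if len(cn_results) == 0 or len(target_results) == 0:
        return []
    cn = cn_results.set_index("mirna")["fdr"]
    tg = target_results.set_index("mirna")
    det = tg["determined"] if "determined" in tg.columns else tg["fdr"].notna()
    selected = []
    for mid in cn.index:
        if mid not in tg.index:
            continue
        if (cn[mid] < fdr_alpha and bool(det[mid])
                and not pd.isna(tg.loc[mid, "fdr"])
                and tg.loc[mid, "fdr"] < fdr_alpha):
            selected.append(mid)
    return selected


def prioritize_targets(mirna_id: str, mirnas: ExpressionMatrix,
                       mrnas: ExpressionMatrix, cset: ConsensusTargetSet,
                       config: AnalysisConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Single-covariate global test per consensus gene; keep raw p < cut.

    Returns (gene, statistic, p, sign) sorted by p then gene. The threshold
    is strict on the raw p-value. Output is invariant to gene input order
    and deterministic under a fixed seed.
    """
    if mirnas.sample_ids != mrnas.sample_ids:
        raise ValueError("inputs are not sample-aligned; call align_samples first")
    y = mirnas.values.loc[mirna_id].to_numpy(float)
    n = y.size
    perms = _shared_permutations(config, n, rng)
    mrna_index = set(mrnas.feature_ids)
    rows = []
    for gene in sorted(cset.genes):
        if gene not in mrna_index:
            logger.warning("gene %s absent from mRNA matrix; skipped", gene)
            continue
        t = mrnas.values.loc[gene].to_numpy(float)
        res = global_test_pvalue(
            y, t[:, None], B=config.permutations, scale=config.scale_covariates,
            exact_cap=config.exact_cap, perm_indices=perms,
        )
        if res.p_value < config.target_p_cut:
            rows.append((mirna_id, gene, res.statistic, res.p_value,
                         association_sign(y, t)))
    out = pd.DataFrame(rows, columns=["mirna", "gene", "statistic", "p", "sign"])
    return out.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)


def filter_printed_targets(table: pd.DataFrame, p_cut: float = 0.01,
                           decimals: int = 3) -> pd.DataFrame:
    """Apply the individual-target p filter to an already-printed table.

    Published tables round p to a fixed number of decimals, so a printed
    value exactly equal to the cut (e.g. 0.010 under a < 0.01 rule) is
    consistent with a raw p below it; such boundary rows are retained.
    Expects columns (gene, p) at least.
    """
    p = table["p"].to_numpy(float)
    keep = (p < p_cut) | (np.round(p, decimals) == np.round(p_cut, decimals))
    return table[keep].reset_index(drop=True)


@dataclass
class CascadeResult:
    """Joined two-level summary plus per-target rows for selected miRNAs."""

    summary: pd.DataFrame       # mirna, chrom, start, cn_p, cn_fdr, target_*, selected
    targets: pd.DataFrame       # mirna, gene, statistic, p, sign
    selected: list[str] = field(default_factory=list)


def run_cascade(mirnas: ExpressionMatrix, mrnas: ExpressionMatrix,
                gridcn: GridCNMatrix, catalogs: list[TargetPredictionCatalog],
                config: AnalysisConfig) -> CascadeResult:
    """Association 1 + consensus + association 2 + selection + prioritisation."""
    rng = np.random.default_rng(config.seed)
    cn = associate_cn(mirnas, gridcn, config, rng)
    consensus = consensus_for_all(catalogs, list(cn["mirna"]),
                                  config.consensus_min_tools)
    tg = associate_targets(mirnas, mrnas, consensus, config, rng)
    tg = tg[tg["mirna"].isin(cn["mirna"])].reset_index(drop=True)
    selected = select_candidates(cn, tg, config.fdr_alpha)
    target_rows = [
        prioritize_targets(mid, mirnas, mrnas, consensus[mid], config, rng)
        for mid in selected
    ]
    targets = (pd.concat(target_rows, ignore_index=True) if target_rows
               else pd.DataFrame(columns=["mirna", "gene", "statistic", "p", "sign"]))
    summary = cn.rename(columns={"p": "cn_p", "fdr": "cn_fdr"}).merge(
        tg.rename(columns={"p": "target_p", "fdr": "target_fdr",
                           "statistic": "target_statistic"})
          .drop(columns=["method"]),
        on="mirna", how="left",
    ).drop(columns=["statistic", "method"])
    summary["selected"] = summary["mirna"].isin(selected)
    summary = summary.sort_values("cn_fdr", kind="stable").reset_index(drop=True)
    return CascadeResult(summary, targets, selected)
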