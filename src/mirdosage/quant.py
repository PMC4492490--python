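"""2^(-ddCt) relative quantification and rank-based group contrasts.

Relative expression from qPCR cycle thresholds: per sample,
dCt = Ct(target assay) - Ct(reference assay); ddCt subtracts the mean dCt
of a calibrator sample group; the fold value is 2^(-ddCt). Group contrasts
(adenoma vs carcinoma, 13q gain vs no gain, adenoma-without-gain vs
carcinoma-with-gain) use the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CtTable, PhenotypeTable
from .stats import mann_whitney

logger = logging.getLogger("mirdosage")

DESIGNS = ("histology", "gain13q", "adenoma_nogain_vs_carcinoma_gain")


def relative_expression(ct: CtTable, calibrator: Sequence[str],
                        center: str = "mean") -> pd.DataFrame:
    """2^(-ddCt) per (sample, assay), normalised to a calibrator group.

    ``calibrator`` is a group of sample ids whose mean (or median) dCt per
    assay defines ddCt = 0. Samples without a reference-assay Ct are
    dropped with a warning. Returns columns (sample, assay, delta_ct,
    ddct, rel_expr); the reference assay itself is not reported.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    wide = ct.pivot()
    calibrator = [s for s in calibrator if s in wide.index]
    if not calibrator:
        raise ValueError("calibrator group is empty or absent from the Ct table")
    ref = wide[ct.reference_assay]
    missing_ref = ref.isna()
    if missing_ref.any():
        logger.warning("dropping %d samples without reference Ct: %s",
                       int(missing_ref.sum()), list(wide.index[missing_ref]))
        wide = wide[~missing_ref]
        ref = ref[~missing_ref]
        calibrator = [s for s in calibrator if s in wide.index]
        if not calibrator:
            raise ValueError("calibrator group lost all samples (missing reference Ct)")
    dct = wide.drop(columns=ct.reference_assay).sub(ref, axis=0)
    cal = dct.loc[calibrator]
    offset = cal.mean(axis=0) if center == "mean" else cal.median(axis=0)
    ddct = dct.sub(offset, axis=1)
    rel = np.power(2.0, -ddct)
    out = (
        dct.stack().rename("delta_ct").to_frame()
        .join(ddct.stack().rename("ddct"))
        .join(rel.stack().rename("rel_expr"))
        .reset_index()
        .rename(columns={"level_0": "sample", "level_1": "assay"})
    )
    return out[["sample", "assay", "delta_ct", "ddct", "rel_expr"]]


@dataclass(frozen=True)
class GroupContrast:
    """A two-group Mann-Whitney comparison of per-sample values."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    n_excluded: int
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float


def group_contrast(values: pd.Series, samples_a: Sequence[str],
                   samples_b: Sequence[str], name: str) -> GroupContrast:
    """Mann-Whitney contrast of ``values`` between two explicit sample lists."""
    a = [s for s in samples_a if s in values.index and not pd.isna(values[s])]
    b = [s for s in samples_b if s in values.index and not pd.isna(values[s])]
    if set(a) & set(b):
        raise ValueError(f"contrast {name!r}: groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"contrast {name!r}: a group has fewer than 2 samples")
    va, vb = values[a].to_numpy(float), values[b].to_numpy(float)
    u, p = mann_whitney(va, vb)
    excluded = len(values) - len(a) - len(b)
    return GroupContrast(name, tuple(a), tuple(b), excluded, u, p,
                         float(np.median(va)), float(np.median(vb)))


def contrast(values: pd.Series, phenotypes: PhenotypeTable,
             design: str) -> GroupContrast:
    """Resolve a named design to sample groups and run the contrast.

    histology: adenomas (A) vs carcinomas (B); gain13q: no-gain (A) vs
    gain (B); adenoma_nogain_vs_carcinoma_gain: adenomas without gain (A)
    vs carcinomas with gain (B). Unknown-status samples are excluded and
    counted in ``n_excluded``.
    """
    if design == "histology":
        a = phenotypes.samples_where(histology="adenoma")
        b = phenotypes.samples_where(histology="carcinoma")
    elif design == "gain13q":
        a = phenotypes.samples_where(gain13q="no_gain")
        b = phenotypes.samples_where(gain13q="gain")
    elif design == "adenoma_nogain_vs_carcinoma_gain":
        a = phenotypes.samples_where(histology="adenoma", gain13q="no_gain")
        b = phenotypes.samples_where(histology="carcinoma", gain13q="gain")
    else:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    try:
        return group_contrast(values, a, b, design)
    except ValueError as err:
        raise ValueError(f"design {design!r}: {err}") from None


def contrast_table(per_assay_values: dict[str, pd.Series],
                   phenotypes: PhenotypeTable,
                   designs: Sequence[str] = DESIGNS) -> pd.DataFrame:
    """All designs x assays, as a tidy frame (assay, design, nA, nB, U, p, medians)."""
    rows = []
    for assay, vals in per_assay_values.items():
        for design in designs:
            c = contrast(vals, phenotypes, design)
            rows.append((assay, design, len(c.group_a), len(c.group_b),
                         c.u_statistic, c.p_value, c.median_a, c.median_b))
    return pd.DataFrame(rows, columns=["assay", "design", "n_a", "n_b",
                                       "u", "p", "median_a", "median_b"])
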