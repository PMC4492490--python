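"""Resampling segmented copy number onto an equally spaced genome grid.

The grid plays the role of a common coordinate system for copy-number
covariates: every sample's segmented profile is evaluated at the same
n_points positions (30,000 by default), after which a miRNA's covariate
set is simply the grid columns falling in a window centred on its start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicGrid, GridCNMatrix, SegmentedCNProfile

logger = logging.getLogger("mirdosage")


def build_grid(genome: Mapping[str, int], n_points: int = 30_000) -> GenomicGrid:
    """Equally spaced positions over a genome description (chrom -> bp length).

    Points sit at midpoints of n_points equal bins along the concatenated
    genome, so spacing is uniform (to 1 bp rounding) and each chromosome
    receives points in proportion to its length.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    genome = {str(c): int(l) for c, l in genome.items()}
    lengths = np.array(list(genome.values()), dtype=np.int64)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    total = int(lengths.sum())
    if total <= n_points:
        raise ValueError("total genome length must exceed n_points")
    step = total / n_points
    global_pos = np.floor((np.arange(n_points) + 0.5) * step).astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    chrom_index = np.searchsorted(offsets, global_pos, side="right") - 1
    positions = global_pos - offsets[chrom_index]
    return GenomicGrid(genome, chrom_index.astype(np.intp), positions)


def segments_to_grid(profiles: Sequence[SegmentedCNProfile],
                     grid: GenomicGrid) -> GridCNMatrix:
    """Evaluate each profile at every grid position.

    A grid point inside a segment takes that segment's value; a point on a
    chromosome the sample has segments for, but not covered by any, takes
    the nearest segment's value (ties to the left); a chromosome absent
    from a sample's segmentation yields NaN.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles given")
    values = np.full((len(profiles), grid.n_points), np.nan)
    for i, prof in enumerate(profiles):
        for chrom in grid.chroms:
            sl = grid.chrom_slice(chrom)
            if sl.start == sl.stop:
                continue
            seg = prof.chrom_segments(chrom)
            if len(seg) == 0:
                continue
            pos = grid.positions[sl]
            starts = seg["start"].to_numpy()
            ends = seg["end"].to_numpy()
            vals = seg["value"].to_numpy()
            left = np.searchsorted(starts, pos, side="right") - 1
            covered = (left >= 0) & (pos < ends[np.clip(left, 0, None)])
            out = np.empty(pos.size)
            out[covered] = vals[left[covered]]
            if (~covered).any():
                unc = np.flatnonzero(~covered)
                li = left[unc]
                d_prev = np.where(li >= 0, pos[unc] - ends[np.clip(li, 0, None)] + 1,
                                  np.iinfo(np.int64).max)
                ri = li + 1
                d_next = np.where(ri < len(seg), starts[np.clip(ri, None, len(seg) - 1)] - pos[unc],
                                  np.iinfo(np.int64).max)
                use_prev = d_prev <= d_next
                out[unc] = np.where(use_prev, vals[np.clip(li, 0, None)],
                                    vals[np.clip(ri, None, len(seg) - 1)])
            values[i, sl] = out
    return GridCNMatrix([p.sample_id for p in profiles], grid, values)


@dataclass
class WindowCovariateSet:
    """Copy-number covariates in a window around one miRNA's start."""

    mirna_id: str
    window: tuple[str, int, int]
    grid_columns: np.ndarray  # indices into the grid
    values: np.ndarray        # samples x n_columns


def window_covariates(mirna_id: str, chrom: str, start: int,
                      gridcn: GridCNMatrix, window_bp: int = 2_000_000) -> WindowCovariateSet:
    """Grid columns within [start - window_bp/2, start + window_bp/2).

    The window is clipped to chromosome bounds. Raises when no grid point
    falls inside (grid too coarse for the requested window).
    """
    grid = gridcn.grid
    if chrom not in grid.genome:
        raise ValueError(f"{mirna_id}: chromosome {chrom!r} not on the grid")
    half = window_bp // 2
    lo = max(0, int(start) - half)
    hi = min(grid.genome[chrom], int(start) + half)
    sl = grid.chrom_slice(chrom)
    pos = grid.positions[sl]
    inside = np.flatnonzero((pos >= lo) & (pos < hi)) + sl.start
    if inside.size == 0:
        raise ValueError(
            f"{mirna_id}: window {chrom}:{lo}-{hi} contains no grid point — "
            "grid too coarse; increase window_bp or grid density"
        )
    return WindowCovariateSet(mirna_id, (chrom, lo, hi), inside,
                              gridcn.values[:, inside])


def call_gain(data, region: tuple[str, int, int], threshold: float = 0.2):
    """Gain call over a region: gain iff mean log2 ratio >= threshold.

    Accepts a GridCNMatrix (returns a per-sample Series of
    gain/no_gain/unknown) or a single SegmentedCNProfile (returns one
    status, length-weighted over overlapping segments). A region with no
    data yields "unknown" (logged).
    """
    chrom, lo, hi = str(region[0]), int(region[1]), int(region[2])
    if hi <= lo:
        raise ValueError("region end must exceed start")
    if isinstance(data, GridCNMatrix):
        grid = data.grid
        if chrom not in grid.genome:
            raise ValueError(f"region chromosome {chrom!r} not on the grid")
        sl = grid.chrom_slice(chrom)
        pos = grid.positions[sl]
        cols = np.flatnonzero((pos >= lo) & (pos < hi)) + sl.start
        if cols.size == 0:
            raise ValueError("region overlaps no grid point")
        sub = data.values[:, cols]
        has_data = ~np.isnan(sub).all(axis=1)
        means = np.full(sub.shape[0], np.nan)
        means[has_data] = np.nanmean(sub[has_data], axis=1)
        out = np.where(means >= threshold, "gain", "no_gain").astype(object)
        missing = np.isnan(means)
        if missing.any():
            logger.info("call_gain: %d samples with no data in region", int(missing.sum()))
            out[missing] = "unknown"
        return pd.Series(out, index=data.samples, name="gain13q")
    if isinstance(data, SegmentedCNProfile):
        seg = data.chrom_segments(chrom)
        if len(seg):
            ov = np.minimum(seg["end"].to_numpy(), hi) - np.maximum(seg["start"].to_numpy(), lo)
            keep = ov > 0
        if len(seg) == 0 or not keep.any():
            logger.info("call_gain: sample %s has no data in region", data.sample_id)
            return "unknown"
        mean = float(np.average(seg["value"].to_numpy()[keep], weights=ov[keep]))
        return "gain" if mean >= threshold else "no_gain"
    raise TypeError("expected GridCNMatrix or SegmentedCNProfile")


def write_gain_calls(calls: pd.Series, path) -> None:
    calls.rename_axis("sample").to_frame().to_csv(path, sep="\t")
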