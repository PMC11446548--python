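"""Anchored signal matrices and averaged metagene profiles.

Includes the hybrid-scale metagene (flanks at real bp scale, gene body
resampled onto a percent scale so genes of different lengths are
comparable) and a robust filter that drops the rows with the most extreme
mean coverage before averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import (
    GeneAnnotation,
    SignalMatrix,
    SignalTrack,
    extract_window,
    pa_anchor,
    tss_anchor,
)

logger = logging.getLogger(__name__)

ANCHORS = ("TSS", "pA", "motif_center")


@dataclass
class MetageneProfile:
    """A per-position averaged profile.

    ``axis`` holds bp offsets relative to the anchor (``scale_tag="real_bp"``)
    or percent bins 0..100 of the gene body (``scale_tag="percent"``);
    ``n_valid`` counts the unmasked cells that entered each column mean.
    """

    axis: np.ndarray
    mean: np.ndarray
    n_valid: np.ndarray
    scale_tag: str = "real_bp"


def _resolve_anchor(ann: GeneAnnotation, anchor: str, motif_centers: dict | None) -> int | None:
    if anchor == "TSS":
        return tss_anchor(ann)
    if anchor == "pA":
        return pa_anchor(ann)
    if anchor == "motif_center":
        if motif_centers is None or ann.gene_id not in motif_centers:
            return None
        # motif centers are given as transcript-sense positions (bp from TSS)
        return ann.genomic_position(int(round(motif_centers[ann.gene_id])))
    raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")


def anchored_matrix(
    track: SignalTrack,
    annotations: list,
    anchor: str,
    upstream: int,
    downstream: int,
    motif_centers: dict | None = None,
) -> SignalMatrix:
    """Build a genes x positions matrix anchored on TSS, pA, or motif center.

    Rows read 5'->3' in transcript sense; offsets run ``-upstream`` to
    ``downstream - 1``.  Out-of-chromosome cells are masked.  A gene lacking
    the requested anchor (no motif) yields a fully masked row.
    """
    n = len(annotations)
    p = upstream + downstream
    values = np.zeros((n, p))
    mask = np.zeros((n, p), dtype=bool)
    for i, ann in enumerate(annotations):
        pos = _resolve_anchor(ann, anchor, motif_centers)
        if pos is None:
            logger.info("gene %s lacks anchor %s; row masked", ann.gene_id, anchor)
            continue
        values[i], mask[i] = extract_window(track, ann, pos, upstream, downstream)
    return SignalMatrix([a.gene_id for a in annotations], anchor, np.arange(-upstream, downstream), values, mask)


def average_profile(matrix: SignalMatrix) -> MetageneProfile:
    """Column-wise mean over valid cells only."""
    n_valid = matrix.mask.sum(axis=0)
    total = np.where(matrix.mask, matrix.values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = total / np.where(n_valid > 0, n_valid, np.nan)
    return MetageneProfile(matrix.offsets.copy(), mean, n_valid)


def robust_filter(matrix: SignalMatrix, extreme_fraction: float = 0.05) -> SignalMatrix:
    """Drop the rows with the most extreme mean coverage before averaging.

    The ``extreme_fraction`` is split evenly between the tails: the
    ``ceil(f/2 * n)`` rows of highest and of lowest row-mean coverage are
    removed.  Ties are resolved by row order (stable sort), so the result is
    deterministic.
    """
    if not 0 <= extreme_fraction < 0.5:
        raise ValueError("extreme_fraction must be in [0, 0.5)")
    n = matrix.n_genes
    k = math.ceil(extreme_fraction / 2 * n)
    if n - 2 * k < 2:
        raise ValueError(f"filtering {2 * k} of {n} rows would leave fewer than 2")
    if k == 0:
        return matrix
    order = np.argsort(matrix.row_means(), kind="stable")
    keep = np.sort(order[k : n - k])
    return matrix.subset(keep)


def bin_columns(matrix: SignalMatrix, width: int, reduce: str = "sum") -> SignalMatrix:
    """Rebin matrix columns to ``width``-bp bins (labelled by left edge).

    ``reduce="sum"`` preserves read mass; ``"mean"`` averages valid cells.
    A binned cell is valid if any constituent cell was valid.
    """
    if width <= 1:
        return matrix
    p = len(matrix.offsets)
    nbins = p // width
    if nbins * width != p:
        raise ValueError(f"{p} columns not divisible by bin width {width}")
    vals = np.where(matrix.mask, matrix.values, 0.0).reshape(matrix.n_genes, nbins, width)
    counts = matrix.mask.reshape(matrix.n_genes, nbins, width).sum(axis=2)
    if reduce == "sum":
        binned = vals.sum(axis=2)
    elif reduce == "mean":
        with np.errstate(invalid="ignore"):
            binned = vals.sum(axis=2) / np.where(counts > 0, counts, np.nan)
        binned = np.nan_to_num(binned)
    else:
        raise ValueError("reduce must be 'sum' or 'mean'")
    return SignalMatrix(matrix.gene_ids, matrix.anchor, matrix.offsets[::width], binned, counts > 0)


def _body_binned(track: SignalTrack, ann: GeneAnnotation, body_bins: int) -> np.ndarray:
    """Mean-within-bin resampling of a gene body onto ``body_bins`` bins."""
    values, mask = extract_window(track, ann, tss_anchor(ann), 0, ann.length)
    edges = np.linspace(0, ann.length, body_bins + 1)
    out = np.empty(body_bins)
    for b in range(body_bins):
        lo, hi = int(edges[b]), max(int(edges[b]), int(edges[b + 1]))
        if hi == lo:
            hi = lo + 1
        seg_mask = mask[lo:hi]
        out[b] = values[lo:hi][seg_mask].mean() if seg_mask.any() else np.nan
    return out


def scaled_metagene(
    track: SignalTrack,
    annotations: list,
    flank5: int = 0,
    flank3: int = 0,
    body_bins: int = 100,
) -> MetageneProfile:
    """Hybrid-scale metagene: real-bp flanks, percent-scale body.

    Each gene's body is resampled to ``body_bins`` by mean-within-bin (mass
    conserving for read-density signals); the 5' and 3' flanks are appended
    at real scale.  Genes shorter than ``body_bins`` bp are skipped (logged).
    The returned axis is flank offsets in bp plus body bin indices; columns
    are averaged with per-column valid counts.
    """
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    usable = [a for a in annotations if a.length >= body_bins]
    skipped = len(annotations) - len(usable)
    if skipped:
        logger.info("scaled_metagene: skipped %d genes shorter than %d bp", skipped, body_bins)
    if not usable:
        raise ValueError(f"no genes of length >= body_bins ({body_bins})")

    p = flank5 + body_bins + flank3
    values = np.zeros((len(usable), p))
    mask = np.zeros((len(usable), p), dtype=bool)
    for i, ann in enumerate(usable):
        if flank5:
            v5, m5 = extract_window(track, ann, tss_anchor(ann), flank5, 0)
            values[i, :flank5], mask[i, :flank5] = v5, m5
        body = _body_binned(track, ann, body_bins)
        ok = ~np.isnan(body)
        values[i, flank5 : flank5 + body_bins][ok] = body[ok]
        mask[i, flank5 : flank5 + body_bins] = ok
        if flank3:
            v3, m3 = extract_window(track, ann, pa_anchor(ann), 0, flank3)
            values[i, flank5 + body_bins :], mask[i, flank5 + body_bins :] = v3, m3
    n_valid = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(mask, values, 0.0).sum(axis=0) / np.where(n_valid > 0, n_valid, np.nan)
    axis = np.concatenate(
        [np.arange(-flank5, 0), np.arange(body_bins), np.arange(body_bins, body_bins + flank3)]
    )
    return MetageneProfile(axis, mean, n_valid, scale_tag="percent")


def profile_correlation(a: MetageneProfile, b: MetageneProfile) -> float:
    """Pearson correlation between two profiles on a common axis (replicate check)."""
    if len(a.mean) != len(b.mean):
        raise ValueError("profiles must share an axis")
    ok = ~(np.isnan(a.mean) | np.isnan(b.mean))
    return float(np.corrcoef(a.mean[ok], b.mean[ok])[0, 1])
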