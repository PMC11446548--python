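"""Pol II backtracking index and Rpb4/Rpb3 stoichiometry profiles.

The backtracking index (BI) is the ratio of total polymerase occupancy
(Rpb3 ChIP) to actively elongating polymerase (run-on signal): a
backtracked polymerase is ChIP-visible but cannot elongate in a run-on, so
high BI marks frequent backtracking.  Per-gene signals are summarised as
the mean of 250 bp tiles at the 5' and 3' transcript ends.  Rpb4
stoichiometry along genes is summarised as Rpb4-ChIP/Rpb3-ChIP ratio
profiles around the TSS and pA, normalised to the TSS -100 position, and
as per-gene body averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SignalTrack, extract_window, pa_anchor, tss_anchor

DEFAULT_TILE = 250


def gene_end_averages(track: SignalTrack, annotations: list, tile: int = DEFAULT_TILE) -> pd.DataFrame:
    """Strand-aware mean signal over the 5' and 3' ``tile`` bp of each transcript.

    Genes shorter than ``tile`` use the whole transcript for both tiles and
    are flagged (``clipped`` True).
    """
    rows = []
    for ann in annotations:
        L = ann.length
        t = min(tile, L)
        v5, m5 = extract_window(track, ann, tss_anchor(ann), 0, t)
        v3, m3 = extract_window(track, ann, pa_anchor(ann), t, 0)
        rows.append(
            {
                "gene_id": ann.gene_id,
                "mean5": float(v5[m5].mean()) if m5.any() else np.nan,
                "mean3": float(v3[m3].mean()) if m3.any() else np.nan,
                "clipped": L < tile,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def backtracking_index(
    chip_means: pd.DataFrame,
    gro_means: pd.DataFrame,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-gene BI = (ChIP + eps) / (GRO + eps) on combined 5'/3' tile means.

    The combined signal per track is the mean of the two tile means.  With
    the default eps = 0, genes with zero run-on signal are flagged
    (``bi_defined`` False) rather than given an arbitrary value.  Per-tile
    indices are also reported.
    """
    common = chip_means.index.intersection(gro_means.index)
    chip = chip_means.loc[common]
    gro = gro_means.loc[common]
    out = pd.DataFrame(index=common)
    chip_c = (chip["mean5"] + chip["mean3"]) / 2
    gro_c = (gro["mean5"] + gro["mean3"]) / 2
    for name, c, g in (("BI", chip_c, gro_c), ("BI5", chip["mean5"], gro["mean5"]), ("BI3", chip["mean3"], gro["mean3"])):
        denom = g + pseudocount
        ok = denom > 0
        out[name] = np.where(ok, (c + pseudocount) / denom.where(ok), np.nan)
    out["bi_defined"] = (gro_c + pseudocount) > 0
    return out


def zscore_median(values) -> np.ndarray:
    """Median-centred z-score: (x - median) / SD, SD about the mean (ddof = 1).

    The transformed vector has median exactly 0 and sample SD exactly 1.
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x[~np.isnan(x)])) < 2:
        raise ValueError("zscore_median needs at least 2 distinct values")
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - np.nanmedian(x)) / sd


def zscore_mad(values) -> np.ndarray:
    """Alternative robust scaling: (x - median) / (1.4826 x MAD)."""
    x = np.asarray(values, dtype=float)
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    if mad == 0:
        raise ValueError("zero median absolute deviation")
    return (x - med) / (1.4826 * mad)


@dataclass
class RatioProfile:
    """Two-segment Rpb4/Rpb3 ratio profile, normalised to TSS -100.

    ``tss_offsets`` span -100..+250 around the TSS and ``pa_offsets``
    -250..+100 around the pA site, in transcript sense.  After
    normalisation the value at TSS -100 is exactly 1.
    """

    tss_offsets: np.ndarray
    tss_ratio: np.ndarray
    pa_offsets: np.ndarray
    pa_ratio: np.ndarray
    n_genes: int
    anchor_value: float  # pre-normalisation ratio at TSS -100


def _segment_mean(track, annotations, anchor_fn, upstream, downstream):
    n = upstream + downstream
    total = np.zeros(n)
    count = np.zeros(n)
    for ann in annotations:
        v, m = extract_window(track, ann, anchor_fn(ann), upstream, downstream)
        total[m] += v[m]
        count[m] += 1
    with np.errstate(invalid="ignore"):
        return total / np.where(count > 0, count, np.nan)


def ratio_profile(
    rpb4_track: SignalTrack,
    rpb3_track: SignalTrack,
    annotations: list,
    gene_set=None,
    tss_window: tuple = (100, 251),
    pa_window: tuple = (250, 101),
    pseudocount: float = 0.0,
) -> RatioProfile:
    """Averaged Rpb4/Rpb3 ratio around TSS and pA for a gene set.

    Uses the ratio of mean signals across genes at each position (robust to
    per-gene zeros), then normalises the whole profile to the TSS -100
    value.  ``pseudocount`` is added to both numerator and denominator
    means; the default 0 keeps noiseless ratios exact and leaves positions
    with zero denominator NaN.
    """
    if gene_set is not None:
        members = set(gene_set.members) if hasattr(gene_set, "members") else set(gene_set)
        annotations = [a for a in annotations if a.gene_id in members]
    if not annotations:
        raise ValueError("empty gene set for ratio_profile")

    segs = {}
    for name, (anchor_fn, (up, down)) in {
        "tss": (tss_anchor, tss_window),
        "pa": (pa_anchor, pa_window),
    }.items():
        m4 = _segment_mean(rpb4_track, annotations, anchor_fn, up, down)
        m3 = _segment_mean(rpb3_track, annotations, anchor_fn, up, down)
        denom = m3 + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, (m4 + pseudocount) / np.where(denom > 0, denom, np.nan), np.nan)
        segs[name] = (np.arange(-up, down), ratio)

    tss_off, tss_ratio = segs["tss"]
    pa_off, pa_ratio = segs["pa"]
    anchor_idx = np.flatnonzero(tss_off == -100)
    if len(anchor_idx) == 0:
        raise ValueError("TSS window must include the -100 position")
    anchor_value = tss_ratio[anchor_idx[0]]
    if not np.isfinite(anchor_value) or anchor_value == 0:
        raise ValueError("ratio at TSS -100 undefined; cannot normalise")
    return RatioProfile(
        tss_off, tss_ratio / anchor_value, pa_off, pa_ratio / anchor_value,
        len(annotations), float(anchor_value),
    )


def body_ratio(
    rpb4_track: SignalTrack,
    rpb3_track: SignalTrack,
    annotations: list,
    tile: int = DEFAULT_TILE,
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-gene mean of per-position Rpb4/Rpb3 ratios over TSS..+tile and -tile..pA."""
    out = {}
    for ann in annotations:
        t = min(tile, ann.length)
        parts = []
        for anchor_fn, up, down in ((tss_anchor, 0, t), (pa_anchor, t, 0)):
            v4, m4 = extract_window(rpb4_track, ann, anchor_fn(ann), up, down)
            v3, m3 = extract_window(rpb3_track, ann, anchor_fn(ann), up, down)
            ok = m4 & m3 & ((v3 + pseudocount) > 0)
            parts.append(((v4[ok] + pseudocount) / (v3[ok] + pseudocount)))
        both = np.concatenate(parts)
        out[ann.gene_id] = float(both.mean()) if both.size else np.nan
    return pd.Series(out, name="rpb4_rpb3_body")


def correlation_ledger(
    table: pd.DataFrame,
    pairs: list,
    gene_sets: dict,
) -> pd.DataFrame:
    """Pearson and Spearman correlations per quantity pair and gene-set stratum.

    ``pairs`` is a list of (x_column, y_column); ``gene_sets`` maps stratum
    name to gene ids (use ``{"all": table.index}`` for no stratification).
    Pairwise-complete observations only; n is reported per row.  P-values
    are two-sided with no multiple-testing correction (per-panel reporting).
    """
    rows = []
    for set_name, members in gene_sets.items():
        idx = table.index.intersection(pd.Index(list(members)))
        for x, y in pairs:
            sub = table.loc[idx, [x, y]].dropna()
            n = len(sub)
            for method, func in (("pearson", stats.pearsonr), ("spearman", stats.spearmanr)):
                if n >= 3:
                    r, p = func(sub[x], sub[y])
                else:
                    r, p = np.nan, np.nan
                rows.append(
                    {
                        "pair": f"{x}~{y}",
                        "gene_set": set_name,
                        "method": method,
                        "r": float(r),
                        "p": float(p),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)
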