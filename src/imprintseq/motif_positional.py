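"""Scanning for contiguous (GCT)n repeats and their position relative to pA.

The scanner reports maximal, non-overlapping runs of at least
``min_repeats`` contiguous copies of a trinucleotide unit on the sense
strand.  Positions are summarised as distances upstream of the
polyadenylation site, measured to the run midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSet, transcript_sequence
from .setstats import hypergeom_overlap


@dataclass(frozen=True)
class MotifHit:
    """One maximal (GCT)n run in a transcript's sense sequence.

    ``start_in_transcript`` is bp from the TSS (0-based);
    ``distance_upstream_pa`` is the transcript-sense distance from the pA
    site to the run midpoint (pA coordinate minus motif center).
    """

    gene_id: str
    start_in_transcript: int
    repeats: int
    distance_upstream_pa: float

    @property
    def length(self) -> int:
        return 3 * self.repeats


def scan_unit_repeats(
    sequence: str,
    unit: str = "GCT",
    min_repeats: int = 2,
    gene_id: str = "",
    offset: int = 0,
    transcript_length: int | None = None,
) -> list:
    """Maximal non-overlapping runs of >= min_repeats contiguous units.

    ``offset`` shifts reported start positions (for scanning a window of a
    longer transcript); ``transcript_length`` sets the pA coordinate used
    for the upstream distance (defaults to ``offset + len(sequence)``).
    Runs containing N break automatically (N never matches the unit).
    """
    seq = sequence.upper()
    m = len(unit)
    if transcript_length is None:
        transcript_length = offset + len(seq)
    hits = []
    i = 0
    n = len(seq)
    while i + m * min_repeats <= n:
        if seq[i : i + m] == unit:
            r = 1
            while seq[i + r * m : i + (r + 1) * m] == unit:
                r += 1
            if r >= min_repeats:
                start = offset + i
                center = start + (m * r) / 2
                hits.append(
                    MotifHit(gene_id, start, r, float(transcript_length - center))
                )
                i += r * m
                continue
            i += r * m  # shorter run cannot seed a later hit inside itself
        else:
            i += 1
    return hits


def scan_gct_repeats(sequence: str, min_repeats: int = 2, gene_id: str = "", **kw) -> list:
    """Convenience wrapper of :func:`scan_unit_repeats` for the GCT unit."""
    return scan_unit_repeats(sequence, unit="GCT", min_repeats=min_repeats, gene_id=gene_id, **kw)


def hits_near_pa(
    annotations: list,
    genome: dict,
    window_upstream: int = 160,
    unit: str = "GCT",
    min_repeats: int = 2,
) -> pd.DataFrame:
    """Scan the ``window_upstream`` bp upstream of each pA site (clipped at TSS).

    Returns one row per gene with a presence flag and, where present, the
    hit nearest the pA (start, repeats, upstream distance to run midpoint).
    """
    rows = []
    for ann in annotations:
        L = ann.length
        win_start = max(0, L - window_upstream)
        seq = transcript_sequence(genome, ann)[win_start:L]
        hits = scan_unit_repeats(
            seq, unit=unit, min_repeats=min_repeats, gene_id=ann.gene_id,
            offset=win_start, transcript_length=L,
        )
        if hits:
            best = min(hits, key=lambda h: h.distance_upstream_pa)
            rows.append(
                {
                    "gene_id": ann.gene_id,
                    "has_motif": True,
                    "start_in_transcript": best.start_in_transcript,
                    "repeats": best.repeats,
                    "distance_upstream_pa": best.distance_upstream_pa,
                }
            )
        else:
            rows.append(
                {
                    "gene_id": ann.gene_id,
                    "has_motif": False,
                    "start_in_transcript": np.nan,
                    "repeats": np.nan,
                    "distance_upstream_pa": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("gene_id")


def positional_summary(hits: pd.DataFrame, bin_width: int = 10) -> dict:
    """Mean, median, SEM, and histogram of upstream distances for present hits."""
    d = hits.loc[hits["has_motif"].astype(bool), "distance_upstream_pa"].to_numpy(dtype=float)
    if d.size == 0:
        return {"n": 0, "mean": np.nan, "median": np.nan, "sem": np.nan, "histogram": None}
    edges = np.arange(0, d.max() + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges if len(edges) > 1 else 10)
    return {
        "n": int(d.size),
        "mean": float(d.mean()),
        "median": float(np.median(d)),
        "sem": float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else np.nan,
        "histogram": (counts, edges),
    }


def motif_set_enrichment(
    target: GeneSet,
    background: GeneSet,
    presence: pd.Series,
):
    """Over-representation of motif presence in ``target`` vs ``background``.

    The universe is the union of the two sets; the hypergeometric upper
    tail tests whether motif-bearing genes concentrate in the target set.
    Returns an :class:`~imprintseq.setstats.OverlapResult`.
    """
    universe = GeneSet("universe", target.members | background.members)
    with_motif = GeneSet(
        "with_motif",
        frozenset(g for g in universe.members if bool(presence.get(g, False))),
    )
    return hypergeom_overlap(target, with_motif, universe)
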