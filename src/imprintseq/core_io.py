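"""Domain types, coordinate conventions, and standard-format readers/writers.

Coordinate convention
---------------------
All internal coordinates are 0-based, half-open (BED-native).  A transcription
unit is described by its transcription start site (``tss``) and polyadenylation
site (``pa``):

* ``+`` strand: the transcript occupies genomic ``[tss, pa)``; ``pa`` is the
  first genomic base *not* in the transcript.
* ``-`` strand: the transcript occupies genomic ``[pa, tss)``; ``tss > pa``.
  In transcript (5'->3') sense, position ``j`` maps to genomic ``tss - 1 - j``,
  so the sense-exclusive end of the transcript again falls just past ``pa``.

Window extraction is always returned in transcript sense (5'->3'), so that
"upstream of the pA site" means the same thing for both strands.  Cells that
fall outside a chromosome are *masked*, never silently zero-filled, so that
downstream averages can use per-column valid counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotations."""


class TrackError(ValueError):
    """Raised for malformed coverage tracks or out-of-bounds intervals."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """One transcription unit.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    chrom : str
        Chromosome name.
    strand : {"+", "-"}
    tss : int
        Transcription start site (0-based).  For ``+`` strand genes this is
        the first transcribed base; for ``-`` strand genes it is the
        half-open end of the transcribed interval (the first base 5' of the
        transcript on the genomic axis).
    pa : int
        Polyadenylation / cleavage site, exclusive end in transcript sense.
    class_tags : frozenset of str
        Free-form labels (e.g. ``RP``, ``RiBi``, ``CRAC+``).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    pa: int
    class_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.pa:
            raise AnnotationError(f"{self.gene_id}: + strand requires tss < pa")
        if self.strand == "-" and not self.tss > self.pa:
            raise AnnotationError(f"{self.gene_id}: - strand requires tss > pa")
        object.__setattr__(self, "class_tags", frozenset(self.class_tags))

    @property
    def length(self) -> int:
        """Transcript length in bp."""
        return abs(self.pa - self.tss)

    @property
    def start(self) -> int:
        """Genomic interval start (0-based, inclusive)."""
        return min(self.tss, self.pa)

    @property
    def end(self) -> int:
        """Genomic interval end (exclusive)."""
        return max(self.tss, self.pa)

    def genomic_position(self, transcript_pos: int) -> int:
        """Map a transcript-sense offset (0 = first base) to a genomic coordinate."""
        if self.strand == "+":
            return self.tss + transcript_pos
        return self.tss - 1 - transcript_pos

    def tagged(self, *tags: str) -> "GeneAnnotation":
        return replace(self, class_tags=self.class_tags | set(tags))


def tss_anchor(ann: GeneAnnotation) -> int:
    """Genomic coordinate of the first transcribed base (sense anchor for the TSS)."""
    return ann.genomic_position(0)


def pa_anchor(ann: GeneAnnotation) -> int:
    """Genomic sense anchor for the pA site: offset 0 is the first base past the transcript."""
    return ann.genomic_position(ann.length)


class SignalTrack:
    """Per-base, strand-resolved, non-negative coverage over a genome.

    Missing regions are zero.  An unstranded track can be materialised on
    both strands via ``strand="both"`` at load time.
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self._data: dict[str, dict[str, np.ndarray]] = {
            chrom: {s: np.zeros(size, dtype=float) for s in STRANDS}
            for chrom, size in self.chrom_sizes.items()
        }

    def values(self, chrom: str, strand: str) -> np.ndarray:
        return self._data[chrom][strand]

    def add_interval(self, chrom: str, start: int, end: int, value: float, strand: str) -> None:
        if chrom not in self._data:
            raise TrackError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        if start < 0 or end > size or start >= end:
            raise TrackError(f"interval {chrom}:{start}-{end} outside chromosome of size {size}")
        strands = STRANDS if strand == "both" else (strand,)
        for s in strands:
            self._data[chrom][s][start:end] += value

    def total(self) -> float:
        return float(sum(v.sum() for d in self._data.values() for v in d.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        out = SignalTrack(self.chrom_sizes)
        for chrom, d in self._data.items():
            for s, v in d.items():
                out._data[chrom][s] = v * factor
        return out

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        if self.chrom_sizes != other.chrom_sizes:
            raise TrackError("cannot add tracks over different genomes")
        out = SignalTrack(self.chrom_sizes)
        for chrom, d in self._data.items():
            for s in STRANDS:
                out._data[chrom][s] = d[s] + other._data[chrom][s]
        return out


@dataclass
class SignalMatrix:
    """Genes x positions matrix anchored on TSS, pA, or a motif center.

    Rows are gene-oriented (5'->3' in transcript sense); ``offsets`` are
    positions relative to the anchor, strictly increasing, negative =
    upstream in transcript sense.  ``mask`` flags valid cells; masked cells
    are excluded from every average.
    """

    gene_ids: list
    anchor: str
    offsets: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, p = self.values.shape
        if len(self.gene_ids) != n or len(self.offsets) != p or self.mask.shape != (n, p):
            raise ValueError("inconsistent SignalMatrix dimensions")
        if p > 1 and not np.all(np.diff(self.offsets) > 0):
            raise ValueError("offsets must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def row_means(self) -> np.ndarray:
        """Per-gene mean over valid cells (NaN where no cell is valid)."""
        nvalid = self.mask.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out = np.where(self.mask, self.values, 0.0).sum(axis=1) / np.where(nvalid > 0, nvalid, np.nan)
        return out

    def row_sums(self) -> np.ndarray:
        return np.where(self.mask, self.values, 0.0).sum(axis=1)

    def subset(self, row_index: np.ndarray) -> "SignalMatrix":
        return SignalMatrix(
            [self.gene_ids[i] for i in row_index],
            self.anchor,
            self.offsets,
            self.values[row_index],
            self.mask[row_index],
        )


@dataclass
class ExpressionTable:
    """Per-gene synthesis rate (SR), mRNA abundance (RA), and half-life (HL).

    Under the steady-state assumption HL = RA / SR, in arbitrary units.
    ``data`` is indexed by gene_id with columns ``SR`` and ``RA`` (``HL``
    added by the kinetics module); ``condition`` labels the sample.
    """

    data: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        missing = {"SR", "RA"} - set(self.data.columns)
        if missing:
            raise ValueError(f"ExpressionTable missing columns {sorted(missing)}")
        if (self.data["SR"] < 0).any() or (self.data["RA"] < 0).any():
            raise ValueError("SR and RA must be non-negative")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def _check_unique(genes: Sequence[GeneAnnotation]) -> list:
    seen: set = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return list(genes)


def read_annotation(path: str | Path, format: str = "BED12") -> list:
    """Read gene annotations from BED(6/12) or GFF3.

    TSS and pA are derived strand-correctly: for BED, a ``+`` strand record
    has ``tss = chromStart`` and ``pa = chromEnd``; a ``-`` strand record
    mirrors them.  GFF3 1-based closed coordinates are converted to 0-based
    half-open.
    """
    fmt = format.upper()
    if fmt in ("BED", "BED6", "BED12"):
        return _read_bed(path)
    if fmt == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed(path: str | Path) -> list:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise AnnotationError(f"{path}:{lineno}: BED line needs >= 6 fields")
            try:
                chrom, start, end, name, _score, strand = fields[:6]
                start, end = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            if strand == "+":
                tss, pa = start, end
            else:
                tss, pa = end, start
            genes.append(GeneAnnotation(name, chrom, strand, tss, pa))
    return _check_unique(genes)


def _read_gff3(path: str | Path) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error", id_spec=["ID", "gene_id", "Name"],
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        start0 = feat.start - 1  # GFF3 is 1-based closed
        end = feat.end
        if feat.strand == "+":
            tss, pa = start0, end
        else:
            tss, pa = end, start0
        genes.append(GeneAnnotation(feat.id, feat.seqid, feat.strand, tss, pa))
    return _check_unique(genes)


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path, format: str = "BED12") -> None:
    """Write annotations as BED12 (or BED6) records, one transcript per line."""
    fmt = format.upper()
    with open(path, "w") as fh:
        for g in genes:
            base = [g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand]
            if fmt == "BED12":
                base += [str(g.start), str(g.end), "0,0,0", "1", str(g.length), "0"]
            fh.write("\t".join(base) + "\n")


# ---------------------------------------------------------------------------
# bedGraph track I/O
# ---------------------------------------------------------------------------


def read_signal_track(
    path: str | Path,
    strand: str,
    chrom_sizes: Mapping[str, int],
    track: SignalTrack | None = None,
) -> SignalTrack:
    """Read a bedGraph file onto a strand (``+``, ``-`` or ``both``).

    Overlapping intervals are summed; unlisted positions stay zero.  Pass an
    existing ``track`` to accumulate several files (e.g. one file per strand).
    """
    if track is None:
        track = SignalTrack(chrom_sizes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackError(f"{path}:{lineno}: bedGraph line needs 4 fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            try:
                track.add_interval(chrom, start, end, value, strand)
            except TrackError as exc:
                raise TrackError(f"{path}:{lineno}: {exc}") from None
    return track


def write_signal_track(track: SignalTrack, path: str | Path, strand: str) -> None:
    """Write one strand of a track as bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes):
            v = track.values(chrom, strand)
            if not v.any():
                continue
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(v) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(v)]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_chrom_sizes(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def extract_window(
    track: SignalTrack,
    ann: GeneAnnotation,
    anchor_pos: int,
    upstream: int,
    downstream: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract a transcript-sense window around a genomic anchor.

    ``anchor_pos`` is the genomic coordinate at transcript-sense offset 0
    (use :func:`tss_anchor` / :func:`pa_anchor` to resolve anchors for either
    strand).  Offsets run from ``-upstream`` to ``downstream - 1``; for a
    ``-`` strand gene offset ``o`` maps to genomic ``anchor_pos - o`` so the
    returned vector always reads 5'->3'.

    Returns ``(values, mask)`` of length ``upstream + downstream``; positions
    outside the chromosome are masked (mask False), never zero-filled.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    n = upstream + downstream
    size = track.chrom_sizes[ann.chrom]
    offsets = np.arange(-upstream, downstream)
    if ann.strand == "+":
        genomic = anchor_pos + offsets
    else:
        genomic = anchor_pos - offsets
    mask = (genomic >= 0) & (genomic < size)
    values = np.zeros(n, dtype=float)
    if mask.any():
        values[mask] = track.values(ann.chrom, ann.strand)[genomic[mask]]
    else:
        logger.warning("window for %s fully outside chromosome %s", ann.gene_id, ann.chrom)
    return values, mask


def transcript_signal_sum(track: SignalTrack, ann: GeneAnnotation) -> float:
    """Total signal over the transcript on its own strand."""
    v = track.values(ann.chrom, ann.strand)
    return float(v[ann.start:ann.end].sum())


# ---------------------------------------------------------------------------
# FASTA and per-gene table helpers
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict:
    """Read a whole FASTA into memory as ``{name: sequence}``."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def transcript_sequence(genome: Mapping[str, str], ann: GeneAnnotation) -> str:
    """Sense-strand (5'->3') sequence of the transcript."""
    seq = genome[ann.chrom][ann.start:ann.end]
    return seq.upper() if ann.strand == "+" else reverse_complement(seq).upper()


def write_table(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a TSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=True)


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
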