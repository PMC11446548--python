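"""Synthetic genomes, tracks, and tables with planted ground truth.

Every downstream stage of the pipeline is testable against this generator:
it emulates the statistical structure of the real study conditions — a
minority gene class whose protein-RNA cross-linking (CRAC) signal piles up
~150 bp upstream of the polyadenylation site, planted (GCT)n motifs at a
similar offset, per-gene half-lives satisfying RA = SR x HL at steady state,
per-gene backtracked-polymerase fractions b with ChIP ~ load and
GRO ~ load x (1 - b), and an Rpb4/Rpb3 occupancy ratio declining linearly
along gene bodies.

The generative model is deliberately simple: Poisson read counts for
coverage tracks and multiplicative lognormal noise for array-style ratios.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionTable,
    GeneAnnotation,
    SignalTrack,
    transcript_sequence,
)

logger = logging.getLogger(__name__)

# Default study conditions: 600-gene analysis universe with a 262-gene
# bound ("CRAC+") minority, peaks at 150 +/- 20 bp upstream of pA, ~50
# specific reads per bound gene, and motifs in ~65% of the bound class.
DEFAULT_N_GENES = 600
DEFAULT_CRAC_FRACTION = 262 / 600
DEFAULT_PEAK_OFFSET_MEAN = 150.0
DEFAULT_PEAK_OFFSET_SD = 20.0
DEFAULT_PILE_SD = 30.0
DEFAULT_READS_PER_GENE = 50.0
DEFAULT_NOISE_PER_KB = 5.0
DEFAULT_MOTIF_FRACTION = 73 / 113


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SimGenome:
    """A simulated genome: annotations, sequences, and the latent truth table.

    ``truth`` is indexed by gene_id and accumulates the planted quantities
    (CRAC status, peak and motif offsets, SR/HL, backtrack fractions, Rpb4
    decline slopes) as the individual generators run.
    """

    annotations: list
    chrom_sizes: dict
    sequences: dict
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def by_id(self, gene_id: str) -> GeneAnnotation:
        return self._index[gene_id]

    def __post_init__(self) -> None:
        self._index = {g.gene_id: g for g in self.annotations}
        if self.truth.empty:
            self.truth = pd.DataFrame(index=pd.Index([g.gene_id for g in self.annotations], name="gene_id"))
            self.truth["length"] = [g.length for g in self.annotations]

    def crac_positive_ids(self) -> list:
        return list(self.truth.index[self.truth["is_crac_positive"].astype(bool)])


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(
    n_genes: int = DEFAULT_N_GENES,
    length_range: tuple = (800, 2500),
    n_chroms: int = 2,
    gc: float = 0.40,
    seed: int = 0,
    gap: int = 300,
    margin: int = 500,
) -> SimGenome:
    """Generate random chromosomes with non-overlapping genes on both strands.

    Genes are laid out left to right with at least ``gap`` bp between
    consecutive transcripts (and ``margin`` bp free at chromosome ends), so
    flank windows of downstream analyses stay on-chromosome.  Chromosome
    sizes are derived from the gene budget.
    """
    if length_range[0] < 300:
        raise ValueError("transcripts must be >= 300 bp")
    if gap < 200:
        raise ValueError("inter-gene gaps must be >= 200 bp")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    per_chrom = np.array_split(np.arange(n_genes), n_chroms)

    annotations: list = []
    chrom_sizes: dict = {}
    sequences: dict = {}
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for ci, idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = margin
        for i in idx:
            L = int(lengths[i])
            start, end = pos, pos + L
            if strands[i] == "+":
                ann = GeneAnnotation(f"g{i:04d}", chrom, "+", start, end)
            else:
                ann = GeneAnnotation(f"g{i:04d}", chrom, "-", end, start)
            annotations.append(ann)
            pos = end + gap
        size = pos - gap + margin if len(idx) else 2 * margin
        chrom_sizes[chrom] = size
        sequences[chrom] = "".join(rng.choice(list("ATGC"), size=size, p=p))
    return SimGenome(annotations, chrom_sizes, sequences)


# ---------------------------------------------------------------------------
# CRAC coverage
# ---------------------------------------------------------------------------


def plant_crac_track(
    sim: SimGenome,
    crac_fraction: float = DEFAULT_CRAC_FRACTION,
    peak_offset_mean: float = DEFAULT_PEAK_OFFSET_MEAN,
    peak_offset_sd: float = DEFAULT_PEAK_OFFSET_SD,
    pile_sd: float = DEFAULT_PILE_SD,
    reads_per_gene: float = DEFAULT_READS_PER_GENE,
    noise_per_kb: float = DEFAULT_NOISE_PER_KB,
    seed: int = 0,
) -> SignalTrack:
    """Plant a cross-linking read track with a 3'-proximal peak in a minority class.

    CRAC+ genes receive ``Poisson(reads_per_gene)`` reads whose positions are
    Gaussian around ``peak_offset`` bases upstream of the pA site (the offset
    itself varies across genes with sd ``peak_offset_sd``), atop a uniform
    background of ``noise_per_kb`` expected reads per kb that all genes get.
    Updates ``sim.truth`` with the planted status, offsets, and read counts.
    """
    if not 0 <= crac_fraction <= 1:
        raise ValueError("crac_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(sim.annotations)
    n_pos = int(round(crac_fraction * n))
    pos_idx = set(rng.choice(n, size=n_pos, replace=False))

    track = SignalTrack(sim.chrom_sizes)
    is_pos = np.zeros(n, dtype=bool)
    offsets = np.full(n, np.nan)
    planted = np.zeros(n, dtype=int)
    for i, ann in enumerate(sim.annotations):
        L = ann.length
        v = track.values(ann.chrom, ann.strand)
        n_reads = 0
        if i in pos_idx:
            is_pos[i] = True
            offset = rng.normal(peak_offset_mean, peak_offset_sd)
            while not 0 < offset < L:
                logger.info("resampling peak offset for %s (len %d)", ann.gene_id, L)
                offset = rng.normal(peak_offset_mean, peak_offset_sd)
            offsets[i] = offset
            k = rng.poisson(reads_per_gene)
            pos = np.clip(np.rint(rng.normal(L - offset, pile_sd, size=k)), 0, L - 1).astype(int)
            np.add.at(v, np.fromiter((ann.genomic_position(int(t)) for t in pos), dtype=int, count=k), 1.0)
            n_reads += k
        k_bg = rng.poisson(noise_per_kb * L / 1000.0)
        if k_bg:
            pos = rng.integers(0, L, size=k_bg)
            np.add.at(v, np.fromiter((ann.genomic_position(int(t)) for t in pos), dtype=int, count=k_bg), 1.0)
            n_reads += k_bg
        planted[i] = n_reads
    sim.truth["is_crac_positive"] = is_pos
    sim.truth["peak_offset"] = offsets
    sim.truth["crac_reads_planted"] = planted
    return track


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------


def _purge_unit_runs(seq_list: list, unit: str = "GCT", keep: tuple | None = None) -> None:
    """Destroy chance >=2-unit runs in a transcript-sense sequence (in place).

    ``keep`` is an (start, end) interval to leave untouched (a planted run).
    The second unit's first base is mutated, which breaks the run without
    creating a new one (A never occurs in GCT).
    """
    m = len(unit)
    s = "".join(seq_list)
    i = 0
    while i + 2 * m <= len(s):
        if s[i : i + m] == unit and s[i + m : i + 2 * m] == unit:
            if keep is not None and i < keep[1] and i + 2 * m > keep[0]:
                i += 1
                continue
            seq_list[i + m] = "A"
            s = "".join(seq_list)
        i += 1


def plant_motifs(
    sim: SimGenome,
    motif_fraction: float = DEFAULT_MOTIF_FRACTION,
    motif_repeats: int = 2,
    offset_mean: float = 150.0,
    offset_sd: float = 25.0,
    unit: str = "GCT",
    purge: bool = True,
    purge_window: int = 250,
    seed: int = 0,
) -> None:
    """Plant contiguous (GCT)n runs upstream of the pA site in CRAC+ genes.

    A ``motif_fraction`` subset of the CRAC+ class receives one run of
    ``motif_repeats`` contiguous units on the sense strand, centered at a
    Gaussian offset upstream of pA.  With ``purge``, chance >=2-unit runs
    within ``purge_window`` bp upstream of every pA are destroyed first so
    planted motifs are the only in-window hits.  Edits ``sim.sequences`` and
    records the planted center offset in ``sim.truth``.
    """
    if "is_crac_positive" not in sim.truth:
        raise ValueError("plant_crac_track must run before plant_motifs")
    if motif_repeats < 2:
        raise ValueError("motif_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    crac_ids = sim.crac_positive_ids()
    n_motif = int(round(motif_fraction * len(crac_ids)))
    chosen = set(rng.choice(crac_ids, size=n_motif, replace=False))

    seqs = {chrom: list(s) for chrom, s in sim.sequences.items()}
    motif = unit * motif_repeats
    mlen = len(motif)
    motif_offsets = pd.Series(np.nan, index=sim.truth.index)
    for ann in sim.annotations:
        L = ann.length
        planted_interval = None
        if ann.gene_id in chosen:
            # sample a center offset that keeps the run inside the transcript
            while True:
                offset = rng.normal(offset_mean, offset_sd)
                start = int(round(L - offset - mlen / 2))
                if 0 <= start and start + mlen <= L:
                    break
            for j, base in enumerate(motif):
                gpos = ann.genomic_position(start + j)
                if ann.strand == "+":
                    seqs[ann.chrom][gpos] = base
                else:
                    seqs[ann.chrom][gpos] = {"G": "C", "C": "G", "T": "A", "A": "T"}[base]
            # guard bases: a chance unit flanking the planted run would
            # extend it and shift the recorded center, so break any such unit
            current = transcript_sequence({c: "".join(sl) for c, sl in seqs.items()}, ann)
            for guard_pos, triplet_start in ((start - 1, start - len(unit)), (start + mlen, start + mlen)):
                if 0 <= triplet_start and triplet_start + len(unit) <= L:
                    if current[triplet_start : triplet_start + len(unit)] == unit:
                        gpos = ann.genomic_position(guard_pos)
                        seqs[ann.chrom][gpos] = "A" if ann.strand == "+" else "T"
            planted_interval = (start, start + mlen)
            motif_offsets[ann.gene_id] = L - (start + mlen / 2)
        if purge:
            win_start = max(0, L - purge_window)
            sense = list(
                transcript_sequence({c: "".join(sl) for c, sl in seqs.items()}, ann)[win_start:L]
            )
            keep = None
            if planted_interval is not None:
                keep = (planted_interval[0] - win_start, planted_interval[1] - win_start)
            _purge_unit_runs(sense, unit=unit, keep=keep)
            for j, base in enumerate(sense):
                gpos = ann.genomic_position(win_start + j)
                if ann.strand == "+":
                    seqs[ann.chrom][gpos] = base
                else:
                    seqs[ann.chrom][gpos] = {"G": "C", "C": "G", "T": "A", "A": "T"}[base]
    sim.sequences = {chrom: "".join(sl) for chrom, sl in seqs.items()}
    sim.truth["motif_offset"] = motif_offsets
    sim.truth["has_motif"] = motif_offsets.notna()


# ---------------------------------------------------------------------------
# Expression / kinetics
# ---------------------------------------------------------------------------


def generate_expression(
    sim: SimGenome,
    sr_range: tuple = (0.5, 20.0),
    hl_range: tuple = (4.0, 60.0),
    noise_cv: float = 0.1,
    conditions: tuple = ("WT", "mut"),
    mutant_hl_multiplier_crac: float = 0.5,
    mutant_sr_multiplier_crac: float = 0.5,
    couple_to_backtracking: bool = False,
    seed: int = 0,
) -> dict:
    """Per-condition expression tables with RA = SR x HL x lognormal noise.

    SR and HL are drawn log-uniformly.  In the mutant condition the HL (and
    SR) of truth-CRAC+ genes is multiplied down, emulating loss of the
    stabilizing factor.  With ``couple_to_backtracking`` the per-gene mutant
    HL multiplier follows the gene's backtracking-index ratio (requires
    :func:`generate_chip_gro` truth columns), so HL and BI shifts are
    correlated within the CRAC+ class only.
    """
    rng = np.random.default_rng(seed)
    n = len(sim.annotations)
    idx = sim.truth.index
    if "sr_true" not in sim.truth:
        sim.truth["sr_true"] = np.exp(rng.uniform(np.log(sr_range[0]), np.log(sr_range[1]), n))
        sim.truth["hl_true"] = np.exp(rng.uniform(np.log(hl_range[0]), np.log(hl_range[1]), n))
    is_pos = sim.truth["is_crac_positive"].astype(bool).to_numpy()

    hl_mult = np.ones(n)
    sr_mult = np.ones(n)
    if couple_to_backtracking:
        if "backtrack_b" not in sim.truth or "backtrack_b_mut" not in sim.truth:
            raise ValueError("couple_to_backtracking requires generate_chip_gro truth")
        bi_ratio = (1 - sim.truth["backtrack_b"].to_numpy()) / (1 - sim.truth["backtrack_b_mut"].to_numpy())
        jitter = _lognormal_factor(rng, 0.05, n)
        hl_mult = np.where(is_pos, bi_ratio * jitter, jitter)
        sr_mult = np.where(is_pos, mutant_sr_multiplier_crac, 1.0)
    else:
        hl_mult[is_pos] = mutant_hl_multiplier_crac
        sr_mult[is_pos] = mutant_sr_multiplier_crac
    sim.truth["hl_mult_mut"] = hl_mult
    sim.truth["sr_mult_mut"] = sr_mult

    tables = {}
    for cond in conditions:
        sr = sim.truth["sr_true"].to_numpy().copy()
        hl = sim.truth["hl_true"].to_numpy().copy()
        if cond != "WT":
            sr = sr * sr_mult
            hl = hl * hl_mult
        ra = sr * hl * _lognormal_factor(rng, noise_cv, n)
        tables[cond] = ExpressionTable(pd.DataFrame({"SR": sr, "RA": ra}, index=idx), condition=cond)
    return tables


# ---------------------------------------------------------------------------
# ChIP / GRO (backtracking)
# ---------------------------------------------------------------------------


def generate_chip_gro(
    sim: SimGenome,
    polII_load_range: tuple = (1.0, 50.0),
    b_range_crac: tuple = (0.3, 0.7),
    b_range_rest: tuple = (0.05, 0.4),
    mutant_b_multiplier_crac: float = 0.5,
    noise_cv: float = 0.0,
    conditions: tuple = ("WT", "mut"),
    seed: int = 0,
) -> dict:
    """Paired (ChIP, GRO) tracks per condition.

    ChIP reports total polymerase (signal ~ load); GRO reports actively
    elongating, non-backtracked polymerase (signal ~ load x (1 - b)).  In
    the mutant condition the backtracked fraction b of truth-CRAC+ genes is
    multiplied by ``mutant_b_multiplier_crac``; other genes keep their b.
    Signals are flat over each transcript, with optional per-gene
    multiplicative lognormal noise on each track.
    """
    rng = np.random.default_rng(seed)
    n = len(sim.annotations)
    is_pos = sim.truth.get("is_crac_positive", pd.Series(False, index=sim.truth.index)).astype(bool).to_numpy()
    if "polII_load" not in sim.truth:
        sim.truth["polII_load"] = np.exp(
            rng.uniform(np.log(polII_load_range[0]), np.log(polII_load_range[1]), n)
        )
    if "backtrack_b" not in sim.truth:
        b = np.where(
            is_pos,
            rng.uniform(b_range_crac[0], b_range_crac[1], n),
            rng.uniform(b_range_rest[0], b_range_rest[1], n),
        )
        sim.truth["backtrack_b"] = b
        sim.truth["backtrack_b_mut"] = np.where(is_pos, b * mutant_b_multiplier_crac, b)

    out = {}
    load = sim.truth["polII_load"].to_numpy()
    for cond in conditions:
        b = (sim.truth["backtrack_b"] if cond == "WT" else sim.truth["backtrack_b_mut"]).to_numpy()
        chip = SignalTrack(sim.chrom_sizes)
        gro = SignalTrack(sim.chrom_sizes)
        chip_noise = _lognormal_factor(rng, noise_cv, n)
        gro_noise = _lognormal_factor(rng, noise_cv, n)
        for i, ann in enumerate(sim.annotations):
            chip.add_interval(ann.chrom, ann.start, ann.end, load[i] * chip_noise[i], ann.strand)
            gro.add_interval(ann.chrom, ann.start, ann.end, load[i] * (1 - b[i]) * gro_noise[i], ann.strand)
        out[cond] = (chip, gro)
    return out


# ---------------------------------------------------------------------------
# Rpb4 / Rpb3 stoichiometry
# ---------------------------------------------------------------------------


def generate_rpb4_tracks(
    sim: SimGenome,
    slope_per_kb,
    epsilon: float = 0.05,
    flank: int = 150,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Paired (Rpb4-ChIP, Rpb3-ChIP) tracks with a linear Rpb4 decline.

    Rpb3 is flat per gene (polymerase load); Rpb4 equals
    ``Rpb3 x max(epsilon, 1 - slope x d / 1000)`` where d is the distance
    from the TSS in bp, clipped to the transcript (the ratio is 1 over the
    upstream flank and holds its pA value over the downstream flank, so
    promoter-anchored normalisation positions are covered).

    ``slope_per_kb`` may be a scalar or a per-gene Series (dimensionless
    decline per kb).  Records the slope in ``sim.truth``.
    """
    rng = np.random.default_rng(seed)
    n = len(sim.annotations)
    if np.isscalar(slope_per_kb):
        slopes = pd.Series(float(slope_per_kb), index=sim.truth.index)
    else:
        slopes = pd.Series(slope_per_kb, index=sim.truth.index).astype(float)
    if "polII_load" not in sim.truth:
        sim.truth["polII_load"] = np.exp(rng.uniform(np.log(1.0), np.log(50.0), n))
    sim.truth["rpb4_slope_per_kb"] = slopes

    rpb4 = SignalTrack(sim.chrom_sizes)
    rpb3 = SignalTrack(sim.chrom_sizes)
    load = sim.truth["polII_load"].to_numpy()
    noise = _lognormal_factor(rng, noise_cv, n)
    for i, ann in enumerate(sim.annotations):
        L = ann.length
        size = sim.chrom_sizes[ann.chrom]
        s = slopes.iloc[i]
        ext = np.arange(-flank, L + flank)  # transcript-sense offsets from TSS
        genomic = ann.tss + ext if ann.strand == "+" else ann.tss - 1 - ext
        ok = (genomic >= 0) & (genomic < size)
        d = np.clip(ext, 0, L).astype(float)
        ratio = np.maximum(epsilon, 1.0 - s * d / 1000.0)
        v3 = rpb3.values(ann.chrom, ann.strand)
        v4 = rpb4.values(ann.chrom, ann.strand)
        v3[genomic[ok]] += load[i] * noise[i]
        v4[genomic[ok]] += load[i] * noise[i] * ratio[ok]
    return rpb4, rpb3


def class_slopes(
    sim: SimGenome,
    crac_slope: float = 0.35,
    rest_slope: float = 0.15,
) -> pd.Series:
    """Per-gene Rpb4-decline slopes (per kb): steeper in the CRAC+ class."""
    is_pos = sim.truth["is_crac_positive"].astype(bool)
    return pd.Series(np.where(is_pos, crac_slope, rest_slope), index=sim.truth.index)
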