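"""Classification of bound transcripts from pA-anchored cross-linking signal.

Workflow: take the top-N transcripts by cross-linking read count, cluster
their pA-anchored (row-scaled) profiles with k-means, call the clusters
whose signal mass concentrates in the window just upstream of the pA site
as bound ("CRAC+"), and compute a per-gene binding-propensity index
(cross-linking RPKM normalised to mRNA level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core_io import GeneSet, SignalMatrix, SignalTrack, transcript_signal_sum
from .metagene import anchored_matrix, bin_columns

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 600
DEFAULT_K = 4
DEFAULT_UPSTREAM_WINDOW = 250
DEFAULT_MASS_THRESHOLD = 0.6


@dataclass
class ClusterResult:
    """k-means clustering of pA-anchored profiles.

    ``labels`` are 1..k, relabelled in decreasing ``upstream_mass_fraction``
    so cluster 1 is the most pA-proximal.  ``cluster_mean_profiles`` are the
    means of the (row-scaled) matrix rows per cluster.
    """

    gene_ids: list
    labels: np.ndarray
    offsets: np.ndarray
    cluster_mean_profiles: np.ndarray
    upstream_mass_fraction: np.ndarray
    seed: int
    crac_positive_clusters: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.cluster_mean_profiles.shape[0]

    def genes_in_clusters(self, clusters) -> list:
        sel = np.isin(self.labels, list(clusters))
        return [g for g, s in zip(self.gene_ids, sel) if s]


def rpkm(counts, lengths, library_size: float) -> pd.Series:
    """Reads per kilobase of transcript per million mapped reads."""
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return counts / (lengths / 1e3) / (library_size / 1e6)


def gene_read_counts(track: SignalTrack, annotations: list) -> pd.Series:
    """Per-gene read mass over the transcript (own strand)."""
    return pd.Series(
        {a.gene_id: transcript_signal_sum(track, a) for a in annotations}, dtype=float
    )


def select_top_genes(counts: pd.Series, n: int = DEFAULT_TOP_N) -> GeneSet:
    """The n genes of highest count; ties broken by gene_id lexicographic order."""
    if n > len(counts):
        raise ValueError(f"requested top {n} of {len(counts)} genes")
    ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
    return GeneSet(f"top{n}", frozenset(ordered.index[:n]))


def row_scale(matrix: SignalMatrix) -> SignalMatrix:
    """Divide each row by its total in-window mass so clustering sees shape only.

    Zero-mass rows are left as zeros (they join the flattest cluster).
    Shape-only scaling is noise-sensitive for rows with very few reads: a
    two-read row concentrated upstream becomes indistinguishable from a
    strong peak, so cluster-level calling then inherits shot noise.
    """
    sums = matrix.row_sums()
    scale = np.where(sums > 0, sums, 1.0)
    return SignalMatrix(
        matrix.gene_ids, matrix.anchor, matrix.offsets, matrix.values / scale[:, None], matrix.mask
    )


def global_scale(matrix: SignalMatrix) -> SignalMatrix:
    """Divide the whole matrix by its mean row mass.

    Clustering then sees read density with between-gene amplitude retained
    (a bound gene's pile is separable from a sparse background row), while
    the classification stays invariant to multiplying the track by any
    positive constant.
    """
    scale = matrix.row_sums().mean()
    if scale <= 0:
        return matrix
    return SignalMatrix(
        matrix.gene_ids, matrix.anchor, matrix.offsets, matrix.values / scale, matrix.mask
    )


def scale_matrix(matrix: SignalMatrix, scaling: str) -> SignalMatrix:
    """Apply the requested pre-clustering scaling: ``global``, ``row``, or ``none``."""
    if scaling == "global":
        return global_scale(matrix)
    if scaling == "row":
        return row_scale(matrix)
    if scaling == "none":
        return matrix
    raise ValueError(f"unknown scaling {scaling!r}")


def _mass_fraction_upstream(profile: np.ndarray, offsets: np.ndarray, upstream_window: int) -> float:
    """Fraction of profile mass with offset in [-upstream_window, 0)."""
    total = profile.sum()
    if total <= 0:
        return 0.0
    sel = (offsets >= -upstream_window) & (offsets < 0)
    return float(profile[sel].sum() / total)


def kmeans_profiles(
    matrix: SignalMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> ClusterResult:
    """k-means clustering of anchored profile rows (expects a row-scaled matrix).

    Deterministic under a fixed seed and ``n_init``.  Labels are renumbered
    so that cluster 1 has the highest mass fraction in the
    ``[-upstream_window, 0)`` window of its mean profile.
    """
    if matrix.n_genes < k:
        raise ValueError(f"{matrix.n_genes} rows < k={k}")
    X = np.where(matrix.mask, matrix.values, 0.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw_labels = km.fit_predict(X)
    means = np.vstack([X[raw_labels == c].mean(axis=0) for c in range(k)])
    fracs = np.array(
        [_mass_fraction_upstream(means[c], matrix.offsets, upstream_window) for c in range(k)]
    )
    order = np.argsort(-fracs, kind="stable")  # most pA-proximal first
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterResult(
        gene_ids=list(matrix.gene_ids),
        labels=relabel[raw_labels],
        offsets=matrix.offsets.copy(),
        cluster_mean_profiles=means[order],
        upstream_mass_fraction=fracs[order],
        seed=seed,
    )


def call_crac_positive(
    clusters: ClusterResult,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    mass_threshold: float = DEFAULT_MASS_THRESHOLD,
) -> GeneSet:
    """Call bound genes: union of clusters whose mean-profile mass fraction
    within ``[-upstream_window, 0)`` of the pA exceeds ``mass_threshold``.

    Per-cluster fractions are recorded on the ``ClusterResult``.
    """
    if upstream_window > -clusters.offsets[0]:
        raise ValueError("upstream_window exceeds matrix extent")
    fracs = np.array(
        [
            _mass_fraction_upstream(clusters.cluster_mean_profiles[c], clusters.offsets, upstream_window)
            for c in range(clusters.k)
        ]
    )
    positive = [c + 1 for c in range(clusters.k) if fracs[c] > mass_threshold]
    clusters.crac_positive_clusters = positive
    clusters.upstream_mass_fraction = fracs
    return GeneSet("CRAC+", frozenset(clusters.genes_in_clusters(positive)))


def cluster_read_mass(raw_matrix: SignalMatrix, clusters: ClusterResult) -> pd.Series:
    """Read mass per cluster from the unscaled matrix (mass accounting).

    The sum over clusters equals the total matrix read mass; the fraction of
    reads in the called-positive clusters is the headline coverage figure of
    the classification report.
    """
    sums = raw_matrix.row_sums()
    out = {}
    for c in range(1, clusters.k + 1):
        out[c] = float(sums[clusters.labels == c].sum())
    return pd.Series(out, name="read_mass")


def crac_index(
    crac_rpkm: pd.Series,
    mrna_level: pd.Series,
    chip_signal: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene binding propensity: cross-linking RPKM over mRNA level.

    Genes with a zero denominator are flagged (``index_defined`` False), not
    dropped.  If a ChIP signal is given, the alternative normalisation
    ``alt_index = rpkm / chip`` is included.
    """
    df = pd.DataFrame({"crac_rpkm": crac_rpkm, "mrna_level": mrna_level})
    ok = df["mrna_level"] > 0
    df["crac_index"] = np.where(ok, df["crac_rpkm"] / df["mrna_level"].where(ok), np.nan)
    df["index_defined"] = ok
    if chip_signal is not None:
        chip = pd.Series(chip_signal).reindex(df.index)
        ok2 = chip > 0
        df["alt_index"] = np.where(ok2, df["crac_rpkm"] / chip.where(ok2), np.nan)
    return df


def silhouette_sweep(matrix: SignalMatrix, k_range=range(2, 9), seed: int = 0, n_init: int = 10) -> pd.Series:
    """Silhouette score for a range of k (cluster-count diagnostic)."""
    X = np.where(matrix.mask, matrix.values, 0.0)
    out = {}
    for k in k_range:
        labels = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit_predict(X)
        out[k] = float(silhouette_score(X, labels))
    return pd.Series(out, name="silhouette")


def threshold_sweep(
    clusters: ClusterResult,
    thresholds=np.arange(0.3, 0.95, 0.05),
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> pd.DataFrame:
    """Sensitivity of the called-set size to the mass threshold."""
    rows = []
    for t in thresholds:
        called = call_crac_positive(clusters, upstream_window, float(t))
        rows.append({"mass_threshold": float(t), "n_positive": len(called)})
    return pd.DataFrame(rows)


@dataclass
class ClassifyReport:
    """End-to-end classification result (see :func:`classify_pipeline`)."""

    top_genes: GeneSet
    clusters: ClusterResult
    crac_positive: GeneSet
    read_mass_per_cluster: pd.Series
    positive_read_fraction: float
    raw_matrix: SignalMatrix
    scaled_matrix: SignalMatrix


def classify_pipeline(
    track: SignalTrack,
    annotations: list,
    top_n: int = DEFAULT_TOP_N,
    upstream: int = 500,
    downstream: int = 100,
    bin_width: int = 10,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    mass_threshold: float = DEFAULT_MASS_THRESHOLD,
    scaling: str = "global",
) -> ClassifyReport:
    """Top-N selection -> pA-anchored matrix -> k-means -> bound-gene call.

    Profiles are binned to ``bin_width`` bp and scaled (default: globally,
    by the mean row mass) before clustering; read-mass accounting uses the
    unscaled matrix.
    """
    counts = gene_read_counts(track, annotations)
    top = select_top_genes(counts, min(top_n, len(counts)))
    selected = [a for a in annotations if a.gene_id in top]
    raw = bin_columns(anchored_matrix(track, selected, "pA", upstream, downstream), bin_width)
    scaled = scale_matrix(raw, scaling)
    clusters = kmeans_profiles(scaled, k=k, seed=seed, n_init=n_init, upstream_window=upstream_window)
    called = call_crac_positive(clusters, upstream_window, mass_threshold)
    mass = cluster_read_mass(raw, clusters)
    total = mass.sum()
    pos_frac = float(mass.loc[clusters.crac_positive_clusters].sum() / total) if total > 0 else 0.0
    return ClassifyReport(top, clusters, called, mass, pos_frac, raw, scaled)
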