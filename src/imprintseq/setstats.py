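"""Hypergeometric inclusion/exclusion tests and gene-set accounting.

Conventions: the enrichment p-value is the upper tail *including* the
observed overlap, P(X >= k); the depletion p-value is the lower tail
P(X <= k).  The universe must always be given explicitly — different
analyses legitimately use different universes, and a silent default to the
union of the sets would change the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSet


@dataclass(frozen=True)
class OverlapResult:
    """Two-set overlap under the hypergeometric null.

    ``fold`` is observed over expected overlap, k / (|A||B|/N).
    """

    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    p_enrich: float
    p_deplete: float
    fold: float


def hypergeom_overlap(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Exact hypergeometric tail probabilities for the overlap of two sets."""
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not set_a.members <= universe.members or not set_b.members <= universe.members:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    a, b = len(set_a), len(set_b)
    k = len(set_a.members & set_b.members)
    rv = stats.hypergeom(n, a, b)
    p_enrich = float(rv.sf(k - 1))  # P(X >= k)
    p_deplete = float(rv.cdf(k))  # P(X <= k)
    expected = a * b / n
    fold = k / expected if expected > 0 else np.nan
    return OverlapResult(n, a, b, k, p_enrich, p_deplete, fold)


def venn_counts(sets: list, universe: GeneSet) -> dict:
    """Exclusive region counts for 2 or 3 sets, keyed by membership tuples.

    Key ``(True, False)`` counts genes in the first set only, etc.  The
    ``"outside"`` key counts universe members in none of the sets; members
    outside the universe raise.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_counts handles 2 or 3 sets")
    for s in sets:
        if not s.members <= universe.members:
            raise ValueError(f"set {s.name!r} has members outside the universe")
    counts: dict = {}
    n_sets = len(sets)
    for pattern in [p for p in _bool_patterns(n_sets) if any(p)]:
        inside = universe.members
        for s, flag in zip(sets, pattern):
            inside = inside & s.members if flag else inside - s.members
        counts[pattern] = len(inside)
    counts["outside"] = len(universe.members - frozenset().union(*(s.members for s in sets)))
    return counts


def _bool_patterns(n: int):
    if n == 1:
        return [(True,), (False,)]
    return [(b,) + rest for b in (True, False) for rest in _bool_patterns(n - 1)]


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adj[idx] = running_max
    return adj


def annotation_enrichment(
    target: GeneSet,
    annotation: pd.DataFrame,
    universe: GeneSet,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment with Holm-Bonferroni adjustment.

    ``annotation`` maps genes to terms (columns ``gene_id`` and ``term``);
    genes outside the universe are ignored.  One upper-tail test per term.
    """
    ann = annotation[annotation["gene_id"].isin(universe.members)]
    rows = []
    for term, grp in ann.groupby("term"):
        term_set = GeneSet(str(term), frozenset(grp["gene_id"]))
        res = hypergeom_overlap(target, term_set, universe)
        rows.append(
            {
                "term": term,
                "term_size": res.size_b,
                "overlap": res.overlap,
                "fold": res.fold,
                "p_enrich": res.p_enrich,
            }
        )
    df = pd.DataFrame(rows).set_index("term")
    if len(df):
        df["p_holm"] = holm_bonferroni(df["p_enrich"].to_numpy())
    return df
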