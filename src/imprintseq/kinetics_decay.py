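"""Steady-state mRNA kinetics and time-course decay fitting.

At steady state, synthesis and decay balance, so the half-life in
arbitrary units is HL = RA / SR (abundance over synthesis rate).  For
transcription-arrest time courses, levels are normalised to a stable
reference transcript (e.g. the Pol III transcript SCR1) and scaled to 100%
at t = 0; a log-linear least-squares fit converts the normalised curve to
a half-life in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionTable


def half_life_steady_state(expr: ExpressionTable) -> pd.DataFrame:
    """Per-gene HL = RA / SR in arbitrary units; SR = 0 genes flagged, not dropped."""
    df = expr.data.copy()
    ok = df["SR"] > 0
    df["HL"] = np.where(ok, df["RA"] / df["SR"].where(ok), np.nan)
    df["hl_defined"] = ok
    return df


def condition_ratio(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    quantity: str = "HL",
    log2: bool = False,
) -> pd.Series:
    """Elementwise B/A ratio of SR, RA, or HL over the shared gene universe."""
    a = table_a.data if quantity in table_a.data else half_life_steady_state(table_a)
    b = table_b.data if quantity in table_b.data else half_life_steady_state(table_b)
    if quantity not in a or quantity not in b:
        raise ValueError(f"unknown quantity {quantity!r}")
    common = a.index.intersection(b.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b.loc[common, quantity] / a.loc[common, quantity]
    ratio.name = f"{quantity}_ratio"
    return np.log2(ratio) if log2 else ratio


@dataclass
class DecayCourse:
    """One gene's transcription-arrest decay time course.

    ``normalized_percent`` is (raw/reference) scaled so t = 0 equals 100%.
    """

    gene_id: str
    timepoints: np.ndarray
    raw_levels: np.ndarray
    reference_levels: np.ndarray
    normalized_percent: np.ndarray


def normalize_decay_course(
    gene_id: str,
    timepoints,
    raw,
    reference,
) -> DecayCourse:
    """Reference-normalise a raw course and rescale to 100% at t = 0."""
    t = np.asarray(timepoints, dtype=float)
    raw = np.asarray(raw, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if not (len(t) == len(raw) == len(ref)):
        raise ValueError("timepoints, raw and reference must have equal length")
    if 0.0 not in t:
        raise ValueError("a t = 0 point is required")
    if (ref <= 0).any():
        raise ValueError("reference must be > 0 at all timepoints")
    order = np.argsort(t, kind="stable")
    t, raw, ref = t[order], raw[order], ref[order]
    rel = raw / ref
    at0 = rel[t == 0][0]
    if at0 <= 0:
        raise ValueError("t = 0 level must be > 0")
    return DecayCourse(gene_id, t, raw, ref, 100.0 * rel / at0)


@dataclass
class DecayFit:
    gene_id: str
    half_life: float  # minutes; NaN when flagged
    slope: float  # of ln(percent) vs t
    r_squared: float
    n_points: int
    flag: str  # "", "no_decay", or "too_few_points"


def fit_decay_halflife(course: DecayCourse, min_points: int = 3) -> DecayFit:
    """Log-linear least squares on the normalised course; HL = ln 2 / |slope|.

    Points at or below zero are excluded (with the rest of the tail they
    carry no log-scale information); a non-negative slope is flagged
    ``no_decay`` rather than converted to a half-life.
    """
    keep = course.normalized_percent > 0
    t = course.timepoints[keep]
    y = np.log(course.normalized_percent[keep])
    if len(t) < min_points:
        return DecayFit(course.gene_id, np.nan, np.nan, np.nan, len(t), "too_few_points")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        return DecayFit(course.gene_id, np.nan, float(slope), float(r2), len(t), "no_decay")
    return DecayFit(course.gene_id, float(np.log(2) / abs(slope)), float(slope), float(r2), len(t), "")


def degron_shift_summary(
    ratios: pd.Series,
    gene_sets: dict,
) -> pd.DataFrame:
    """Median per-gene-set ratio shifts (distributional view of a depletion delta).

    ``gene_sets`` maps set name to an iterable of gene ids; a ``rest`` row
    (genes in none of the sets) is appended automatically.
    """
    rows = []
    covered: set = set()
    for name, members in gene_sets.items():
        members = set(members) & set(ratios.index)
        covered |= members
        vals = ratios.loc[sorted(members)].dropna()
        rows.append({"gene_set": name, "n": len(vals), "median_ratio": float(vals.median())})
    rest = ratios.drop(index=sorted(covered), errors="ignore").dropna()
    rows.append({"gene_set": "rest", "n": len(rest), "median_ratio": float(rest.median())})
    return pd.DataFrame(rows).set_index("gene_set")
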