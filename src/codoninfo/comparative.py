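"""Group-level comparative statistics over per-species measure vectors.

Summaries use medians as the central-tendency statistic (robust to the
outlier species every broad taxonomic sample contains), and express each
of the eight main entropies as an *efficiency*: the percentage of the
maximum attainable entropy for that codon part.  Hypothesis tallies
count, per group, the species for which a strict inequality between two
measures holds; exact floating-point ties count as not satisfied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .info_measures import MeasureRegistry, registry_preset

__all__ = [
    "summarize_groups",
    "efficiency_percentages",
    "tally_hypothesis",
    "diff_stats",
    "pearson",
    "gc_content",
    "TOTAL_SCOPE",
]

#: Scope label for pooled (all-species) rows in the tidy outputs.
TOTAL_SCOPE = "Total"

#: Two measures closer than this are a tie and never satisfy a strict inequality.
TIE_TOL = 1e-12


def _check_groups(measures: pd.DataFrame, groups: pd.Series) -> pd.Series:
    g = groups.reindex(measures.index)
    if g.isna().any():
        missing = list(measures.index[g.isna()])[:5]
        raise ValueError(f"species without a group assignment: {missing}")
    return g


def summarize_groups(
    measures: pd.DataFrame,
    groups: pd.Series,
    registry: MeasureRegistry | None = None,
) -> pd.DataFrame:
    """Tidy per-group and pooled summaries of every measure column.

    Returns one row per (group, measure) with n, median, mean, sd, min,
    max, and — for measures with a defined maximum (the marginal
    entropies and sI's) — ``pct_of_max`` = 100 * median / max.
    Pooled rows carry the group label ``Total``.
    """
    registry = registry or registry_preset("extended54")
    g = _check_groups(measures, groups)
    maxima = {m.name: m.max_value for m in registry.measures}
    rows = []
    scopes = [(TOTAL_SCOPE, measures)]
    for key in sorted(g.unique()):
        sub = measures.loc[g == key]
        if sub.empty:
            raise ValueError(f"group {key!r} has no species")
        scopes.append((key, sub))
    for key, sub in scopes:
        for col in measures.columns:
            x = sub[col].to_numpy(dtype=float)
            med = float(np.median(x))
            mx = maxima.get(col)
            rows.append(
                {
                    "group": key,
                    "measure": col,
                    "n": len(x),
                    "median": med,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                    "min": float(np.min(x)),
                    "max": float(np.max(x)),
                    "pct_of_max": 100.0 * med / mx if mx else np.nan,
                }
            )
    return pd.DataFrame(rows)


def efficiency_percentages(
    measures: pd.DataFrame, registry: MeasureRegistry | None = None
) -> pd.Series:
    """Pooled-median efficiency of each bounded measure, in percent.

    For each measure with a defined maximum, 100 * (median over all
    species) / max.  For the main entropies this is how close a sample
    of genomes comes to using a codon part at full informational
    capacity.
    """
    registry = registry or registry_preset("extended54")
    out = {}
    for m in registry.measures:
        if m.max_value and m.name in measures.columns:
            out[m.name] = 100.0 * float(measures[m.name].median()) / m.max_value
    if not out:
        raise ValueError("no bounded measures present in the matrix")
    return pd.Series(out, name="pct_of_max")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def tally_hypothesis(
    measures: pd.DataFrame,
    groups: pd.Series,
    lhs: str,
    rhs: str,
) -> pd.DataFrame:
    """Per-group counts of species with ``measures[lhs] > measures[rhs]``.

    Strict inequality; values equal within 1e-12 are ties and count as
    not satisfied (the ``ties`` column reports how many).  Includes a
    pooled ``Total`` row; group rows sum to it.
    """
    for col in (lhs, rhs):
        if col not in measures.columns:
            raise KeyError(f"unknown measure {col!r}; available: {list(measures.columns)[:8]}...")
    g = _check_groups(measures, groups)
    diff = measures[lhs].to_numpy(dtype=float) - measures[rhs].to_numpy(dtype=float)
    sat = diff > TIE_TOL
    tie = np.abs(diff) <= TIE_TOL
    frame = pd.DataFrame({"group": g.to_numpy(), "satisfied": sat, "tie": tie})
    rows = []
    for key, sub in frame.groupby("group", sort=True):
        rows.append(
            {
                "group": key,
                "satisfied": int(sub["satisfied"].sum()),
                "total": len(sub),
                "ties": int(sub["tie"].sum()),
            }
        )
    rows.append(
        {
            "group": TOTAL_SCOPE,
            "satisfied": int(sat.sum()),
            "total": len(sat),
            "ties": int(tie.sum()),
        }
    )
    out = pd.DataFrame(rows)
    out["percent"] = [
        _round_half_away(100.0 * s / t) for s, t in zip(out["satisfied"], out["total"])
    ]
    return out


@dataclass
class DiffStats:
    """Distributional summary of a per-species difference statistic."""

    scope: str
    n: int
    min: float
    max: float
    median: float
    mean: float
    ci99_low: float | None
    ci99_high: float | None


def diff_stats(
    measures: pd.DataFrame,
    groups: pd.Series | None = None,
    lhs: str = "H(T|aa)",
    rhs: str = "H(F|aa)",
) -> list[DiffStats]:
    """Summaries of Diff = lhs - rhs, pooled and (optionally) per group.

    Diff = H(T|aa) - H(F|aa) by default: positive when the third base is
    conditionally more variable than the first once the amino-acid
    composition is discounted.  The 99% confidence interval for the mean
    uses the normal approximation mean +/- z(0.995) * sd / sqrt(n) and is
    omitted (None) when n < 2.
    """
    diff = measures[lhs] - measures[rhs]
    scopes: list[tuple[str, pd.Series]] = [(TOTAL_SCOPE, diff)]
    if groups is not None:
        g = _check_groups(measures, groups)
        scopes += [(key, diff.loc[g == key]) for key in sorted(g.unique())]
    z = float(stats.norm.ppf(0.995))
    out = []
    for key, d in scopes:
        x = d.to_numpy(dtype=float)
        n = len(x)
        mean = float(np.mean(x))
        if n >= 2:
            half = z * float(np.std(x, ddof=1)) / math.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = None
        out.append(
            DiffStats(
                scope=key,
                n=n,
                min=float(np.min(x)),
                max=float(np.max(x)),
                median=float(np.median(x)),
                mean=mean,
                ci99_low=lo,
                ci99_high=hi,
            )
        )
    return out


def pearson(a, b) -> tuple[float, float]:
    """Sample Pearson correlation of two equal-length columns: (r, r^2)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance column")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


# number of G/C bases in each codon, canonical order
def _gc_counts() -> np.ndarray:
    from .genetic_code import CODONS

    return np.array([sum(b in "GC" for b in c) for c in CODONS], dtype=float)


_GC_COUNTS = _gc_counts()


def gc_content(rcf: np.ndarray) -> float:
    """GC fraction of coding positions implied by an RCF, in [0, 1].

    Sum over codons of rcf(c) * (G/C bases in c) / 3.
    """
    r = np.asarray(rcf, dtype=float)
    if r.shape != (64,):
        raise ValueError("RCF must be a 64-vector")
    return float((r * _GC_COUNTS).sum() / 3.0)
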