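"""Age-stratified statistics over synchronization patterns.

Patterns from many (individual, stimulated region) runs are pooled
into age bins — either the coarse young (< 30), middle (30-59) and
old (>= 60) groups, or fine 5-year bins with the sparse oldest bins
merged (65-75 and 75-90) — and summarized as:

- class proportions (asynchronous / chimera / synchronous, summing to
  1 per group) and their net change between age groups;
- pattern prevalence tables with low (< 3%), medium (3-5%, boundaries
  inclusive) and high (> 5%) tiers;
- the pattern similarity
  :math:`P_s = \\frac{1}{N_p(N_p-1)} \\sum_{i \\ne j}
  \\frac{1}{N_{CS}} \\sum_k \\delta_{ijk}`,
  the mean fraction of cognitive systems labelled identically across
  ordered pattern pairs, and its decomposition into *individual
  similarity* (how reproducible a region's pattern is across people)
  and *region similarity* (how uniform patterns are across a system's
  regions within one person);
- t-based 95% confidence intervals;
- the dominant class per strength decile of the stimulated region.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COARSE_BINS",
    "assign_age_bin",
    "fine_bin_order",
    "class_proportions",
    "net_change",
    "prevalence_table",
    "pattern_similarity",
    "similarity_decomposition",
    "confidence_interval",
    "strength_class_stratification",
]

logger = logging.getLogger(__name__)

COARSE_BINS = ("young", "middle", "old")
CLASS_ORDER = ("asynchronous", "chimera", "synchronous")

_FINE_MERGES = {65: (65, 75), 70: (65, 75), 75: (75, 90), 80: (75, 90), 85: (75, 90)}


def assign_age_bin(age: float, scheme: str = "coarse") -> str:
    """Age-bin label for one age.

    Coarse: ``young`` (< 30), ``middle`` (30 <= age < 60), ``old``
    (>= 60).  Fine: 5-year bins ``"a-b"``, with 65-70/70-75 merged
    into ``"65-75"`` and 75-80/80-85/85-90 into ``"75-90"``.
    """
    if age < 0:
        raise ValueError(f"negative age {age}")
    if scheme == "coarse":
        return "young" if age < 30 else "middle" if age < 60 else "old"
    if scheme == "fine":
        lo = int(age // 5) * 5
        lo, hi = _FINE_MERGES.get(lo, (lo, lo + 5))
        return f"{lo}-{hi}"
    raise ValueError(f"unknown binning scheme {scheme!r}")


def fine_bin_order(labels) -> list[str]:
    """Fine-bin labels sorted by their lower edge."""
    return sorted(set(labels), key=lambda s: int(s.split("-")[0]))


def _check_patterns(df: pd.DataFrame) -> None:
    if "cls" not in df.columns:
        raise ValueError("pattern table needs a 'cls' column")


def class_proportions(patterns: pd.DataFrame, by=("age_bin",)) -> pd.DataFrame:
    """Per-group proportions of the three classes.

    ``patterns`` is a tidy table with one row per (individual, region)
    run and at least the columns ``cls`` plus the grouping keys.
    Returns one row per group with columns ``asynchronous``,
    ``chimera``, ``synchronous`` and ``n``; proportions sum to 1 per
    row.  Empty groups are simply absent (with a log warning when a
    categorical grouping level goes unused).
    """
    _check_patterns(patterns)
    by = list(by)
    rows = []
    for key, grp in patterns.groupby(by, observed=False):
        if len(grp) == 0:
            logger.warning("empty group %s omitted", key)
            continue
        counts = grp["cls"].value_counts()
        n = len(grp)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        for c in CLASS_ORDER:
            row[c] = counts.get(c, 0) / n
        row["n"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def net_change(props_young: pd.Series | dict, props_old: pd.Series | dict) -> dict:
    """Signed per-class proportion differences, old minus young.

    Both inputs must provide all three classes; the differences sum to
    zero because each proportion triple sums to one.
    """
    out = {}
    for c in CLASS_ORDER:
        if c not in props_young or c not in props_old:
            raise ValueError(f"missing class {c!r} in proportions")
        out[c] = float(props_old[c]) - float(props_young[c])
    return out


def _tier(p: float, low: float = 0.03, high: float = 0.05) -> str:
    # the 3% and 5% boundaries both belong to the medium tier
    if p < low:
        return "low"
    if p <= high:
        return "medium"
    return "high"


def prevalence_table(
    patterns: pd.DataFrame, by=("age_bin",), low: float = 0.03, high: float = 0.05
) -> pd.DataFrame:
    """Ranked pattern prevalence with low/medium/high tiers.

    Per group, distinct label vectors (column ``labels``) are ranked
    by relative frequency; each gets a proportion, a rank (0 = most
    prevalent) and a tier: below ``low`` is low-prevalence, above
    ``high`` is high-prevalence, and the closed interval between them
    (boundaries included) is medium.
    """
    _check_patterns(patterns)
    if "labels" not in patterns.columns:
        raise ValueError("pattern table needs a 'labels' column")
    by = list(by)
    rows = []
    for key, grp in patterns.groupby(by, observed=True):
        counts = grp["labels"].value_counts()
        n = len(grp)
        for rank, (labels, c) in enumerate(counts.items()):
            p = c / n
            row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
            row.update(
                labels=labels, count=int(c), proportion=p, rank=rank,
                tier=_tier(p, low, high), cls=_labels_class(labels),
            )
            rows.append(row)
    return pd.DataFrame(rows)


def _labels_class(labels) -> str:
    vals = tuple(labels)
    if all(v == 1 for v in vals):
        return "synchronous"
    if all(v == 0 for v in vals):
        return "asynchronous"
    return "chimera"


def pattern_similarity(patterns) -> float:
    """Mean pairwise agreement P_s of a set of label vectors.

    ``patterns`` is a sequence of equal-length binary vectors.
    P_s is the average over ordered pairs (i != j) of the fraction of
    systems with identical labels; 1 for identical sets, 0 for two
    complementary patterns.  Needs at least two patterns.
    """
    M = np.asarray([tuple(p) for p in patterns], dtype=int)
    n_p = M.shape[0]
    if n_p < 2:
        raise ValueError("pattern similarity needs at least two patterns")
    n_cs = M.shape[1]
    # sum over unordered pairs of matching systems, via column counts
    ones = M.sum(axis=0)
    agree = ones * (ones - 1) / 2 + (n_p - ones) * (n_p - ones - 1) / 2
    return float(2 * agree.sum() / (n_p * (n_p - 1) * n_cs))


def similarity_decomposition(
    patterns: pd.DataFrame,
    mode: str,
    chimera_only: bool = False,
) -> float | None:
    """Individual- or region-wise mean pattern similarity.

    ``patterns`` must have columns ``individual``, ``region`` and
    ``labels`` (and ``cls`` when ``chimera_only``).  *Individual
    similarity* averages, over regions, the P_s of each region's
    patterns across individuals — high values mean different people
    respond alike.  *Region similarity* averages, over individuals,
    the P_s across the regions present — high values mean a system's
    regions behave interchangeably within a person.  Groups left with
    fewer than two patterns (e.g. after chimera-only filtering) are
    skipped with a warning; returns None when nothing remains.
    """
    if mode not in ("individual", "region"):
        raise ValueError("mode must be 'individual' or 'region'")
    df = patterns
    if chimera_only:
        df = df[df["cls"] == "chimera"]
    group_key = "region" if mode == "individual" else "individual"
    values = []
    for key, grp in df.groupby(group_key):
        if len(grp) < 2:
            logger.warning("%s %r has < 2 patterns; skipped", group_key, key)
            continue
        values.append(pattern_similarity(grp["labels"].tolist()))
    if not values:
        return None
    return float(np.mean(values))


def confidence_interval(samples, confidence: float = 0.95) -> tuple[float, float]:
    """Sample mean and t-based CI half-width.

    Half-width = t_{(1+c)/2, n-1} * s / sqrt(n) with s the sample
    standard deviation (ddof=1).  Needs n >= 2.
    """
    x = np.asarray(list(samples), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("confidence interval needs at least two samples")
    t = stats.t.ppf((1 + confidence) / 2, df=n - 1)
    half = float(t * x.std(ddof=1) / np.sqrt(n))
    return float(x.mean()), half


def strength_class_stratification(
    patterns: pd.DataFrame, n_bins: int = 10
) -> pd.DataFrame:
    """Class proportions per strength bin of the stimulated region.

    ``patterns`` needs columns ``strength`` and ``cls``.  Strengths
    are cut into ``n_bins`` equal-count bins (deciles by default —
    strength distributions are heavy-tailed, so equal-width bins go
    empty); within each bin the three class proportions and the
    dominant class are reported, ties broken toward chimera (the
    intermediate state).  Bins that come out empty after deduplication
    of cut points are merged by pandas ``qcut`` automatically.
    """
    df = patterns.copy()
    df["strength_bin"] = pd.qcut(df["strength"], q=n_bins, duplicates="drop")
    out = class_proportions(df, by=("strength_bin",))
    dominant = []
    for _, row in out.iterrows():
        props = {c: row[c] for c in CLASS_ORDER}
        best = max(props.values())
        winners = [c for c in CLASS_ORDER if props[c] == best]
        dominant.append("chimera" if "chimera" in winners and len(winners) > 1
                        else winners[0])
    out["dominant"] = dominant
    return out
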