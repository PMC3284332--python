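"""Monte-Carlo and exact tests on event placement.

* a clustering null for the minimum distance among uniformly placed
  crossovers,
* a placement null for the exonic content of a set of spans,
* an exact (Fisher) comparison of short-word counts between two pooled
  sequence sets, and
* pairwise-distance summaries for single- and double-crossover chromatids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ClusterNullResult",
    "PlacementNullResult",
    "min_distance_null",
    "min_distance_closed_form",
    "interval_placement_null",
    "word_count_fisher",
    "pairwise_distance_summary",
]


@dataclass
class ClusterNullResult:
    n_trials: int
    n_events: int
    region_length: int
    threshold: int
    mean_min_distance: float
    fraction_below_threshold: float
    null_min_distances: np.ndarray


@dataclass
class PlacementNullResult:
    n_trials: int
    observed_stat: float | None
    null_stats: np.ndarray
    null_mean: float
    empirical_p: float | None
    alternative: str


def min_distance_null(
    n_events: int = 15,
    region_length: int = 14_000_000,
    n_trials: int = 10_000,
    threshold: int = 25_000,
    seed: int = 0,
) -> ClusterNullResult:
    """Null distribution of the smallest adjacent distance among
    ``n_events`` integer coordinates drawn uniformly (with replacement) on
    ``[1, region_length]``."""
    if n_events < 2:
        raise ValueError("need at least two events")
    rng = np.random.default_rng(seed)
    coords = rng.integers(1, region_length + 1,
                          size=(n_trials, n_events), dtype=np.int64)
    coords.sort(axis=1)
    mins = np.diff(coords, axis=1).min(axis=1)
    return ClusterNullResult(
        n_trials=n_trials,
        n_events=n_events,
        region_length=region_length,
        threshold=threshold,
        mean_min_distance=float(mins.mean()),
        fraction_below_threshold=float(np.mean(mins <= threshold)),
        null_min_distances=mins,
    )


def min_distance_closed_form(n_events: int, region_length: float,
                             threshold: float) -> float:
    """Continuous order-statistics probability that the minimum gap among
    ``n`` uniform points is at most d: 1 - (1 - (n-1) d / L)^n."""
    n, d, L = n_events, threshold, float(region_length)
    inner = 1.0 - (n - 1) * d / L
    return 1.0 if inner <= 0 else 1.0 - inner ** n


def _exon_prefix(annotation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merged exon intervals (0-based half-open) and a coverage prefix sum."""
    import pandas as pd

    if isinstance(annotation, pd.DataFrame):
        exons = annotation.loc[annotation["feature"] == "exon",
                               ["start", "end"]].to_numpy(dtype=np.int64)
    else:
        exons = np.asarray(annotation, dtype=np.int64).reshape(-1, 2)
    if exons.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros(1, dtype=np.int64)
    exons = exons[np.argsort(exons[:, 0])]
    merged = [list(exons[0])]
    for s, e in exons[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    merged = np.asarray(merged, dtype=np.int64)
    starts, ends = merged[:, 0], merged[:, 1]
    prefix = np.concatenate(([0], np.cumsum(ends - starts)))
    return starts, ends, prefix


def _exonic_coverage_below(x: np.ndarray, starts, ends, prefix) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(np.shape(x), dtype=np.int64)
    i = np.searchsorted(starts, x, side="right")
    j = np.maximum(i - 1, 0)
    part = prefix[j] + np.clip(x - starts[j], 0, ends[j] - starts[j])
    return np.where(i > 0, part, 0)


def exonic_fraction(intervals: np.ndarray, annotation) -> float:
    """Exonic proportion of a set of 0-based half-open intervals."""
    starts, ends, prefix = _exon_prefix(annotation)
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    ex = _exonic_coverage_below(iv[:, 1], starts, ends, prefix) - \
        _exonic_coverage_below(iv[:, 0], starts, ends, prefix)
    total = (iv[:, 1] - iv[:, 0]).sum()
    return float(ex.sum() / total) if total else float("nan")


def interval_placement_null(
    span_lengths,
    annotation,
    chromosome_length: int,
    n_trials: int = 1000,
    observed_stat: float | None = None,
    alternative: str = "less",
    seed: int = 0,
) -> PlacementNullResult:
    """Place each span independently and uniformly on the chromosome and
    record the aggregate exonic proportion of each random set.

    ``alternative='less'`` (exon avoidance) counts null sets with a
    proportion at most the observed one.
    """
    span_lengths = np.asarray(span_lengths, dtype=np.int64)
    if np.any(span_lengths > chromosome_length):
        raise ValueError("span longer than chromosome")
    if np.any(span_lengths < 1):
        raise ValueError("span lengths must be >= 1")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    rng = np.random.default_rng(seed)
    starts, ends, prefix = _exon_prefix(annotation)
    total_len = float(span_lengths.sum())
    nulls = np.empty(n_trials)
    for t in range(n_trials):
        s = rng.integers(0, chromosome_length - span_lengths + 1)
        e = s + span_lengths
        ex = _exonic_coverage_below(e, starts, ends, prefix) - \
            _exonic_coverage_below(s, starts, ends, prefix)
        nulls[t] = ex.sum() / total_len
    emp = None
    if observed_stat is not None:
        if alternative == "less":
            emp = float(np.mean(nulls <= observed_stat))
        else:
            emp = float(np.mean(nulls >= observed_stat))
    return PlacementNullResult(
        n_trials=n_trials,
        observed_stat=observed_stat,
        null_stats=nulls,
        null_mean=float(nulls.mean()),
        empirical_p=emp,
        alternative=alternative,
    )


def word_count_fisher(
    count_a: int,
    length_a: int,
    count_b: int,
    length_b: int,
    word_length: int = 7,
    alternative: str = "two-sided",
) -> float:
    """Fisher exact P comparing word occurrences between two pooled
    sequence sets, with the number of nonoverlapping word positions
    (floor(length / word_length)) as the totals.

    Default is the conventional two-sided P (sum of all tables at most as
    probable as the observed one); ``alternative`` accepts the one-sided
    variants too.
    """
    if min(count_a, length_a, count_b, length_b, word_length) < 0:
        raise ValueError("inputs must be nonnegative")
    n_a = length_a // word_length
    n_b = length_b // word_length
    if count_a > n_a or count_b > n_b:
        raise ValueError("counts exceed available nonoverlapping positions")
    table = [[count_a, n_a - count_a], [count_b, n_b - count_b]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def pairwise_distance_summary(crossovers) -> dict:
    """Mean pairwise distance between single-CO midpoints and the midpoint
    separation of each double-CO chromatid.

    ``crossovers`` is a list of events with ``progeny_id`` and ``midpoint``
    attributes.  Undefined summaries are returned as None.
    """
    by_progeny: dict[str, list[float]] = {}
    for c in crossovers:
        by_progeny.setdefault(c.progeny_id, []).append(float(c.midpoint))
    sco_mids = sorted(m[0] for m in by_progeny.values() if len(m) == 1)
    dco = {pid: abs(m[1] - m[0]) for pid, m in by_progeny.items()
           if len(m) == 2}

    out: dict = {
        "sco_midpoints": sco_mids,
        "dco_separations": dco,
        "sco_mean_pairwise_distance": None,
        "dco_mean_separation": None,
    }
    if len(sco_mids) >= 2:
        x = np.asarray(sco_mids)
        n = x.size
        coef = 2.0 * np.arange(1, n + 1) - n - 1
        out["sco_mean_pairwise_distance"] = float(
            np.dot(coef, x) / (n * (n - 1) / 2.0))
    if dco:
        out["dco_mean_separation"] = float(np.mean(list(dco.values())))
    return out
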