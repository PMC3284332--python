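"""Segmentation of progeny haplotype calls into crossover and conversion events.

A hemizygous chromatid is read as a sequence of parental-origin calls at
known marker positions.  Maximal runs of one parent are extracted (missing
calls ignored); short internal runs bounded on both sides by the opposite
parent are interpreted as noncrossover gene conversions (GC), every other
run boundary as a crossover (CO).  Candidate conversions supported by fewer
than ``min_gc_markers`` markers are reported separately as low-confidence
candidates: with a nonzero false-call rate these are dominated by isolated
genotyping errors, and excluding them plays the role the study's
Sanger re-verification played for sequencing-based candidates.

Span bookkeeping follows the joint likelihood's partition of the data: every
gap between adjacent called markers that does not overlap a detected
conversion tract is a "span that witnessed no conversion" and enters the
span histogram; gaps above the cutoff ``b`` carry almost no information
about the conversion process and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MISSING, MarkerMap, ObservedCalls

__all__ = [
    "HaplotypeRun",
    "CrossoverEvent",
    "ConversionEvent",
    "SpanHistogram",
    "segment_haplotype",
    "classify_events",
    "span_histogram",
    "summarize_events",
    "detect_dataset",
    "events_to_frames",
]


@dataclass(frozen=True)
class HaplotypeRun:
    """Maximal run of identical parental calls over the called markers."""

    start: int  # index into the called-marker subsequence, inclusive
    end: int  # inclusive
    parent: int

    @property
    def n_markers(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CrossoverEvent:
    progeny_id: str
    distal_flank_pos: int  # last marker of the preceding haplotype
    proximal_flank_pos: int  # first marker of the following haplotype
    co_class: str = "SCO"  # SCO or DCO-member

    @property
    def span(self) -> int:
        return self.proximal_flank_pos - self.distal_flank_pos

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.distal_flank_pos + self.proximal_flank_pos)


@dataclass(frozen=True)
class ConversionEvent:
    progeny_id: str
    distal_flank_pos: int  # nearest nonconverted called marker, distal side
    proximal_flank_pos: int
    first_converted_pos: int
    last_converted_pos: int
    n_converted: int
    donor_parent: int

    def __post_init__(self) -> None:
        if not (self.distal_flank_pos < self.first_converted_pos
                <= self.last_converted_pos < self.proximal_flank_pos):
            raise ValueError("conversion event coordinates out of order")

    @property
    def min_tract(self) -> int:
        return self.last_converted_pos - self.first_converted_pos

    @property
    def max_tract(self) -> int:
        return self.proximal_flank_pos - self.distal_flank_pos

    @property
    def span(self) -> int:
        return self.max_tract

    @property
    def left_offset(self) -> int:
        return self.first_converted_pos - self.distal_flank_pos

    @property
    def right_offset(self) -> int:
        return self.proximal_flank_pos - self.last_converted_pos


@dataclass
class SpanHistogram:
    """Counts ``N_a`` of no-conversion inter-marker spans of length a <= b."""

    b: int
    counts: np.ndarray  # length b + 1; index a = span length, index 0 unused

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != self.b + 1:
            raise ValueError("counts must have length b + 1")
        if np.any(self.counts < 0):
            raise ValueError("span counts must be nonnegative")

    @classmethod
    def empty(cls, b: int = 10_000) -> "SpanHistogram":
        return cls(b=b, counts=np.zeros(b + 1, dtype=np.int64))

    def add(self, other: "SpanHistogram") -> "SpanHistogram":
        if other.b != self.b:
            raise ValueError("histograms have different b")
        return SpanHistogram(self.b, self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        """(span lengths a, counts N_a) for nonzero entries."""
        a = np.flatnonzero(self.counts)
        return a, self.counts[a]


def segment_haplotype(calls: ObservedCalls) -> list[HaplotypeRun]:
    """Extract maximal same-parent runs over the called markers."""
    vals = calls.calls[calls.calls != MISSING]
    if vals.size == 0:
        raise ValueError("all calls missing; cannot segment haplotype")
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [vals.size - 1]))
    return [HaplotypeRun(int(s), int(e), int(vals[s]))
            for s, e in zip(starts, ends)]


def classify_events(
    runs: list[HaplotypeRun],
    called_positions: np.ndarray,
    progeny_id: str = "progeny",
    min_flank_markers: int = 1,
    max_gc_extent: int = 10_000,
    min_gc_markers: int = 2,
) -> tuple[list[CrossoverEvent], list[ConversionEvent], list[ConversionEvent]]:
    """Classify run boundaries into COs, conversions and low-confidence
    conversion candidates.

    ``called_positions`` are the bp positions of the called markers the runs
    index into.  An internal run whose outer span (distance between the
    nearest called markers of the neighbouring runs) is at most
    ``max_gc_extent`` is a conversion candidate; wider internal runs are
    read as a pair of crossovers.  Candidates with fewer than
    ``min_gc_markers`` converted markers are set aside as low confidence.
    """
    called_positions = np.asarray(called_positions, dtype=np.int64)
    conversions: list[ConversionEvent] = []
    low_conf: list[ConversionEvent] = []
    kept: list[HaplotypeRun] = []
    for j, run in enumerate(runs):
        internal = 0 < j < len(runs) - 1
        is_candidate = False
        if internal:
            prev_run, next_run = runs[j - 1], runs[j + 1]
            distal = int(called_positions[prev_run.end])
            proximal = int(called_positions[next_run.start])
            if (proximal - distal <= max_gc_extent
                    and prev_run.n_markers >= min_flank_markers
                    and next_run.n_markers >= min_flank_markers):
                is_candidate = True
                event = ConversionEvent(
                    progeny_id=progeny_id,
                    distal_flank_pos=distal,
                    proximal_flank_pos=proximal,
                    first_converted_pos=int(called_positions[run.start]),
                    last_converted_pos=int(called_positions[run.end]),
                    n_converted=run.n_markers,
                    donor_parent=run.parent,
                )
                if run.n_markers >= min_gc_markers:
                    conversions.append(event)
                else:
                    low_conf.append(event)
        if not is_candidate:
            kept.append(run)

    # merge neighbouring kept runs of the same parent (conversion runs that
    # separated them have been explained away); the remaining alternation
    # boundaries are crossovers
    merged: list[HaplotypeRun] = []
    for run in kept:
        if merged and merged[-1].parent == run.parent:
            merged[-1] = HaplotypeRun(merged[-1].start, run.end, run.parent)
        else:
            merged.append(run)

    n_co = len(merged) - 1
    co_class = "SCO" if n_co == 1 else "DCO-member"
    crossovers = [
        CrossoverEvent(
            progeny_id=progeny_id,
            distal_flank_pos=int(called_positions[left.end]),
            proximal_flank_pos=int(called_positions[right.start]),
            co_class=co_class,
        )
        for left, right in zip(merged[:-1], merged[1:])
    ]
    return crossovers, conversions, low_conf


def span_histogram(
    called_positions_per_progeny: list[np.ndarray],
    conversions: list[ConversionEvent],
    progeny_ids: list[str] | None = None,
    b: int = 10_000,
) -> SpanHistogram:
    """Aggregate no-conversion spans between adjacent called markers.

    A gap between adjacent called markers contributes one count at its
    length unless it lies within the outer span of a detected conversion on
    the same progeny, or exceeds ``b``.
    """
    counts = np.zeros(b + 1, dtype=np.int64)
    if progeny_ids is None:
        progeny_ids = [f"progeny_{i:03d}"
                       for i in range(len(called_positions_per_progeny))]
    conv_by_progeny: dict[str, list[ConversionEvent]] = {}
    for ev in conversions:
        conv_by_progeny.setdefault(ev.progeny_id, []).append(ev)
    for pid, pos in zip(progeny_ids, called_positions_per_progeny):
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size < 2:
            continue
        gaps = np.diff(pos)
        keep = gaps <= b
        for ev in conv_by_progeny.get(pid, ()):
            inside = (pos[:-1] >= ev.distal_flank_pos) & \
                     (pos[1:] <= ev.proximal_flank_pos)
            keep &= ~inside
        counts += np.bincount(gaps[keep], minlength=b + 1)[: b + 1]
    return SpanHistogram(b=b, counts=counts)


def _exonic_overlap(intervals: np.ndarray, annotation: pd.DataFrame) -> int:
    """Total exonic bp covered by 1-based inclusive [start, end] intervals."""
    exons = annotation.loc[annotation["feature"] == "exon", ["start", "end"]]
    exons = exons.sort_values("start").to_numpy(dtype=np.int64)
    if exons.size == 0 or intervals.size == 0:
        return 0
    # merge then prefix-sum exonic coverage (0-based half-open)
    merged = [list(exons[0])]
    for s, e in exons[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    merged = np.asarray(merged, dtype=np.int64)
    starts, ends = merged[:, 0], merged[:, 1]
    prefix = np.concatenate(([0], np.cumsum(ends - starts)))

    def cov_below(x: np.ndarray) -> np.ndarray:
        i = np.searchsorted(starts, x, side="right")
        full = prefix[i - 1] + np.clip(x - starts[np.maximum(i - 1, 0)], 0,
                                       (ends - starts)[np.maximum(i - 1, 0)])
        return np.where(i > 0, full, 0)

    lo = intervals[:, 0] - 1  # to 0-based half-open
    hi = intervals[:, 1]
    return int(np.sum(cov_below(hi) - cov_below(lo)))


def summarize_events(
    crossovers: list[CrossoverEvent],
    conversions: list[ConversionEvent],
    annotation: pd.DataFrame | None = None,
    localized: list[bool] | None = None,
) -> dict:
    """Span and tract bookkeeping over detected events.

    ``localized`` optionally flags which crossovers are narrowly localized;
    unlocalized spans are excluded from mean/total span statistics (but still
    count toward per-chromatid crossover tallies).
    """
    from .resampling import pairwise_distance_summary

    if localized is None:
        localized = [True] * len(crossovers)
    loc_spans = np.array([c.span for c, ok in zip(crossovers, localized) if ok],
                         dtype=np.int64)
    gc_max = np.array([g.max_tract for g in conversions], dtype=np.int64)

    out: dict = {
        "n_crossovers": len(crossovers),
        "n_conversions": len(conversions),
        "n_localized_spans": int(loc_spans.size),
        "total_co_span": int(loc_spans.sum()) if loc_spans.size else None,
        "mean_co_span": float(loc_spans.mean()) if loc_spans.size else None,
        "total_gc_max_tract": int(gc_max.sum()) if gc_max.size else None,
    }

    per_chromatid = {}
    for c in crossovers:
        per_chromatid[c.progeny_id] = per_chromatid.get(c.progeny_id, 0) + 1
    out["co_per_chromatid"] = per_chromatid
    out["n_sco_chromatids"] = sum(1 for v in per_chromatid.values() if v == 1)
    out["n_dco_chromatids"] = sum(1 for v in per_chromatid.values() if v == 2)

    dist = pairwise_distance_summary(crossovers)
    out.update(dist)

    if annotation is not None:
        co_iv = np.array([[c.distal_flank_pos + 1, c.proximal_flank_pos]
                          for c, ok in zip(crossovers, localized) if ok],
                         dtype=np.int64).reshape(-1, 2)
        gc_iv = np.array([[g.distal_flank_pos + 1, g.proximal_flank_pos]
                          for g in conversions], dtype=np.int64).reshape(-1, 2)
        co_ex = _exonic_overlap(co_iv, annotation)
        gc_ex = _exonic_overlap(gc_iv, annotation)
        out["co_span_exonic_bp"] = co_ex
        out["gc_tract_exonic_bp"] = gc_ex
        out["co_span_exonic_fraction"] = (
            co_ex / out["total_co_span"] if out["total_co_span"] else None)
        out["gc_tract_exonic_fraction"] = (
            gc_ex / out["total_gc_max_tract"] if out["total_gc_max_tract"] else None)
    return out


def detect_dataset(
    marker_map: MarkerMap,
    observed: list[ObservedCalls],
    min_flank_markers: int = 1,
    max_gc_extent: int = 10_000,
    min_gc_markers: int = 2,
    b: int = 10_000,
) -> dict:
    """Run segmentation, classification and span bookkeeping for a dataset."""
    crossovers: list[CrossoverEvent] = []
    conversions: list[ConversionEvent] = []
    low_conf: list[ConversionEvent] = []
    called_positions = []
    ids = []
    for obs in observed:
        mask = obs.calls != MISSING
        pos = marker_map.positions[mask]
        called_positions.append(pos)
        ids.append(obs.progeny_id)
        if pos.size == 0:
            continue
        runs = segment_haplotype(obs)
        cos, convs, lc = classify_events(
            runs, pos, obs.progeny_id,
            min_flank_markers=min_flank_markers,
            max_gc_extent=max_gc_extent,
            min_gc_markers=min_gc_markers,
        )
        crossovers.extend(cos)
        conversions.extend(convs)
        low_conf.extend(lc)
    hist = span_histogram(called_positions, conversions, ids, b=b)
    return {
        "crossovers": crossovers,
        "conversions": conversions,
        "low_confidence": low_conf,
        "span_histogram": hist,
    }


def events_to_frames(crossovers, conversions) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate events in the layout of the study's event tables."""
    co = pd.DataFrame(
        [
            {
                "progeny": c.progeny_id,
                "co_class": c.co_class,
                "distal_snp": c.distal_flank_pos,
                "proximal_snp": c.proximal_flank_pos,
                "span": c.span,
            }
            for c in crossovers
        ]
    )
    gc = pd.DataFrame(
        [
            {
                "progeny": g.progeny_id,
                "distal_snp": g.distal_flank_pos,
                "first_snp": g.first_converted_pos,
                "n_converted": g.n_converted,
                "last_snp": g.last_converted_pos,
                "proximal_snp": g.proximal_flank_pos,
                "min_tract": g.min_tract,
                "max_tract": g.max_tract,
                "donor_parent": g.donor_parent,
            }
            for g in conversions
        ]
    )
    return co, gc
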