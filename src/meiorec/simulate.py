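"""Synthetic meiosis: marker maps and recombinant chromatids with known truth.

The generator emulates a cross between two isogenized parental lines that
differ at tens of thousands of SNP/InDel markers along one hemizygous
chromosome arm.  Each simulated chromatid carries

* 0-2 crossovers (COs), placed with a distal bias and a hard minimum
  separation standing in for interference, and
* noncrossover gene-conversion (GC) events: double-strand breaks (DSBs)
  placed as a Poisson process along the chromosome, each converting an
  interval ``[dsb - left, dsb + right]`` where the left/right extensions are
  independent geometric draws with cessation probability ``p`` (the DSB
  nucleotide itself is always converted, so ``p = 1`` converts exactly one
  site).

The observation model then degrades the truth the way progeny resequencing
does: each marker is called with probability ``call_rate`` and each called
marker is flipped to the opposite parent with probability
``false_call_rate`` (isolated single-marker errors, the raw material of
false conversion candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MarkerMap",
    "SimulationParams",
    "ChromatidTruth",
    "ObservedCalls",
    "generate_marker_map",
    "generate_annotation",
    "simulate_chromatid",
    "apply_observation_model",
    "simulate_dataset",
    "DEFAULT_PARAMS",
]

P1, P2, MISSING = 0, 1, -1

#: Default scale of the study design: ~93.5k markers on a 22.4-Mb arm.
DEFAULT_N_MARKERS = 93_538
DEFAULT_CHROM_LENGTH = 22_400_000

#: Dispersion of inter-marker gaps (gamma shape = 1 / clustering).  Real
#: polymorphism is strongly clumped; this default makes gaps over-dispersed
#: enough that a conversion tract of mean total length ~476 bp covers a
#: genotyped marker roughly 40% of the time, the detectability the study
#: design implies, instead of the ~75% a uniform map would give.
DEFAULT_CLUSTERING = 6.0


@dataclass(frozen=True)
class MarkerMap:
    """Ordered polymorphic positions distinguishing the two parents."""

    chromosome_name: str
    chromosome_length: int
    positions: np.ndarray  # 1-based bp, strictly increasing
    kinds: np.ndarray  # "SNP" or "InDel"; carried but not used downstream
    alleles_p1: np.ndarray
    alleles_p2: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size:
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > self.chromosome_length:
                raise ValueError("marker positions outside chromosome bounds")
        if np.any(self.alleles_p1 == self.alleles_p2):
            raise ValueError("parental alleles must differ at every marker")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class SimulationParams:
    """Stochastic model of one female meiosis, as transmitted to one chromatid."""

    n_progeny: int = 30
    co_count_probs: tuple = (0.4, 0.5, 0.1)
    #: piecewise-constant CO density: (breakpoints incl. 0 and L fractions, weights)
    co_density_breaks: tuple = (0.0, 2.0 / 3.0, 1.0)
    co_density_weights: tuple = (0.9, 0.1)
    interference_min_separation: int = 4_000_000
    nco_dsb_rate: float = 1.8e-8  # DSBs per bp per transmitted chromatid
    tract_p: float = 1.0 / 239.0  # geometric cessation probability
    call_rate: float = 0.7
    false_call_rate: float = 1.2e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.co_count_probs) - 1.0) > 1e-9:
            raise ValueError("co_count_probs must sum to 1")
        if self.nco_dsb_rate < 0:
            raise ValueError("nco_dsb_rate must be >= 0")
        if not (0.0 < self.tract_p <= 1.0):
            raise ValueError("tract_p must be in (0, 1]")
        for r in (self.call_rate, self.false_call_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if len(self.co_density_weights) != len(self.co_density_breaks) - 1:
            raise ValueError("co_density_weights/breaks length mismatch")


DEFAULT_PARAMS = SimulationParams()


@dataclass(frozen=True)
class ChromatidTruth:
    """Ground truth for one simulated chromatid."""

    progeny_id: str
    start_parent: int  # parent of the distal-most segment (P1/P2)
    co_breakpoints: np.ndarray  # bp; CO between position x and x+1
    gc_events: list  # of (dsb_position, left_extension, right_extension)

    def converted_intervals(self) -> np.ndarray:
        """Inclusive 1-based [start, end] conversion intervals, one per DSB."""
        if not self.gc_events:
            return np.empty((0, 2), dtype=np.int64)
        arr = np.array(
            [(d - l, d + r) for d, l, r in self.gc_events], dtype=np.int64
        )
        return arr

    def parental_origin(self, positions: np.ndarray) -> np.ndarray:
        """Parental origin (P1/P2) at each queried position."""
        positions = np.asarray(positions, dtype=np.int64)
        n_flips = np.searchsorted(self.co_breakpoints, positions, side="left")
        origin = (self.start_parent + n_flips) % 2
        conv = np.zeros(positions.shape, dtype=bool)
        for start, end in self.converted_intervals():
            conv |= (positions >= start) & (positions <= end)
        origin = np.where(conv, 1 - origin, origin)
        return origin.astype(np.int8)


@dataclass(frozen=True)
class ObservedCalls:
    """Per-progeny parental-origin calls at every map marker.

    ``calls`` holds P1 (0), P2 (1) or MISSING (-1), one entry per marker of
    the map the progeny was genotyped against.
    """

    progeny_id: str
    calls: np.ndarray  # int8

    def __post_init__(self) -> None:
        object.__setattr__(self, "calls", np.asarray(self.calls, dtype=np.int8))

    @property
    def n_called(self) -> int:
        return int(np.sum(self.calls != MISSING))


def _chromatid_rng(seed: int, index: int) -> np.random.Generator:
    # deterministic substream per (dataset seed, progeny index)
    return np.random.default_rng([int(seed), int(index)])


def generate_marker_map(
    n_markers: int = DEFAULT_N_MARKERS,
    chromosome_length: int = DEFAULT_CHROM_LENGTH,
    clustering: float = DEFAULT_CLUSTERING,
    seed: int = 0,
    chromosome_name: str = "X",
    snp_fraction: float = 0.845,
) -> MarkerMap:
    """Draw a marker map with optionally clumped positions.

    Inter-marker gaps are proportional to Gamma(1/clustering) weights:
    ``clustering = 1`` reproduces uniform order statistics, larger values
    give over-dispersed (clumped) gaps like real polymorphism data.
    """
    if n_markers < 0:
        raise ValueError("n_markers must be >= 0")
    if n_markers > chromosome_length:
        raise ValueError("n_markers cannot exceed chromosome_length")
    rng = np.random.default_rng(seed)
    if n_markers == 0:
        empty = np.empty(0)
        return MarkerMap(chromosome_name, chromosome_length, empty, empty.astype(str),
                         empty.astype(str), empty.astype(str))
    if clustering <= 0:
        raise ValueError("clustering must be > 0")
    weights = rng.gamma(1.0 / clustering, 1.0, size=n_markers + 1)
    cum = np.cumsum(weights)
    frac = cum[:-1] / cum[-1]
    pos = np.floor(frac * chromosome_length).astype(np.int64) + 1
    # enforce strict increase within [1, chromosome_length]
    idx = np.arange(n_markers, dtype=np.int64)
    pos = np.maximum.accumulate(pos - idx) + idx
    pos = np.minimum(pos, chromosome_length - n_markers + 1 + idx)
    pos = np.maximum.accumulate(pos - idx) + idx  # re-fix after upper clip

    bases = np.array(["A", "C", "G", "T"])
    a1 = rng.integers(0, 4, size=n_markers)
    a2 = (a1 + rng.integers(1, 4, size=n_markers)) % 4
    kinds = np.where(rng.random(n_markers) < snp_fraction, "SNP", "InDel")
    alleles_p1 = bases[a1].copy()
    alleles_p2 = bases[a2].copy()
    indel = kinds == "InDel"
    # represent InDels as insertion alleles on the P2 side
    alleles_p2 = np.where(indel, np.char.add(bases[a1], bases[a2]), alleles_p2)
    return MarkerMap(chromosome_name, int(chromosome_length), pos, kinds,
                     alleles_p1, alleles_p2)


def _draw_co_positions(rng: np.random.Generator, n_co: int,
                       params: SimulationParams, length: int) -> np.ndarray:
    if n_co == 0:
        return np.empty(0, dtype=np.int64)
    breaks = np.asarray(params.co_density_breaks) * length
    weights = np.asarray(params.co_density_weights, dtype=float)
    weights = weights / weights.sum()
    for _ in range(10_000):
        seg = rng.choice(len(weights), size=n_co, p=weights)
        lo, hi = breaks[seg], breaks[seg + 1]
        pos = np.sort((lo + rng.random(n_co) * (hi - lo)).astype(np.int64))
        pos = np.clip(pos, 1, length - 1)
        if n_co < 2 or np.all(np.diff(pos) >= params.interference_min_separation):
            return pos
    raise RuntimeError("could not satisfy interference constraint")


def simulate_chromatid(
    marker_map: MarkerMap,
    params: SimulationParams,
    seed: int,
    index: int = 0,
    progeny_id: str | None = None,
) -> tuple[ChromatidTruth, np.ndarray]:
    """Simulate one transmitted chromatid; returns truth and the true
    parental-origin vector at the map's marker positions."""
    rng = _chromatid_rng(seed, index)
    length = marker_map.chromosome_length
    n_co = int(rng.choice(len(params.co_count_probs), p=params.co_count_probs))
    co_pos = _draw_co_positions(rng, n_co, params, length)
    start_parent = int(rng.integers(0, 2))

    n_dsb = int(rng.poisson(params.nco_dsb_rate * length))
    gc_events = []
    if n_dsb:
        dsb_pos = rng.integers(1, length + 1, size=n_dsb)
        left = rng.geometric(params.tract_p, size=n_dsb) - 1
        right = rng.geometric(params.tract_p, size=n_dsb) - 1
        gc_events = [(int(d), int(l), int(r))
                     for d, l, r in zip(dsb_pos, left, right)]

    truth = ChromatidTruth(
        progeny_id=progeny_id or f"progeny_{index:03d}",
        start_parent=start_parent,
        co_breakpoints=co_pos,
        gc_events=gc_events,
    )
    origin = truth.parental_origin(marker_map.positions)
    return truth, origin


def apply_observation_model(
    origin: np.ndarray,
    call_rate: float,
    false_call_rate: float,
    seed_or_rng,
    progeny_id: str = "progeny",
) -> ObservedCalls:
    """Degrade a true origin vector into progeny calls.

    Markers drop out independently with probability ``1 - call_rate``; each
    surviving call flips to the opposite parent with probability
    ``false_call_rate``.
    """
    for r in (call_rate, false_call_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must be in [0, 1]")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    origin = np.asarray(origin, dtype=np.int8)
    calls = origin.copy()
    missing = rng.random(origin.size) >= call_rate
    flipped = rng.random(origin.size) < false_call_rate
    calls = np.where(flipped, 1 - calls, calls)
    calls[missing] = MISSING
    return ObservedCalls(progeny_id=progeny_id, calls=calls.astype(np.int8))


def simulate_dataset(
    marker_map: MarkerMap,
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> tuple[list[ChromatidTruth], list[ObservedCalls]]:
    """Simulate ``params.n_progeny`` chromatids and their observed calls."""
    params = params or DEFAULT_PARAMS
    seed = params.seed if seed is None else seed
    truths, observed = [], []
    for i in range(params.n_progeny):
        pid = f"progeny_{i:03d}"
        truth, origin = simulate_chromatid(marker_map, params, seed, i, pid)
        rng = _chromatid_rng(seed, i + 1_000_000)  # separate observation stream
        obs = apply_observation_model(origin, params.call_rate,
                                      params.false_call_rate, rng, pid)
        truths.append(truth)
        observed.append(obs)
    return truths, observed


def generate_annotation(
    chromosome_length: int = DEFAULT_CHROM_LENGTH,
    seed: int = 0,
    mean_exon: float = 400.0,
    mean_intron: float = 1000.0,
    mean_intergenic: float = 2500.0,
    mean_exons_per_gene: float = 4.0,
    chromosome_name: str = "X",
):
    """Synthetic exon/intron/intergenic annotation (0-based half-open).

    Genes alternate exons and introns; defaults give a chromosome that is
    roughly one-quarter exonic, the ballpark of a compact insect genome.
    Returns a pandas DataFrame with columns chrom/start/end/feature.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    pos = 0
    while pos < chromosome_length:
        inter = int(rng.exponential(mean_intergenic)) + 1
        end = min(pos + inter, chromosome_length)
        rows.append((chromosome_name, pos, end, "intergenic"))
        pos = end
        if pos >= chromosome_length:
            break
        n_ex = 1 + rng.geometric(1.0 / mean_exons_per_gene)
        for j in range(n_ex):
            if j > 0:
                ilen = int(rng.exponential(mean_intron)) + 1
                end = min(pos + ilen, chromosome_length)
                rows.append((chromosome_name, pos, end, "intron"))
                pos = end
                if pos >= chromosome_length:
                    break
            elen = int(rng.exponential(mean_exon)) + 1
            end = min(pos + elen, chromosome_length)
            rows.append((chromosome_name, pos, end, "exon"))
            pos = end
            if pos >= chromosome_length:
                break
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature"])
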