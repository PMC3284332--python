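"""Motif statistics downstream of external motif discovery.

Motif discovery and pairwise motif alignment themselves are consumed as
inputs (position weight matrices in MEME-minimal text, similarity tables as
TSV); this module implements the bespoke post-processing:

* exact word counting and composition-based expected counts (O/E ratios),
* PWM scanning with exact score p-values (dynamic programming over the
  discretized score distribution under the background model) and a
  ``p-value x match length`` pass filter,
* Fisher tests of motif enrichment in focal spans versus flanking sequence
  with Benjamini-Hochberg correction,
* "metamotif" clustering: connected components of the motif-similarity
  graph thresholded on ``p-value x alignment length``, and
* empirical nulls from random same-length region sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRegion",
    "PositionWeightMatrix",
    "MotifMatch",
    "count_words",
    "expected_word_count",
    "pwm_scan",
    "flank_enrichment",
    "metamotif_components",
    "empirical_region_null",
    "extract_flank_coords",
    "read_meme_minimal",
    "write_meme_minimal",
    "read_similarity_table",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class SequenceRegion:
    region_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match coordinates")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError("sequence contains non-DNA letters")


@dataclass(frozen=True)
class PositionWeightMatrix:
    motif_id: str
    matrix: np.ndarray  # (width, 4) probabilities, columns A C G T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background",
                           np.asarray(self.background, dtype=float))
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("matrix must be (width, 4)")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("matrix rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    region_id: str
    offset: int  # 0-based within region
    strand: str  # "+" or "-"
    score: float
    p_value: float


def _revcomp(word: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(word).reverse_complement())


def count_words(regions, word: str, both_strands: bool = False):
    """Count (overlapping) occurrences of a DNA word in each region.

    Returns (per-region dict, total).  With ``both_strands`` the reverse
    complement is counted too; a palindromic word is then counted twice per
    site by construction.
    """
    word = word.upper()
    if not word or set(word) - set(_BASES):
        raise ValueError("word must be nonempty A/C/G/T text")
    targets = [word] + ([_revcomp(word)] if both_strands else [])
    per_region = {}
    total = 0
    for reg in regions:
        seq = reg.sequence.upper()
        c = 0
        for t in targets:
            start = seq.find(t)
            while start != -1:
                c += 1
                start = seq.find(t, start + 1)
        per_region[reg.region_id] = c
        total += c
    return per_region, total


def expected_word_count(regions, word: str, composition: str = "pooled"):
    """Expected word count from nucleotide composition, and the O/E ratio.

    Expectation per region is (len - w + 1) times the product over word
    positions of the base frequency of that letter; composition is either
    pooled over all regions (default) or per region.
    """
    word = word.upper()
    if not regions:
        raise ValueError("regions must be non-empty")
    if set(word) - set(_BASES):
        raise ValueError("word must be A/C/G/T text")
    w = len(word)

    def freqs(seq: str) -> np.ndarray:
        counts = np.array([seq.count(b) for b in _BASES], dtype=float)
        return counts / counts.sum() if counts.sum() else counts

    if composition == "pooled":
        pooled = freqs("".join(r.sequence.upper() for r in regions))
        per_freq = {r.region_id: pooled for r in regions}
    elif composition == "per_region":
        per_freq = {r.region_id: freqs(r.sequence.upper()) for r in regions}
    else:
        raise ValueError("composition must be 'pooled' or 'per_region'")

    expected = 0.0
    for r in regions:
        n_pos = max(len(r.sequence) - w + 1, 0)
        f = per_freq[r.region_id]
        expected += n_pos * float(np.prod([f[_CODE[c]] for c in word]))
    _, observed = count_words(regions, word)
    ratio = observed / expected if expected > 0 else None
    return {"observed": observed, "expected": expected, "oe_ratio": ratio,
            "undefined": expected <= 0}


def _score_table(pwm: PositionWeightMatrix, pseudocount: float) -> np.ndarray:
    m = (pwm.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
    return np.log2(m / pwm.background)


def _discretize(scores: np.ndarray, granularity: float) -> np.ndarray:
    # floor keeps the reported p-value conservative (never below the exact)
    return np.floor(scores / granularity).astype(np.int64)


def _score_pvalues(d: np.ndarray, background: np.ndarray):
    """Survival function of the discretized total score under the
    background: returns (offset, sf) so that P(S >= t) = sf[t - offset]."""
    cur_lo = 0
    cur = np.array([1.0])
    for drow in d:
        new_lo = cur_lo + int(drow.min())
        new_hi = cur_lo + len(cur) - 1 + int(drow.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(drow[b]) - new_lo
            new[off:off + len(cur)] += background[b] * cur
        cur, cur_lo = new, new_lo
    sf = np.cumsum(cur[::-1])[::-1]
    return cur_lo, np.concatenate((sf, [0.0]))


def pwm_scan(
    regions,
    pwm: PositionWeightMatrix,
    filter_constant: float = 0.001,
    granularity: float = 1e-4,
    pseudocount: float = 1e-6,
    both_strands: bool = True,
    filter_direction: str = "le",
) -> list[MotifMatch]:
    """Scan regions with a PWM and keep matches passing the p-value filter.

    The log-odds score is computed at every offset and strand; its exact
    p-value is the background tail mass of the discretized score
    distribution.  A match passes when ``p_value * width <= filter_constant``
    (``filter_direction='ge'`` inverts the comparison, for compatibility
    with pipelines that filter the other way).
    """
    if filter_direction not in ("le", "ge"):
        raise ValueError("filter_direction must be 'le' or 'ge'")
    table = _score_table(pwm, pseudocount)
    d = _discretize(table, granularity)
    lo, sf = _score_pvalues(d, pwm.background)
    hi = int(d.max(axis=1).sum())
    w = pwm.width

    matches: list[MotifMatch] = []
    for reg in regions:
        seq = reg.sequence.upper()
        if len(seq) < w:
            continue
        code = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int64)
        for b, i in _CODE.items():
            lut[ord(b)] = i
        codes = lut[code]
        valid = codes >= 0
        strands = [("+", codes, valid)]
        if both_strands:
            rc = np.where(valid, 3 - codes, -1)[::-1]
            strands.append(("-", rc, rc >= 0))
        for strand, cvec, vmask in strands:
            n_off = len(cvec) - w + 1
            win = np.lib.stride_tricks.sliding_window_view(cvec, w)
            ok = np.lib.stride_tricks.sliding_window_view(vmask, w).all(axis=1)
            safe = np.where(win >= 0, win, 0)
            tot = np.take_along_axis(
                np.broadcast_to(d, (n_off, w, 4)), safe[:, :, None], axis=2
            )[:, :, 0].sum(axis=1)
            raw = np.take_along_axis(
                np.broadcast_to(table, (n_off, w, 4)), safe[:, :, None], axis=2
            )[:, :, 0].sum(axis=1)
            idx = np.clip(tot - lo, 0, len(sf) - 1)
            pvals = np.where(tot > hi, 0.0, sf[idx])
            for off in np.flatnonzero(ok):
                p = float(pvals[off])
                crit = p * w
                passes = crit <= filter_constant if filter_direction == "le" \
                    else crit >= filter_constant
                if passes and p > 0.0:
                    real_off = off if strand == "+" else len(cvec) - w - off
                    matches.append(MotifMatch(
                        motif_id=pwm.motif_id, region_id=reg.region_id,
                        offset=int(real_off), strand=strand,
                        score=float(raw[off]), p_value=p))
    return matches


def extract_flank_coords(start: int, end: int, width: int,
                         chromosome_length: int) -> list[tuple[int, int]]:
    """1-based inclusive left/right flank intervals of a focal span,
    clipped at the chromosome ends and excluding the span itself."""
    flanks = []
    left = (max(1, start - width), start - 1)
    right = (end + 1, min(chromosome_length, end + width))
    for lo, hi in (left, right):
        if hi >= lo:
            flanks.append((lo, hi))
    return flanks


def flank_enrichment(
    counts: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher tests of motif match density in spans versus flanks.

    ``counts`` must have one row per (motif_id, flank_width) with columns
    ``span_count, span_positions, flank_count, flank_positions`` where the
    position totals are the nonoverlapping word positions
    (floor(length / motif width)).  Adds raw and Benjamini-Hochberg adjusted
    two-sided P (adjusted within each flank width across motifs) and an
    over/under direction.
    """
    from scipy.stats import fisher_exact
    from statsmodels.stats.multitest import multipletests

    required = {"motif_id", "flank_width", "span_count", "span_positions",
                "flank_count", "flank_positions"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts missing columns {required - set(counts.columns)}")
    df = counts.copy()
    raw, direction = [], []
    for _, row in df.iterrows():
        table = [
            [row.span_count, row.span_positions - row.span_count],
            [row.flank_count, row.flank_positions - row.flank_count],
        ]
        raw.append(float(fisher_exact(table, alternative="two-sided")[1]))
        span_d = row.span_count / row.span_positions if row.span_positions else 0
        flank_d = row.flank_count / row.flank_positions if row.flank_positions else 0
        direction.append("over" if span_d >= flank_d else "under")
    df["p_raw"] = raw
    df["direction"] = direction
    df["p_adj"] = np.nan
    for width, grp in df.groupby("flank_width"):
        adj = multipletests(grp["p_raw"].to_numpy(), method="fdr_bh")[1]
        df.loc[grp.index, "p_adj"] = adj
    df["significant"] = df["p_adj"] <= alpha
    return df


def metamotif_components(
    similarity: pd.DataFrame,
    threshold_constant: float = 0.001,
    run_of=None,
) -> list[dict]:
    """Connected components ("metamotifs") of the motif-similarity graph.

    ``similarity`` has columns motif_a, motif_b, p_value, aln_length and
    must be symmetric (each off-diagonal pair present in both orientations
    with equal values, or given once and mirrored explicitly is rejected).
    An edge joins two motifs when p_value * aln_length <= threshold.
    Components are returned largest first; if ``run_of`` maps a motif id to
    its discovery run, each component reports how many distinct runs
    contributed a member.
    """
    import networkx as nx

    seen: dict[tuple, tuple] = {}
    for row in similarity.itertuples(index=False):
        key = (row.motif_a, row.motif_b)
        rkey = (row.motif_b, row.motif_a)
        val = (float(row.p_value), float(row.aln_length))
        if rkey in seen and not np.allclose(seen[rkey], val):
            raise ValueError(f"similarity matrix asymmetric at {key}")
        seen[key] = val

    for (a, b) in list(seen):
        if a != b and (b, a) not in seen:
            raise ValueError(f"similarity matrix missing symmetric entry ({b}, {a})")

    g = nx.Graph()
    for (a, b), (p, ln) in seen.items():
        g.add_node(a)
        g.add_node(b)
        if a != b and p * ln <= threshold_constant:
            g.add_edge(a, b)

    comps = []
    for nodes in nx.connected_components(g):
        members = sorted(nodes)
        comp = {"members": members, "size": len(members)}
        if run_of is not None:
            getter = run_of if callable(run_of) else run_of.get
            comp["n_runs"] = len({getter(m) for m in members})
        comps.append(comp)
    comps.sort(key=lambda c: (-c["size"], c["members"]))
    return comps


def empirical_region_null(
    statistic,
    regions,
    chromosome_sequence: str,
    n_sets: int = 100,
    seed: int = 0,
    alternative: str = "greater",
) -> dict:
    """Empirical P for a region-set statistic against random same-length
    region sets drawn from the chromosome sequence."""
    lens = [len(r.sequence) for r in regions]
    L = len(chromosome_sequence)
    if max(lens) > L:
        raise ValueError("region longer than source sequence")
    rng = np.random.default_rng(seed)
    observed = float(statistic(regions))
    nulls = np.empty(n_sets)
    for t in range(n_sets):
        fake = []
        for j, ln in enumerate(lens):
            s = int(rng.integers(0, L - ln + 1))
            fake.append(SequenceRegion(
                region_id=f"null_{t}_{j}", start=s + 1, end=s + ln,
                sequence=chromosome_sequence[s:s + ln]))
        nulls[t] = float(statistic(fake))
    if alternative == "greater":
        emp = float(np.mean(nulls >= observed))
    elif alternative == "less":
        emp = float(np.mean(nulls <= observed))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return {"observed": observed, "null_stats": nulls, "empirical_p": emp}


def read_meme_minimal(path) -> list[PositionWeightMatrix]:
    """Read PWMs from a MEME-minimal text file (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][j] for b in _BASES]
                        for j in range(m.length)])
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = np.array([m.background[b] for b in _BASES]) \
            if m.background else np.full(4, 0.25)
        out.append(PositionWeightMatrix(
            motif_id=m.name or f"motif_{len(out) + 1}",
            matrix=mat, background=bg / bg.sum()))
    return out


def write_meme_minimal(pwms, path) -> None:
    """Write PWMs in MEME-minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            # large nsites: Bio.motifs reconstructs counts as prob * nsites,
            # so this bounds the probability quantization at 5e-6
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 100000 E= 0\n")
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_similarity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"motif_a", "motif_b", "p_value", "aln_length"}
    if not required.issubset(df.columns):
        raise ValueError(f"similarity table missing {required - set(df.columns)}")
    return df
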