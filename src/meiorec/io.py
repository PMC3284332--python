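"""Plain-text interchange for marker maps, progeny calls and ground truth.

Formats are deliberately simple, deterministic and diff-friendly:

* marker maps and per-progeny calls as tab-separated text,
* ground-truth events as BED (0-based half-open, crossovers as 1 bp
  features between the flanking nucleotides, conversions as the true
  converted interval),
* simulation parameters as YAML,
* sequences as FASTA (via Biopython).

Round-tripping a dataset through :func:`export_dataset` /
:func:`load_dataset` is byte-stable for a fixed seed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import (
    MISSING,
    ChromatidTruth,
    MarkerMap,
    ObservedCalls,
    SimulationParams,
)

__all__ = [
    "write_marker_map",
    "read_marker_map",
    "write_calls",
    "read_calls",
    "write_truth_bed",
    "read_truth_bed",
    "write_annotation_bed",
    "read_annotation_bed",
    "write_params",
    "read_params",
    "write_fasta",
    "read_fasta",
    "export_dataset",
    "load_dataset",
]

_CALL_TO_TEXT = {0: "P1", 1: "P2", MISSING: "NA"}
_TEXT_TO_CALL = {v: k for k, v in _CALL_TO_TEXT.items()}


def write_marker_map(marker_map: MarkerMap, path) -> None:
    df = pd.DataFrame({
        "chrom": marker_map.chromosome_name,
        "pos": marker_map.positions,
        "kind": marker_map.kinds,
        "allele_P1": marker_map.alleles_p1,
        "allele_P2": marker_map.alleles_p2,
    })
    with open(path, "w") as fh:
        fh.write(f"#chromosome_length={marker_map.chromosome_length}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#chromosome_length="):
            raise ValueError("marker map file missing chromosome_length header")
        length = int(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", dtype={"allele_P1": str, "allele_P2": str})
    df = df.sort_values("pos", kind="stable").reset_index(drop=True)
    chrom = str(df["chrom"].iloc[0]) if len(df) else "X"
    return MarkerMap(
        chromosome_name=chrom,
        chromosome_length=length,
        positions=df["pos"].to_numpy(np.int64),
        kinds=df["kind"].to_numpy(str),
        alleles_p1=df["allele_P1"].to_numpy(str),
        alleles_p2=df["allele_P2"].to_numpy(str),
    )


def write_calls(calls: list[ObservedCalls], marker_map: MarkerMap, path) -> None:
    """One row per marker, one column per progeny (P1/P2/NA)."""
    data = {"chrom": marker_map.chromosome_name, "pos": marker_map.positions}
    for obs in calls:
        data[obs.progeny_id] = [_CALL_TO_TEXT[int(c)] for c in obs.calls]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[ObservedCalls]:
    # keep_default_na: the literal string NA is a missing call, not NaN
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df = df.sort_values("pos", kind="stable").reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    out = []
    for col in df.columns:
        if col in ("chrom", "pos"):
            continue
        vec = np.array([_TEXT_TO_CALL[v] for v in df[col]], dtype=np.int8)
        out.append(ObservedCalls(progeny_id=col, calls=vec))
    return out


def write_truth_bed(truths: list[ChromatidTruth], chromosome_name: str,
                    path) -> None:
    """Ground truth as BED: crossovers as ``CO`` 1 bp features at the
    breakpoint (between base x and x+1), conversions as
    ``GC:<left>:<right>`` over the converted interval."""
    rows = []
    for truth in truths:
        for bp in truth.co_breakpoints:
            rows.append((chromosome_name, int(bp), int(bp) + 1,
                         f"CO\t{truth.progeny_id}"))
        for (dsb, left, right) in truth.gc_events:
            start, end = dsb - left, dsb + right  # 1-based inclusive
            rows.append((chromosome_name, start - 1, end,
                         f"GC:{left}:{right}\t{truth.progeny_id}"))
    with open(path, "w") as fh:
        for chrom, s, e, rest in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{rest}\n")


def read_truth_bed(path) -> list[ChromatidTruth]:
    by_progeny: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            chrom, s, e, name, pid = line.rstrip("\n").split("\t")
            rec = by_progeny.setdefault(pid, {"co": [], "gc": []})
            if name == "CO":
                rec["co"].append(int(s))
            elif name.startswith("GC:"):
                _, left, right = name.split(":")
                left, right = int(left), int(right)
                dsb = int(s) + 1 + left  # invert start = (dsb - left) - 1
                rec["gc"].append((dsb, left, right))
            else:
                raise ValueError(f"unrecognized truth feature {name!r}")
    out = []
    for pid in sorted(by_progeny):
        rec = by_progeny[pid]
        out.append(ChromatidTruth(
            progeny_id=pid,
            start_parent=0,  # not recorded in BED; irrelevant to event truth
            co_breakpoints=np.array(sorted(rec["co"]), dtype=np.int64),
            gc_events=sorted(rec["gc"]),
        ))
    return out


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    annotation[["chrom", "start", "end", "feature"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_annotation_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "feature"])


def write_params(params: SimulationParams, path) -> None:
    import yaml

    d = {
        "n_progeny": params.n_progeny,
        "co_count_probs": list(params.co_count_probs),
        "co_density_breaks": list(params.co_density_breaks),
        "co_density_weights": list(params.co_density_weights),
        "interference_min_separation": params.interference_min_separation,
        "nco_dsb_rate": params.nco_dsb_rate,
        "tract_p": params.tract_p,
        "call_rate": params.call_rate,
        "false_call_rate": params.false_call_rate,
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_params(path) -> SimulationParams:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("co_count_probs", "co_density_breaks", "co_density_weights"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationParams(**d)


def write_fasta(records: dict, path) -> None:
    """Write a mapping of name -> sequence as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    seqio_write(recs, path, "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def export_dataset(out_dir, marker_map: MarkerMap,
                   truths: list[ChromatidTruth],
                   calls: list[ObservedCalls],
                   params: SimulationParams | None = None) -> dict:
    """Write a full simulated dataset into ``out_dir``; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "marker_map": os.path.join(out_dir, "marker_map.tsv"),
        "calls": os.path.join(out_dir, "calls.tsv"),
        "truth": os.path.join(out_dir, "truth.bed"),
    }
    write_marker_map(marker_map, paths["marker_map"])
    write_calls(calls, marker_map, paths["calls"])
    write_truth_bed(truths, marker_map.chromosome_name, paths["truth"])
    if params is not None:
        paths["params"] = os.path.join(out_dir, "params.yaml")
        write_params(params, paths["params"])
    return paths


def load_dataset(out_dir) -> dict:
    paths = {
        "marker_map": os.path.join(out_dir, "marker_map.tsv"),
        "calls": os.path.join(out_dir, "calls.tsv"),
        "truth": os.path.join(out_dir, "truth.bed"),
        "params": os.path.join(out_dir, "params.yaml"),
    }
    out = {
        "marker_map": read_marker_map(paths["marker_map"]),
        "calls": read_calls(paths["calls"]),
        "truths": read_truth_bed(paths["truth"]),
    }
    if os.path.exists(paths["params"]):
        out["params"] = read_params(paths["params"])
    return out
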