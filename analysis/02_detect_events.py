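"""Detect crossovers and noncrossover conversions in the simulated
dataset and tabulate them next to the reference event tables.

Reads results/dataset/, writes results/events_co.tsv, results/events_gc.tsv
and results/events_summary.json.
"""

import json
import pathlib

from meiorec import detect, io

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = io.load_dataset(ROOT / "dataset")
    res = detect.detect_dataset(data["marker_map"], data["calls"])
    co, gc = detect.events_to_frames(res["crossovers"], res["conversions"])
    co.to_csv(ROOT / "events_co.tsv", sep="\t", index=False)
    gc.to_csv(ROOT / "events_gc.tsv", sep="\t", index=False)
    summary = detect.summarize_events(res["crossovers"], res["conversions"])
    summary = {k: v for k, v in summary.items()
               if isinstance(v, (int, float, str, type(None)))}
    with open(ROOT / "events_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
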