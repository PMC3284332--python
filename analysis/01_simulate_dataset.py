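"""Simulate the study-scale dataset: 30 transmitted X chromatids genotyped
at ~93.5k markers over 22.4 Mb, under the default meiosis model.

Writes the marker map, per-progeny calls, ground truth and parameters to
results/dataset/ for the downstream steps.
"""

import pathlib
import sys

from meiorec import io, simulate

SEED = 2025
OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    marker_map = simulate.generate_marker_map(seed=seed)
    params = simulate.SimulationParams(seed=seed)
    truths, calls = simulate.simulate_dataset(marker_map, params)
    paths = io.export_dataset(OUT, marker_map, truths, calls, params)
    for name, path in paths.items():
        print(f"{name}: {path}")


if __name__ == "__main__":
    main()
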