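"""Spacing statistics of the reference crossovers: the clustering null
(minimum adjacent distance of uniformly placed events) and the observed
DCO / SCO midpoint separations.

Writes results/spacing.json.
"""

import json
import pathlib

from meiorec import resampling
from meiorec import reference_events as ref

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 2025


def main() -> None:
    null = resampling.min_distance_null(
        n_events=15, region_length=14_000_000, n_trials=10_000,
        threshold=25_000, seed=SEED)
    closed = resampling.min_distance_closed_form(15, 1.4e7, 25_000)

    co = ref.crossover_table()
    events = [type("E", (), {"progeny_id": r.progeny_id,
                             "midpoint": r.midpoint})()
              for r in co.itertuples(index=False)]
    spacing = resampling.pairwise_distance_summary(events)
    out = {
        "null_fraction_min_distance_le_25kb": null.fraction_below_threshold,
        "null_closed_form": closed,
        "null_mean_min_distance": null.mean_min_distance,
        "dco_separations": spacing["dco_separations"],
        "dco_mean_separation": spacing["dco_mean_separation"],
        "sco_mean_pairwise_distance": spacing["sco_mean_pairwise_distance"],
    }
    with open(ROOT / "spacing.json", "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
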